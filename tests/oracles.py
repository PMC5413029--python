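"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the textbook definition, deliberately avoiding
the code paths in :mod:`divscan` that it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_enumeration(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional HWE p-value by full enumeration in rational
    arithmetic.

    Given n individuals and the observed minor-allele count, the
    probability of h heterozygotes is
    ``2^h * n! / (hAA! h! haa!) / (2n)!/(n_minor! n_major!)``-normalized;
    the two-sided p sums probabilities <= the observed one.
    """
    n = n_hom_major + n_het + n_hom_minor
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)

    def weight(h: int) -> Fraction:
        rem = n_minor - h
        if rem < 0 or rem % 2:
            return Fraction(0)
        hom_minor = rem // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            return Fraction(0)
        # multinomial count x 2^h allele arrangements
        w = Fraction(2) ** h
        w *= Fraction(
            comb(n, h) * comb(n - h, hom_minor)
        )
        return w

    hs = [h for h in range(n_minor % 2, n_minor + 1, 2)]
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    h_obs = n_het
    p_obs = probs[h_obs]
    return float(sum(p for p in probs.values() if p <= p_obs))


def wc_components_scalar(pops: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one biallelic locus, written as
    explicit scalar loops over populations.

    ``pops`` holds one genotype vector (0/1/2 dosages, no missing) per
    population.
    """
    r = len(pops)
    n = [len(g) for g in pops]
    p = [g.sum() / (2 * len(g)) for g in pops]
    h = [(g == 1).mean() for g in pops]

    nbar = sum(n) / r
    nc = (sum(n) - sum(ni**2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)

    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def kinship_tabular(pedigree) -> dict[str, float]:
    """Inbreeding coefficients from the full numerator relationship matrix
    built by the classic tabular recursion (parents-first)."""
    from divscan.cohort import UNKNOWN_PARENT, validate_pedigree

    ped = validate_pedigree(pedigree)
    ids = ped["id"].tolist()
    pos = {ind: i for i, ind in enumerate(ids)}
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    n = len(ids)
    A = np.zeros((n, n))

    def a_of(i: int, parent: str) -> float:
        if parent == UNKNOWN_PARENT or parent not in pos:
            return 0.0
        return A[i, pos[parent]]

    for j, ind in enumerate(ids):
        s, d = sire[ind], dam[ind]
        for i in range(j):
            A[i, j] = A[j, i] = 0.5 * (a_of(i, s) + a_of(i, d))
        if s != UNKNOWN_PARENT and d != UNKNOWN_PARENT and s in pos and d in pos:
            A[j, j] = 1.0 + 0.5 * A[pos[s], pos[d]]
        else:
            A[j, j] = 1.0
    return {ind: A[pos[ind], pos[ind]] - 1.0 for ind in ids}


def random_pedigree(rng: np.random.Generator, n: int):
    """Random acyclic pedigree of <= n individuals for oracle comparison."""
    import pandas as pd
    from divscan.cohort import UNKNOWN_PARENT

    rows = []
    ids = []
    for i in range(n):
        ind = f"I{i}"
        if i < 2 or rng.random() < 0.25:
            sire = dam = UNKNOWN_PARENT
        else:
            sire, dam = rng.choice(ids, size=2, replace=True)
            if sire == dam and rng.random() < 0.8:
                dam = UNKNOWN_PARENT  # mostly avoid selfing, keep some
        rows.append({"id": ind, "sire": sire, "dam": dam, "breed": "X"})
        ids.append(ind)
    return pd.DataFrame(rows)
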