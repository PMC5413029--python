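"""Synthetic cohorts with known ground truth.

Four generators cover every analysis stage:

* :func:`simulate_balding_nichols` — breed allele frequencies drawn around a
  shared ancestral frequency with a per-breed drift parameter ``c``; the
  expected Weir-Cockerham theta is ``c``, making it the oracle for the F_ST
  stage.
* :func:`simulate_pedigree` + :func:`gene_drop` — pedigrees with known
  expected inbreeding, gene-dropped through a recombining genome so that
  true autozygous (identical-by-descent) tracts are recorded exactly;
  oracle for ROH detection and the inbreeding coefficients.
* :func:`simulate_wright_fisher` — forward simulation of a constant-size
  random-mating population (Poisson recombination, recurrent mutation);
  oracle for LD-based Ne recovery.
* :func:`inject_sweep` — drives a region toward fixation in chosen breeds, a
  positive control for signature calling and ROH hotspots.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import UNKNOWN_PARENT, Cohort, make_snp_table

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------- layouts
def default_snp_layout(
    n_snps: int = 5000,
    n_chromosomes: int = 26,
    spacing_bp: int = 100_000,
    cm_per_mb: float = 1.0,
) -> pd.DataFrame:
    """Evenly spaced SNPs over equal-sized autosomes with a uniform genetic
    map (default 1 cM/Mb)."""
    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes, dtype=int)
    per_chrom[: n_snps % n_chromosomes] += 1
    chroms, bps, ids = [], [], []
    for c in range(n_chromosomes):
        k = per_chrom[c]
        chroms += [c + 1] * k
        pos = (np.arange(k) * spacing_bp + 1).tolist()
        bps += pos
        ids += [f"snp{c + 1}_{j + 1}" for j in range(k)]
    cm = [(b - 1) / 1e6 * cm_per_mb for b in bps]
    tbl = make_snp_table(ids, chroms, bps, cm)
    tbl["allele_counted"] = "A"
    tbl["allele_other"] = "B"
    return tbl


# --------------------------------------------------------- Balding-Nichols
@dataclass
class BreedSimConfig:
    """One breed in the drift model: its label, sample size and drift
    parameter ``c`` (the expected differentiation from the shared ancestral
    population)."""

    label: str
    n_individuals: int
    drift_c: float

    def __post_init__(self) -> None:
        if not 0 < self.drift_c < 1:
            raise ValueError(f"drift_c must be in (0, 1), got {self.drift_c}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def simulate_balding_nichols(
    configs: list[BreedSimConfig],
    snp_table: pd.DataFrame | None = None,
    n_snps: int = 5000,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Multi-breed cohort under the Balding-Nichols drift model.

    Per SNP an ancestral frequency ``p`` is drawn uniformly; each breed's
    frequency comes from ``Beta(p(1-c)/c, (1-p)(1-c)/c)`` and genotypes are
    binomial draws from it (Hardy-Weinberg within breed).
    """
    if len(configs) < 2:
        raise ValueError("need >= 2 breeds")
    rng = np.random.default_rng(seed)
    snps = snp_table if snp_table is not None else default_snp_layout(n_snps)
    m = len(snps)
    p_anc = rng.uniform(*ancestral_range, size=m)

    blocks, ids, breeds = [], [], []
    for cfg in configs:
        c = cfg.drift_c
        freq = rng.beta(p_anc * (1 - c) / c, (1 - p_anc) * (1 - c) / c)
        blocks.append(rng.binomial(2, freq, size=(cfg.n_individuals, m)).astype(np.int8))
        ids += [f"{cfg.label}_{i + 1:04d}" for i in range(cfg.n_individuals)]
        breeds += [cfg.label] * cfg.n_individuals
    calls = np.vstack(blocks)
    samples = pd.DataFrame({"id": ids, "breed": breeds})
    return Cohort(calls=calls, snps=snps.copy(), samples=samples)


# ----------------------------------------------------------------- pedigree
def simulate_pedigree(
    n_founders: int = 20,
    generations: int = 3,
    mating: str = "random",
    offspring_per_generation: int | None = None,
    breed: str = "PED",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pedigree with a known expected inbreeding structure.

    ``random``: each generation draws distinct sires/dams uniformly from the
    previous one.  ``full_sib_loop``: two founders, then repeated full-sib
    matings (first-loop offspring have F = 1/4).  ``half_sib_loop``: one
    shared sire and two dams, then the two half-sibs are mated (offspring
    F = 1/8), continuing with sib matings in later loops.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def add(ind: str, sire: str, dam: str) -> None:
        rows.append({"id": ind, "sire": sire, "dam": dam, "breed": breed})

    if mating == "random":
        prev = [f"G0_{i + 1}" for i in range(n_founders)]
        for ind in prev:
            add(ind, UNKNOWN_PARENT, UNKNOWN_PARENT)
        size = offspring_per_generation or n_founders
        for g in range(1, generations + 1):
            cur = []
            for i in range(size):
                sire, dam = rng.choice(prev, size=2, replace=False)
                ind = f"G{g}_{i + 1}"
                add(ind, sire, dam)
                cur.append(ind)
            prev = cur
    elif mating == "full_sib_loop":
        add("G0_1", UNKNOWN_PARENT, UNKNOWN_PARENT)
        add("G0_2", UNKNOWN_PARENT, UNKNOWN_PARENT)
        prev = ("G0_1", "G0_2")
        for g in range(1, generations + 1):
            a, b = f"G{g}_1", f"G{g}_2"
            add(a, prev[0], prev[1])
            add(b, prev[0], prev[1])
            prev = (a, b)
    elif mating == "half_sib_loop":
        for ind in ("G0_sire", "G0_dam1", "G0_dam2"):
            add(ind, UNKNOWN_PARENT, UNKNOWN_PARENT)
        add("G1_1", "G0_sire", "G0_dam1")
        add("G1_2", "G0_sire", "G0_dam2")
        prev = ("G1_1", "G1_2")
        for g in range(2, generations + 1):
            a, b = f"G{g}_1", f"G{g}_2"
            add(a, prev[0], prev[1])
            add(b, prev[0], prev[1])
            prev = (a, b)
    else:
        raise ValueError(f"unknown mating rule {mating!r}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- gene drop
def gene_drop(
    pedigree: pd.DataFrame,
    snp_table: pd.DataFrame,
    founder_freqs: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[Cohort, pd.DataFrame]:
    """Drop founder haplotypes through a pedigree with recombination.

    Founders carry two uniquely labelled haplotypes whose alleles are drawn
    from ``founder_freqs`` (default: uniform 0.5).  Each meiosis recombines
    the parental pair with a Poisson number of crossovers placed uniformly
    in genetic distance.  A descendant's autozygous tracts are the maximal
    marker intervals where both haplotype labels agree.

    Returns the cohort and a truth table with one row per autozygous
    segment (columns ``individual_id, chrom, start_bp, end_bp, n_snps``)
    plus per-individual autozygosity fractions in ``.attrs["autozygosity"]``.
    """
    rng = np.random.default_rng(seed)
    snps = snp_table.reset_index(drop=True)
    m = len(snps)
    cm = snps["cM"].to_numpy(float)
    if np.isnan(cm).any():
        raise ValueError("gene_drop requires genetic positions on every SNP")
    freqs = np.full(m, 0.5) if founder_freqs is None else np.asarray(founder_freqs, float)

    chrom_slices: list[tuple[int, slice, np.ndarray]] = []
    for chrom, sub in snps.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        chrom_slices.append((chrom, slice(idx[0], idx[-1] + 1), cm[idx]))

    labels: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    next_label = 0

    def new_founder_haps() -> tuple[np.ndarray, np.ndarray]:
        nonlocal next_label
        lab = np.empty((2, m), dtype=np.int32)
        lab[0], lab[1] = next_label, next_label + 1
        next_label += 2
        al = (rng.random((2, m)) < freqs).astype(np.int8)
        return lab, al

    def gamete(parent: str) -> tuple[np.ndarray, np.ndarray]:
        lab_out = np.empty(m, dtype=np.int32)
        al_out = np.empty(m, dtype=np.int8)
        plab, pal = labels[parent], alleles[parent]
        for _, sl, cms in chrom_slices:
            span = cms[-1] - cms[0]
            k = rng.poisson(span / 100.0)  # crossovers ~ Poisson(Morgans)
            cuts = np.sort(rng.uniform(cms[0], cms[-1], size=k))
            phase = (np.searchsorted(cuts, cms, side="right") + rng.integers(2)) % 2
            lab_out[sl] = np.where(phase == 0, plab[0, sl], plab[1, sl])
            al_out[sl] = np.where(phase == 0, pal[0, sl], pal[1, sl])
        return lab_out, al_out

    from .cohort import validate_pedigree

    ped = validate_pedigree(pedigree)
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    for ind in ped["id"]:
        s, d = sire[ind], dam[ind]
        if s == UNKNOWN_PARENT or d == UNKNOWN_PARENT:
            labels[ind], alleles[ind] = new_founder_haps()
            continue
        for par in (s, d):
            if par not in labels:  # parent listed but never a row: founder
                labels[par], alleles[par] = new_founder_haps()
        l1, a1 = gamete(s)
        l2, a2 = gamete(d)
        labels[ind] = np.stack([l1, l2])
        alleles[ind] = np.stack([a1, a2])

    ids = ped["id"].tolist()
    calls = np.stack([alleles[i].sum(axis=0) for i in ids]).astype(np.int8)
    samples = pd.DataFrame({"id": ids, "breed": ped["breed"].tolist()})
    cohort = Cohort(calls=calls, snps=snps.copy(), samples=samples, pedigree=ped)

    bp = snps["bp"].to_numpy()
    truth_rows = []
    autozygosity: dict[str, float] = {}
    genome_span = sum(int(bp[sl][-1] - bp[sl][0]) for _, sl, _ in chrom_slices)
    for ind in ids:
        ibd = labels[ind][0] == labels[ind][1]
        covered = 0
        for chrom, sl, _ in chrom_slices:
            mask = ibd[sl]
            b = bp[sl]
            j = 0
            while j < mask.size:
                if not mask[j]:
                    j += 1
                    continue
                k2 = j
                while k2 + 1 < mask.size and mask[k2 + 1]:
                    k2 += 1
                truth_rows.append(
                    {"individual_id": ind, "chrom": chrom, "start_bp": int(b[j]),
                     "end_bp": int(b[k2]), "n_snps": k2 - j + 1}
                )
                covered += int(b[k2] - b[j])
                j = k2 + 1
        autozygosity[ind] = covered / genome_span if genome_span else 0.0
    truth = pd.DataFrame(
        truth_rows, columns=["individual_id", "chrom", "start_bp", "end_bp", "n_snps"]
    )
    truth.attrs["autozygosity"] = autozygosity
    return cohort, truth


# ------------------------------------------------------------ Wright-Fisher
def simulate_wright_fisher(
    n_diploid: int,
    generations: int,
    snp_table: pd.DataFrame | None = None,
    n_snps: int = 2000,
    n_chromosomes: int = 2,
    spacing_bp: int = 100_000,
    mutation_rate: float = 1e-5,
    n_sample: int | None = None,
    initial_freq: tuple[float, float] = (0.2, 0.8),
    seed: int | np.random.Generator = 0,
    breed: str = "WF",
) -> Cohort:
    """Forward simulation of a constant-size random-mating diploid
    population.

    2N haplotypes evolve for the given number of generations; gametes
    recombine as an interference-free (Poisson) crossover process on the
    genetic map and mutate at ``mutation_rate`` per site per transmission.
    A terminal sample of individuals is returned as a cohort; N is the
    ground truth for LD-based Ne recovery.
    """
    if n_diploid < 20:
        raise ValueError("n_diploid must be >= 20")
    rng = np.random.default_rng(seed)
    snps = (
        snp_table.reset_index(drop=True)
        if snp_table is not None
        else default_snp_layout(n_snps, n_chromosomes, spacing_bp)
    )
    m = len(snps)
    cm = snps["cM"].to_numpy(float)
    haps = (
        rng.random((2 * n_diploid, m)) < rng.uniform(*initial_freq, size=m)
    ).astype(np.int8)

    chrom_info = []
    for _, sub in snps.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        chrom_info.append((slice(idx[0], idx[-1] + 1), cm[idx]))

    n_gam = 2 * n_diploid
    for _ in range(generations):
        parents = rng.integers(n_diploid, size=n_gam)
        new = np.empty_like(haps)
        for sl, cms in chrom_info:
            span_m = (cms[-1] - cms[0]) / 100.0
            k = rng.poisson(span_m, size=n_gam)
            total = int(k.sum())
            cuts = rng.uniform(cms[0], cms[-1], size=total)
            gidx = np.repeat(np.arange(n_gam), k)
            sidx = np.searchsorted(cms, cuts, side="right")
            switch = np.zeros((n_gam, cms.size), dtype=np.int32)
            valid = sidx < cms.size
            np.add.at(switch, (gidx[valid], sidx[valid]), 1)
            phase = (np.cumsum(switch, axis=1) + rng.integers(2, size=n_gam)[:, None]) % 2
            a = haps[2 * parents, sl]
            b = haps[2 * parents + 1, sl]
            new[:, sl] = np.where(phase == 0, a, b)
        n_mut = rng.poisson(mutation_rate * n_gam * m)
        if n_mut:
            rr = rng.integers(n_gam, size=n_mut)
            cc = rng.integers(m, size=n_mut)
            new[rr, cc] ^= 1
        haps = new

    n_sample = n_sample or n_diploid
    pick = rng.choice(n_diploid, size=min(n_sample, n_diploid), replace=False)
    calls = (haps[2 * pick] + haps[2 * pick + 1]).astype(np.int8)
    samples = pd.DataFrame(
        {"id": [f"{breed}_{i + 1:04d}" for i in range(len(pick))], "breed": breed}
    )
    return Cohort(calls=calls, snps=snps.copy(), samples=samples)


# ------------------------------------------------------------------ sweeps
@dataclass
class SweepConfig:
    """A post-hoc selective sweep: genotypes inside the region are resampled
    toward ``final_freq`` (near 1) in the target breeds only."""

    chrom: int
    start_bp: int
    end_bp: int
    target_breeds: list[str] = field(default_factory=list)
    final_freq: float = 0.98


def inject_sweep(
    cohort: Cohort, sweep: SweepConfig, seed: int | np.random.Generator = 0
) -> Cohort:
    """Return a copy of the cohort with the sweep applied."""
    rng = np.random.default_rng(seed)
    snps = cohort.snps
    in_region = (
        (snps["chrom"] == sweep.chrom)
        & (snps["bp"] >= sweep.start_bp)
        & (snps["bp"] <= sweep.end_bp)
    ).to_numpy()
    if in_region.sum() < 5:
        raise ValueError(
            f"sweep region {sweep.chrom}:{sweep.start_bp}-{sweep.end_bp} holds "
            f"{int(in_region.sum())} SNPs, need >= 5"
        )
    calls = cohort.calls.copy()
    targets = sweep.target_breeds or cohort.breeds
    for breed in targets:
        rows = cohort.breed_index[breed]
        block = rng.binomial(2, sweep.final_freq, size=(rows.size, int(in_region.sum())))
        calls[np.ix_(rows, np.flatnonzero(in_region))] = block.astype(np.int8)
    return Cohort(
        calls=calls,
        snps=snps.copy(),
        samples=cohort.samples.copy(),
        pedigree=cohort.pedigree,
        n_autosomes=cohort.n_autosomes,
    )
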