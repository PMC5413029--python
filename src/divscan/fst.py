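"""Weir-Cockerham F_ST and selection-signature calling.

Per SNP the three variance components of the Weir & Cockerham (1984)
estimator are computed from observed genotype (and heterozygote) counts:
``a`` among populations, ``b`` among individuals within populations, ``c``
within individuals; ``theta = a / (a + b + c)``.  A centred 5-SNP window
smooths per-SNP theta; signatures are seeded at the top 0.1% of windowed
values and extended SNP-by-SNP until two consecutive SNPs fall outside the
top 5%, including the first of the stopping pair and excluding the second.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, Cohort

logger = logging.getLogger(__name__)

FST_COLUMNS = ["snp_id", "chrom", "bp", "a", "b", "c", "theta"]


# --------------------------------------------------------------- estimator
def wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Weir-Cockerham (1984) variance components for one locus
    set.

    Parameters are per-population arrays of shape ``(r, m)``: sample sizes
    ``n`` (typed individuals), allele frequencies ``p`` and observed
    heterozygote frequencies ``h``.  Returns ``(a, b, c)`` of shape ``(m,)``.
    """
    r = n.shape[0]
    if r < 2:
        raise ValueError("need >= 2 populations")
    n_sum = n.sum(axis=0)
    nbar = n_sum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1)
        pbar = (n * p).sum(axis=0) / n_sum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / n_sum

        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1.0)
            * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def wc_theta(cohort: Cohort, breeds: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components and theta across the given breeds
    (default: all).  Monomorphic-across-breeds SNPs get theta NaN."""
    breeds = breeds or cohort.breeds
    if len(breeds) < 2:
        raise ValueError("need >= 2 breeds for F_ST")
    index = cohort.breed_index
    m = cohort.n_snps
    r = len(breeds)
    n = np.zeros((r, m))
    p = np.zeros((r, m))
    h = np.zeros((r, m))
    for k, breed in enumerate(breeds):
        calls = cohort.calls[index[breed]]
        typed = calls != MISSING
        nk = typed.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(typed, calls, 0).sum(axis=0) / (2.0 * np.maximum(nk, 1)), np.nan)
            h[k] = np.where(nk > 0, (calls == 1).sum(axis=0) / np.maximum(nk, 1), np.nan)

    a, b, c = wc_components(n, p, h)
    denom = a + b + c
    pbar = (n * p).sum(axis=0) / n.sum(axis=0)
    poly = (pbar > 0) & (pbar < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(poly & (denom != 0), a / denom, np.nan)

    out = cohort.snps[["snp_id", "chrom", "bp"]].copy()
    out["a"], out["b"], out["c"] = a, b, c
    out["theta"] = theta
    return out


def pairwise_fst(cohort: Cohort) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-SNP theta for every breed pair (6 breeds -> 15 tables)."""
    return {
        (b1, b2): wc_theta(cohort, [b1, b2])
        for b1, b2 in itertools.combinations(cohort.breeds, 2)
    }


def mean_genomic_fst(records: pd.DataFrame) -> float:
    """Unweighted mean of per-SNP theta over SNPs where it is defined."""
    theta = records["theta"].to_numpy(float)
    if np.isnan(theta).all():
        raise ValueError("no defined theta values")
    return float(np.nanmean(theta))


# ----------------------------------------------------------------- windows
def window_average(records: pd.DataFrame, window_snps: int = 5) -> pd.DataFrame:
    """Centred moving average of theta; the middle SNP of each full
    same-chromosome window carries the mean, edge SNPs get NaN."""
    if window_snps % 2 == 0 or window_snps < 1:
        raise ValueError("window_snps must be odd and positive")
    half = window_snps // 2
    out = records.copy()
    win = np.full(len(out), np.nan)
    for _, sub in out.groupby("chrom", sort=False):
        theta = sub["theta"].to_numpy(float)
        if theta.size < window_snps:
            continue
        sums = pd.Series(theta).rolling(window_snps, center=True, min_periods=window_snps).mean()
        win[sub.index.to_numpy()] = sums.to_numpy()
    out["windowed_theta"] = win
    defined = ~np.isnan(win)
    pct = np.full(len(out), np.nan)
    if defined.any():
        vals = win[defined]
        pct[defined] = stats.rankdata(vals, method="max") / vals.size
    out["percentile_rank"] = pct
    return out


# -------------------------------------------------------------- signatures
def call_signatures(
    records: pd.DataFrame, top_call: float = 0.001, top_extend: float = 0.05
) -> pd.DataFrame:
    """Call selection-signature regions from windowed theta.

    Seeds are SNPs at or above the (1 - top_call) empirical quantile of the
    windowed values.  From each seed the region grows SNP-by-SNP in both
    directions; growth stops once two consecutive SNPs rank outside the top
    ``top_extend`` fraction — the first of that pair is kept inside the
    region, the second is not.  Overlapping or adjacent regions merge.
    """
    win = records["windowed_theta"].to_numpy(float)
    defined = ~np.isnan(win)
    if not defined.any():
        return pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "n_top_snps", "max_windowed_theta", "max_snp_id"]
        )
    call_thr = float(np.quantile(win[defined], 1.0 - top_call))
    ext_thr = float(np.quantile(win[defined], 1.0 - top_extend))

    regions: list[tuple[int, int, int]] = []  # (chrom-start idx range)
    rows_out = []
    for chrom, sub in records.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        w = win[idx]
        seeds = np.flatnonzero(~np.isnan(w) & (w >= call_thr))
        if seeds.size == 0:
            continue
        intervals: list[tuple[int, int]] = []
        for s in seeds:
            lo = _extend(w, s, -1, ext_thr)
            hi = _extend(w, s, +1, ext_thr)
            intervals.append((lo, hi))
        intervals.sort()
        merged = [intervals[0]]
        for lo, hi in intervals[1:]:
            if lo <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        seed_set = set(seeds.tolist())
        bp = sub["bp"].to_numpy()
        sid = sub["snp_id"].to_numpy()
        for lo, hi in merged:
            inside = np.arange(lo, hi + 1)
            w_in = w[inside]
            best = inside[int(np.nanargmax(w_in))]
            rows_out.append(
                {
                    "chrom": chrom,
                    "start_bp": int(bp[lo]),
                    "end_bp": int(bp[hi]),
                    "n_top_snps": sum(1 for j in inside if j in seed_set),
                    "max_windowed_theta": float(w[best]),
                    "max_snp_id": sid[best],
                }
            )
    return pd.DataFrame(
        rows_out,
        columns=["chrom", "start_bp", "end_bp", "n_top_snps", "max_windowed_theta", "max_snp_id"],
    )


def _extend(w: np.ndarray, seed: int, step: int, ext_thr: float) -> int:
    """Walk from a seed in one direction; stop at two consecutive SNPs below
    the extension threshold, keeping the first and dropping the second.
    NaN windowed values (chromosome edges) count as below threshold."""
    last_in = seed
    consec = 0
    j = seed + step
    while 0 <= j < w.size:
        below = np.isnan(w[j]) or w[j] < ext_thr
        if not below:
            last_in = j
            consec = 0
        else:
            consec += 1
            if consec == 2:
                break
            last_in = j  # first sub-threshold SNP stays inside
        j += step
    return min(seed, last_in) if step < 0 else max(seed, last_in)


# ------------------------------------------------------------- correlation
def correlate_snp_stat_with_incidence(
    records: pd.DataFrame, incidence: np.ndarray, stat: str = "theta"
) -> tuple[float, float]:
    """Pearson correlation (r, p) between a per-SNP statistic and per-SNP
    ROH incidence over SNPs where both are defined."""
    x = records[stat].to_numpy(float)
    y = np.asarray(incidence, dtype=float)
    if x.size != y.size:
        raise ValueError("statistic and incidence must cover the same SNP set")
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        raise ValueError("correlation undefined: zero variance or too few SNPs")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)
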