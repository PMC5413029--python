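"""Effective population size from the decay of linkage disequilibrium.

Within a breed, squared genotype correlations (r²) between same-chromosome
SNP pairs are adjusted for sample size, binned by the recombination
fraction ``c`` implied by physical distance, and inverted through

    N_T(t) = (4 f(c_t))^-1 * ( E[r²_adj | c_t]^-1 - alpha )

where ``t = (2 f(c_t))^-1`` generations ago, ``f`` is the distance-to-
recombination mapping and ``alpha`` corrects for mutation (2) or not (1).
Bins at large ``c`` (distant pairs) inform recent generations; bins at
small ``c`` inform deeper history.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort

logger = logging.getLogger(__name__)

MAPPING_FUNCTIONS = ("linear_1cM_per_Mb", "haldane", "sved_feldman")


@dataclass
class NeParams:
    """Settings for the LD -> Ne inversion.

    min_maf:
        within-breed MAF filter before pair formation (default 0.05).
    max_pair_distance_kb:
        only pairs closer than this are used (default 10 Mb).
    n_distance_bins:
        equal-width bins in recombination fraction (default 30).
    min_pairs_per_bin:
        bins with fewer pairs are dropped (default 100).
    mapping_function:
        physical distance -> recombination fraction: ``linear_1cM_per_Mb``
        (c = bp * 1e-8, capped at 0.5), ``haldane`` (c = (1 - e^{-2m})/2)
        or ``sved_feldman`` (c = m / (1 + 2m)), m in Morgans at 1 cM/Mb.
    alpha_mutation:
        2 with the mutation correction (default), 1 without.
    sample_size_adjustment:
        ``unphased`` subtracts 1/n (genotype r², default); ``phased``
        subtracts 1/(2n).
    generation_interval_years:
        multiplies t for the optional calendar-year column (default 4).
    """

    min_maf: float = 0.05
    max_pair_distance_kb: float = 10_000.0
    n_distance_bins: int = 30
    min_pairs_per_bin: int = 100
    mapping_function: str = "sved_feldman"
    alpha_mutation: float = 2.0
    sample_size_adjustment: str = "unphased"
    generation_interval_years: float = 4.0

    def __post_init__(self) -> None:
        if self.n_distance_bins < 2:
            raise ValueError("n_distance_bins must be >= 2")
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")
        if self.mapping_function not in MAPPING_FUNCTIONS:
            raise ValueError(f"mapping_function must be one of {MAPPING_FUNCTIONS}")
        if self.sample_size_adjustment not in ("unphased", "phased"):
            raise ValueError("sample_size_adjustment must be 'unphased' or 'phased'")


# ---------------------------------------------------------------- plumbing
def distance_to_c(distance_bp: float, mapping: str = "linear_1cM_per_Mb") -> float:
    """Recombination fraction for a physical distance, assuming 1 cM/Mb."""
    m = distance_bp * 1e-8  # Morgans
    if mapping == "linear_1cM_per_Mb":
        return min(m, 0.5)
    if mapping == "haldane":
        return 0.5 * (1.0 - math.exp(-2.0 * m))
    if mapping == "sved_feldman":
        return m / (1.0 + 2.0 * m)
    raise ValueError(f"unknown mapping {mapping!r}")


def adjust_r2(r2: float, n: int, mode: str = "unphased") -> float:
    """Subtract the finite-sample expectation: 1/n for genotype (unphased)
    r², 1/(2n) for haplotype (phased) r².  May go negative."""
    if n < 2:
        raise ValueError("need n >= 2")
    if mode == "unphased":
        return r2 - 1.0 / n
    if mode == "phased":
        return r2 - 1.0 / (2.0 * n)
    raise ValueError(f"unknown adjustment mode {mode!r}")


def pairwise_r2(
    cohort: Cohort, breed: str, params: NeParams | None = None
) -> pd.DataFrame:
    """All same-chromosome SNP pairs within the distance cap for one breed:
    columns ``distance_bp, r2, n`` (n = individuals typed at both SNPs).

    SNPs below the within-breed MAF threshold are excluded up front.
    """
    params = params or NeParams()
    sub = cohort.breed_view(breed)
    maf = sub.minor_allele_frequencies()
    keep = np.flatnonzero(maf > params.min_maf)
    sub = sub.subset(snps=keep)
    max_d = params.max_pair_distance_kb * 1e3

    dist_out: list[np.ndarray] = []
    r2_out: list[np.ndarray] = []
    n_out: list[np.ndarray] = []
    for _, chrom_snps in sub.snps.groupby("chrom", sort=True):
        idx = chrom_snps.index.to_numpy()
        bp = chrom_snps["bp"].to_numpy(dtype=np.int64)
        calls = sub.calls[:, idx].astype(np.float64)
        missing = sub.calls[:, idx] == MISSING
        if missing.any():
            d, r2, n = _pairwise_r2_masked(calls, missing, bp, max_d)
        else:
            d, r2, n = _pairwise_r2_complete(calls, bp, max_d)
        dist_out.append(d)
        r2_out.append(r2)
        n_out.append(n)
    return pd.DataFrame(
        {
            "distance_bp": np.concatenate(dist_out) if dist_out else np.array([], dtype=np.int64),
            "r2": np.concatenate(r2_out) if r2_out else np.array([]),
            "n": np.concatenate(n_out) if n_out else np.array([], dtype=np.int64),
        }
    )


def _pairwise_r2_complete(calls, bp, max_d):
    """Fast path, no missing data: standardized cross-products per block."""
    n_ind, m = calls.shape
    mu = calls.mean(axis=0)
    sd = calls.std(axis=0)
    z = (calls - mu) / sd  # MAF filter guarantees sd > 0
    d_list, r_list, n_list = [], [], []
    for j in range(m - 1):
        hi = np.searchsorted(bp, bp[j] + max_d, side="right")
        if hi <= j + 1:
            continue
        r = z[:, j + 1: hi].T @ z[:, j] / n_ind
        d_list.append(bp[j + 1: hi] - bp[j])
        r_list.append(r * r)
        n_list.append(np.full(hi - j - 1, n_ind, dtype=np.int64))
    if not d_list:
        return (np.array([], dtype=np.int64), np.array([]), np.array([], dtype=np.int64))
    return np.concatenate(d_list), np.concatenate(r_list), np.concatenate(n_list)


def _pairwise_r2_masked(calls, missing, bp, max_d):
    """Pairwise-complete path for data with missing genotypes."""
    m = calls.shape[1]
    d_list, r_list, n_list = [], [], []
    for j in range(m - 1):
        hi = np.searchsorted(bp, bp[j] + max_d, side="right")
        for k in range(j + 1, hi):
            ok = ~missing[:, j] & ~missing[:, k]
            n = int(ok.sum())
            if n < 2:
                continue
            x, y = calls[ok, j], calls[ok, k]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
            d_list.append(bp[k] - bp[j])
            r_list.append(r * r)
            n_list.append(n)
    return (
        np.asarray(d_list, dtype=np.int64),
        np.asarray(r_list, dtype=float),
        np.asarray(n_list, dtype=np.int64),
    )


# --------------------------------------------------------------- inversion
def estimate_ne(bins: pd.DataFrame, params: NeParams | None = None) -> pd.DataFrame:
    """Apply the closed-form inversion to distance bins.

    ``bins`` needs columns ``c`` and ``mean_r2_adj``; adds ``N_t`` and
    ``t`` (= 1/(2c) generations).  Bins with non-positive adjusted r² or
    non-positive N_t are flagged invalid (N_t = NaN, valid = False).
    """
    params = params or NeParams()
    out = bins.copy()
    c = out["c"].to_numpy(float)
    r2 = out["mean_r2_adj"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_t = np.where(r2 > 0, (1.0 / (4.0 * c)) * (1.0 / r2 - params.alpha_mutation), np.nan)
    valid = np.isfinite(n_t) & (n_t > 0)
    out["N_t"] = np.where(valid, n_t, np.nan)
    out["t"] = 1.0 / (2.0 * c)
    out["valid"] = valid
    return out


def bin_pairs(pairs: pd.DataFrame, params: NeParams | None = None) -> pd.DataFrame:
    """Adjust r² for sample size and average it within equal-width bins of
    the recombination fraction implied by distance."""
    params = params or NeParams()
    if pairs.empty:
        return pd.DataFrame(columns=["c", "mean_distance_bp", "mean_r2_adj", "n_pairs"])
    d = pairs["distance_bp"].to_numpy(float)
    c = np.array([distance_to_c(x, params.mapping_function) for x in np.unique(d)])
    c_map = dict(zip(np.unique(d), c))
    c_all = np.array([c_map[x] for x in d])
    adj = pairs["r2"].to_numpy(float) - (
        1.0 / pairs["n"].to_numpy(float)
        if params.sample_size_adjustment == "unphased"
        else 1.0 / (2.0 * pairs["n"].to_numpy(float))
    )
    edges = np.linspace(c_all.min(), c_all.max(), params.n_distance_bins + 1)
    which = np.clip(np.digitize(c_all, edges) - 1, 0, params.n_distance_bins - 1)
    rows = []
    for b in range(params.n_distance_bins):
        sel = which == b
        n_pairs = int(sel.sum())
        if n_pairs < params.min_pairs_per_bin:
            continue
        rows.append(
            {
                "c": float(c_all[sel].mean()),
                "mean_distance_bp": float(d[sel].mean()),
                "mean_r2_adj": float(adj[sel].mean()),
                "n_pairs": n_pairs,
            }
        )
    return pd.DataFrame(rows)


def ne_trajectory(
    cohort: Cohort, breed: str, params: NeParams | None = None
) -> pd.DataFrame:
    """Full pipeline for one breed: pairwise r² -> adjust -> bin -> invert;
    sorted by t ascending, with a calendar-years column."""
    params = params or NeParams()
    pairs = pairwise_r2(cohort, breed, params)
    bins = bin_pairs(pairs, params)
    if bins.empty:
        logger.warning("ne_trajectory(%s): no bin met the minimum pair count", breed)
        return pd.DataFrame(
            columns=["t", "years", "c", "mean_distance_bp", "mean_r2_adj", "n_pairs", "N_t", "valid"]
        )
    est = estimate_ne(bins, params)
    est["years"] = est["t"] * params.generation_interval_years
    est = est.sort_values("t").reset_index(drop=True)
    return est[["t", "years", "c", "mean_distance_bp", "mean_r2_adj", "n_pairs", "N_t", "valid"]]
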