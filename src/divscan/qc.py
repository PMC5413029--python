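"""Quality control and LD pruning.

The filter chain runs in a fixed order: individual/SNP call rate, then
autosome + minor-allele-frequency, then within-breed Hardy-Weinberg exact
test.  LD pruning is a separate step used before structure-sensitive
analyses.  Re-running the chain on its own output removes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort

logger = logging.getLogger(__name__)


@dataclass
class QcParams:
    """Thresholds for the QC chain.

    min_call_rate:
        individuals and SNPs below this fraction of non-missing calls are
        dropped (default 0.95).
    min_maf:
        SNPs with minor allele frequency strictly below this are dropped
        (default 0.01); frequency is computed across all retained individuals.
    hwe_p_threshold:
        a SNP is dropped if its exact HWE p-value falls strictly below this
        in ANY single breed (default 1e-7).
    prune_r2, prune_window_snps:
        LD pruning: within sliding windows of ``prune_window_snps`` SNPs the
        later SNP of any pair with genotype r² > ``prune_r2`` is removed.
    """

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    hwe_p_threshold: float = 1e-7
    prune_r2: float = 0.1
    prune_window_snps: int = 50

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.prune_window_snps < 2:
            raise ValueError("prune_window_snps must be >= 2")


@dataclass
class QcReport:
    """Per-step removal counts, in application order."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, kind: str, removed: int, retained: int) -> None:
        self.steps.append(
            {"step": step, "kind": kind, "removed": int(removed), "retained": int(retained)}
        )
        logger.info("qc %s: removed %d %s, retained %d", step, removed, kind, retained)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "kind", "removed", "retained"])


# ------------------------------------------------------------------ filters
def filter_call_rate(
    cohort: Cohort, params: QcParams | None = None, report: QcReport | None = None
) -> tuple[Cohort, QcReport]:
    """Drop individuals, then SNPs, with call rate below the threshold.

    SNP call rates are computed on the retained individuals.
    """
    params = params or QcParams()
    report = report or QcReport()
    ind_rate = cohort.call_rates(axis=1)
    keep_ind = np.flatnonzero(ind_rate >= params.min_call_rate)
    if keep_ind.size == 0:
        raise ValueError("call-rate filter removed every individual")
    report.add("call_rate", "individuals", cohort.n_individuals - keep_ind.size, keep_ind.size)
    cohort = cohort.subset(individuals=keep_ind)

    snp_rate = cohort.call_rates(axis=0)
    keep_snp = np.flatnonzero(snp_rate >= params.min_call_rate)
    report.add("call_rate", "snps", cohort.n_snps - keep_snp.size, keep_snp.size)
    return cohort.subset(snps=keep_snp), report


def filter_maf_autosomal(
    cohort: Cohort, params: QcParams | None = None, report: QcReport | None = None
) -> tuple[Cohort, QcReport]:
    """Drop non-autosomal SNPs, then SNPs with MAF < min_maf (strict)."""
    params = params or QcParams()
    report = report or QcReport()
    auto = cohort.is_autosomal()
    report.add("autosomal", "snps", int((~auto).sum()), int(auto.sum()))
    cohort = cohort.subset(snps=np.flatnonzero(auto))

    maf = cohort.minor_allele_frequencies()
    keep = np.flatnonzero(~(maf < params.min_maf))  # NaN (all-missing) kept here
    report.add("maf", "snps", cohort.n_snps - keep.size, keep.size)
    return cohort.subset(snps=keep), report


# ----------------------------------------------------------------- HWE test
@lru_cache(maxsize=100_000)
def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts with the same parity, the hypergeometric probabilities that are
    at most the probability of the observed configuration.  No mid-p
    correction.
    """
    nAA, nAa, naa = int(n_hom_major), int(n_het), int(n_hom_minor)
    if min(nAA, nAa, naa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = nAA + nAa + naa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_minor = 2 * naa + nAa
    n_major = 2 * nAA + nAa
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor

    log_probs = _hwe_log_probs(n, n_minor)
    # log_probs index k corresponds to het count n_minor%2 + 2k
    het_counts = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    obs_lp = log_probs[np.searchsorted(het_counts, nAa)]
    p = np.exp(log_probs[log_probs <= obs_lp + 1e-12]).sum()
    return float(min(p, 1.0))


def _hwe_log_probs(n: int, n_minor: int) -> np.ndarray:
    """Log-probabilities of each feasible heterozygote count given n
    individuals and n_minor copies of the rarer allele."""
    from scipy.special import gammaln

    het = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_minor = (n_minor - het) // 2
    hom_major = n - het - hom_minor
    lp = (
        het * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(het + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hom_major + 1)
    )
    # normalize within the conditional distribution
    m = lp.max()
    lp = lp - (m + np.log(np.exp(lp - m).sum()))
    return lp


def hwe_filter_within_breed(
    cohort: Cohort, params: QcParams | None = None, report: QcReport | None = None
) -> tuple[Cohort, QcReport]:
    """Drop SNPs whose exact HWE p-value is below threshold in any breed."""
    params = params or QcParams()
    report = report or QcReport()
    fail = np.zeros(cohort.n_snps, dtype=bool)
    for breed, rows in cohort.breed_index.items():
        calls = cohort.calls[rows]
        n_het = (calls == 1).sum(axis=0)
        n_hom_minor = (calls == 2).sum(axis=0)
        n_hom_major = (calls == 0).sum(axis=0)
        for j in range(cohort.n_snps):
            if fail[j]:
                continue
            total = n_hom_major[j] + n_het[j] + n_hom_minor[j]
            if total == 0:
                logger.debug("breed %s: SNP %d all-missing, HWE skipped", breed, j)
                continue
            p = hwe_exact_test(int(n_hom_major[j]), int(n_het[j]), int(n_hom_minor[j]))
            if p < params.hwe_p_threshold:
                fail[j] = True
    keep = np.flatnonzero(~fail)
    report.add("hwe", "snps", int(fail.sum()), keep.size)
    return cohort.subset(snps=keep), report


def run_qc_chain(
    cohort: Cohort, params: QcParams | None = None
) -> tuple[Cohort, QcReport]:
    """Full chain: call rate -> autosome/MAF -> within-breed HWE."""
    params = params or QcParams()
    report = QcReport()
    cohort, report = filter_call_rate(cohort, params, report)
    cohort, report = filter_maf_autosomal(cohort, params, report)
    cohort, report = hwe_filter_within_breed(cohort, params, report)
    return cohort, report


# --------------------------------------------------------------- LD pruning
def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors with pairwise
    deletion of missing genotypes; NaN if fewer than 2 shared calls or a
    vector is constant."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(cohort: Cohort, params: QcParams | None = None) -> Cohort:
    """Remove the later SNP of every within-window pair with r² above the
    threshold.

    Windows slide one SNP at a time over the kept set: each candidate SNP is
    compared against the previous ``prune_window_snps - 1`` kept SNPs on its
    chromosome and dropped on the first violation, so the earlier (lower-bp)
    SNP of a violating pair always survives and no within-window pair of the
    output exceeds the threshold.  Deterministic given input order.
    """
    params = params or QcParams()
    w = params.prune_window_snps
    keep_mask = np.zeros(cohort.n_snps, dtype=bool)
    for _, sub in cohort.snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        kept: list[int] = []  # kept SNPs so far on this chromosome, in order
        for j in idx:
            clean = True
            for a in kept[-(w - 1):]:
                r2 = genotype_r2(cohort.calls[:, a], cohort.calls[:, j])
                if not np.isnan(r2) and r2 > params.prune_r2:
                    clean = False
                    break
            if clean:
                kept.append(j)
                keep_mask[j] = True
    keep = np.flatnonzero(keep_mask)
    logger.info("ld_prune: removed %d of %d SNPs", cohort.n_snps - keep.size, cohort.n_snps)
    return cohort.subset(snps=keep)
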