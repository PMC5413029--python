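"""Runs of homozygosity: sliding-window detection, length-class and
chromosome summaries, per-SNP incidence, hotspot calling, recombination-rate
windows and TMRCA binning from genetic lengths.

Detection follows the classic 50-SNP sliding-window scan: windows tolerate
at most one heterozygote and two missing calls; a SNP joins a run when a
sufficient fraction of the windows overlapping it are compliant; runs are
split at large physical gaps and must clear minimum SNP-count, length and
density bounds.  The minimum SNP count guards against chance runs and is
derived from the genome-wide false-positive rate:

    l = ceil( ln(alpha / (n_s * n_i)) / ln(1 - mean_het) )

with ``n_s`` SNPs per individual, ``n_i`` individuals and ``mean_het`` the
mean per-SNP heterozygosity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = [
    "individual_id",
    "breed",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_mb",
    "genetic_length_cM",
]

#: physical length classes (Mb), left-closed right-open
LENGTH_CLASSES = [(1.0, 5.0), (5.0, 10.0), (10.0, 15.0), (15.0, 20.0), (20.0, math.inf)]

#: TMRCA bins: a run of genetic length l cM reflects a common ancestor about
#: g = 100/(2 l) generations back, so bin edges at g = 5, 10, 20 generations
#: fall at l = 10, 5, 2.5 cM.
TMRCA_BINS = [
    ("<=5 generations", 10.0, math.inf),
    ("5-10 generations", 5.0, 10.0),
    ("10-20 generations", 2.5, 5.0),
    (">20 generations", 0.0, 2.5),
]


@dataclass
class RohScanParams:
    """Sliding-window scan parameters (defaults are the standard SNP-array
    settings: 50-SNP windows, <=1 het, <=2 missing, 1 SNP/100 kb density,
    250-kb maximum gap, 1-Mb minimum length)."""

    window_size: int = 50
    max_missing_per_window: int = 2
    max_het_per_window: int = 1
    window_hit_threshold: float = 0.05
    min_snps: int | None = None  # None: derive via lencz_min_snps
    min_length_mb: float = 1.0
    min_density_kb_per_snp: float = 100.0
    max_gap_kb: float = 250.0
    false_positive_alpha: float = 0.05
    min_window_size: int = 20  # smallest usable window on short chromosomes

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        for name in ("window_hit_threshold", "min_length_mb", "min_density_kb_per_snp", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def lencz_min_snps(
    n_snps_per_individual: int,
    n_individuals: int,
    alpha: float = 0.05,
    mean_het: float = 0.35,
) -> int:
    """Minimum SNPs per run for a genome-wide false-positive rate ``alpha``.

    Evaluates ``ceil(ln(alpha/(n_s*n_i)) / ln(1-mean_het))``.
    """
    if not 0 < mean_het < 1:
        raise ValueError("mean_het must be in (0, 1)")
    if n_snps_per_individual < 1 or n_individuals < 1:
        raise ValueError("counts must be >= 1")
    value = math.log(alpha / (n_snps_per_individual * n_individuals)) / math.log(
        1.0 - mean_het
    )
    return int(math.ceil(value))


def mean_snp_heterozygosity(cohort: Cohort) -> float:
    """Mean over SNPs of the fraction of heterozygous calls among typed
    individuals."""
    het = (cohort.calls == 1).sum(axis=0, dtype=float)
    typed = (cohort.calls != MISSING).sum(axis=0, dtype=float)
    with np.errstate(invalid="ignore"):
        per_snp = np.where(typed > 0, het / np.maximum(typed, 1), np.nan)
    return float(np.nanmean(per_snp))


# -------------------------------------------------------------------- scan
def scan_roh(cohort: Cohort, params: RohScanParams | None = None) -> pd.DataFrame:
    """Detect ROH for every individual; returns one row per segment sorted
    by individual, chromosome, start."""
    params = params or RohScanParams()
    min_snps = params.min_snps
    if min_snps is None:
        het = mean_snp_heterozygosity(cohort)
        if not 0 < het < 1:
            raise ValueError(f"cannot derive minimum run length: mean het {het}")
        min_snps = lencz_min_snps(
            cohort.n_snps, cohort.n_individuals, params.false_positive_alpha, het
        )
        logger.info("scan_roh: Lencz minimum run length = %d SNPs (mean het %.3f)", min_snps, het)

    rows: list[tuple] = []
    ids = cohort.samples["id"].to_numpy()
    breeds = cohort.samples["breed"].to_numpy()
    max_gap_bp = params.max_gap_kb * 1e3
    for chrom, sub in cohort.snps.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        n = idx.size
        w = params.window_size
        if n < w:
            if n >= params.min_window_size:
                w = n
            else:
                logger.warning("chromosome %s: %d SNPs < %d, skipped", chrom, n, params.min_window_size)
                continue
        bp = sub["bp"].to_numpy()
        cm = sub["cM"].to_numpy(dtype=float)
        calls = cohort.calls[:, idx]
        gap_split = np.flatnonzero(np.diff(bp) > max_gap_bp)  # run breaks after these

        for i in range(cohort.n_individuals):
            g = calls[i]
            qual = _qualifying_snps(g, w, params)
            for s, e in _runs(qual, gap_split):
                n_run = e - s + 1
                length_bp = bp[e] - bp[s] + 1
                if n_run < min_snps:
                    continue
                if length_bp < params.min_length_mb * 1e6:
                    continue
                if length_bp / n_run > params.min_density_kb_per_snp * 1e3:
                    continue
                gen_len = cm[e] - cm[s] if not (np.isnan(cm[s]) or np.isnan(cm[e])) else np.nan
                rows.append(
                    (ids[i], breeds[i], chrom, int(bp[s]), int(bp[e]), n_run,
                     length_bp / 1e6, gen_len)
                )
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return seg.sort_values(["individual_id", "chrom", "start_bp"], kind="stable").reset_index(
        drop=True
    )


def _qualifying_snps(g: np.ndarray, w: int, params: RohScanParams) -> np.ndarray:
    """Boolean mask of SNPs whose fraction of overlapping compliant windows
    meets the hit threshold."""
    n = g.size
    het = np.concatenate(([0], np.cumsum(g == 1)))
    mis = np.concatenate(([0], np.cumsum(g == MISSING)))
    n_win = n - w + 1
    starts = np.arange(n_win)
    compliant = (
        (het[starts + w] - het[starts] <= params.max_het_per_window)
        & (mis[starts + w] - mis[starts] <= params.max_missing_per_window)
    ).astype(np.int64)
    ccum = np.concatenate(([0], np.cumsum(compliant)))
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n_win - 1)
    total = hi - lo + 1
    hits = ccum[hi + 1] - ccum[lo]
    return hits / total >= params.window_hit_threshold


def _runs(qual: np.ndarray, gap_split: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, split after indices listed in ``gap_split``."""
    if not qual.any():
        return []
    breaks = set(gap_split.tolist())
    runs: list[tuple[int, int]] = []
    start = None
    for j, q in enumerate(qual):
        if q and start is None:
            start = j
        if start is not None and (not q):
            runs.append((start, j - 1))
            start = None
        elif start is not None and j in breaks:
            runs.append((start, j))
            start = None
    if start is not None:
        runs.append((start, qual.size - 1))
    return runs


# --------------------------------------------------------------- summaries
def summarize_length_classes(segments: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Mean per-animal sum of ROH length (Mb) per breed per physical length
    class; animals without ROH in a class contribute zero."""
    counts = cohort.samples.groupby("breed", sort=False).size()
    out = []
    for lo, hi in LENGTH_CLASSES:
        label = f"[{lo:g},{hi:g})" if math.isfinite(hi) else f">={lo:g}"
        in_class = segments[(segments["length_mb"] >= lo) & (segments["length_mb"] < hi)]
        sums = in_class.groupby("breed")["length_mb"].sum()
        for breed, n_animals in counts.items():
            out.append(
                {
                    "breed": breed,
                    "length_class_mb": label,
                    "mean_sum_mb": float(sums.get(breed, 0.0)) / n_animals,
                }
            )
    return pd.DataFrame(out)


def snp_roh_incidence(
    segments: pd.DataFrame, cohort: Cohort, breed: str | None = None
) -> np.ndarray:
    """Per-SNP fraction of individuals (of one breed, or pooled) whose ROH
    set covers the SNP."""
    if breed is None:
        n_scope = cohort.n_individuals
        seg = segments
    else:
        n_scope = int((cohort.samples["breed"] == breed).sum())
        seg = segments[segments["breed"] == breed]
    counts = np.zeros(cohort.n_snps, dtype=np.int64)
    if n_scope == 0:
        return counts.astype(float)
    for chrom, sub in cohort.snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        bp = sub["bp"].to_numpy()
        for row in seg[seg["chrom"] == chrom].itertuples():
            s = np.searchsorted(bp, row.start_bp, side="left")
            e = np.searchsorted(bp, row.end_bp, side="right") - 1
            if e >= s:
                counts[idx[s]: idx[s] + (e - s) + 1] += 1
    return counts / n_scope


def call_hotspots(
    incidence: np.ndarray, cohort: Cohort, top_fraction: float = 0.01
) -> pd.DataFrame:
    """Merge runs of map-adjacent SNPs at or above the top incidence
    percentile into hotspot regions."""
    threshold = float(np.quantile(incidence, 1.0 - top_fraction))
    # a SNP never seen inside a ROH can never be a hotspot member
    selected = (incidence >= threshold) & (incidence > 0)
    rows = []
    for chrom, sub in cohort.snps.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        bp = sub["bp"].to_numpy()
        cm = sub["cM"].to_numpy(dtype=float)
        sel = selected[idx]
        j = 0
        while j < sel.size:
            if not sel[j]:
                j += 1
                continue
            k = j
            while k + 1 < sel.size and sel[k + 1]:
                k += 1
            span_mb = (bp[k] - bp[j]) / 1e6
            if k > j and not (np.isnan(cm[j]) or np.isnan(cm[k])) and span_mb > 0:
                rate = (cm[k] - cm[j]) / span_mb
            else:
                rate = np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(bp[j]),
                    "end_bp": int(bp[k]),
                    "n_snps": k - j + 1,
                    "mean_recomb_cM_per_Mb": rate,
                }
            )
            j = k + 1
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "mean_recomb_cM_per_Mb"])


def chromosome_roh_fraction(segments: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Breed x chromosome table of mean per-individual ROH coverage divided
    by the SNP-covered chromosome length."""
    counts = cohort.samples.groupby("breed", sort=False).size()
    rows = []
    for chrom, sub in cohort.snps.groupby("chrom", sort=True):
        bp = sub["bp"].to_numpy()
        length = float(bp[-1] - bp[0])
        on_chrom = segments[segments["chrom"] == chrom]
        sums = (on_chrom["end_bp"] - on_chrom["start_bp"] + 1).groupby(
            on_chrom["breed"]
        ).sum()
        for breed, n_animals in counts.items():
            frac = float(sums.get(breed, 0.0)) / n_animals / length if length > 0 else np.nan
            rows.append({"breed": breed, "chrom": chrom, "roh_fraction": frac})
    return pd.DataFrame(rows)


def tmrca_bins(segments: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Mean per-animal sum of ROH genetic length (cM) per breed per TMRCA
    bin; segments without a genetic length are excluded and counted."""
    counts = cohort.samples.groupby("breed", sort=False).size()
    has_cm = segments["genetic_length_cM"].notna()
    dropped = int((~has_cm).sum())
    if dropped:
        logger.warning("tmrca_bins: %d segment(s) lack genetic length, excluded", dropped)
    seg = segments[has_cm]
    rows = []
    for label, lo, hi in TMRCA_BINS:
        in_bin = seg[(seg["genetic_length_cM"] >= lo) & (seg["genetic_length_cM"] < hi)]
        sums = in_bin.groupby("breed")["genetic_length_cM"].sum()
        for breed, n_animals in counts.items():
            rows.append(
                {
                    "breed": breed,
                    "tmrca_bin": label,
                    "mean_sum_cM": float(sums.get(breed, 0.0)) / n_animals,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_segments_without_cM"] = dropped
    return out


def tmrca_bin_label(genetic_length_cM: float) -> str:
    """TMRCA bin for one run: l = 100/(2g) cM maps bin edges g=5,10,20 to
    l=10,5,2.5 cM (left-closed)."""
    for label, lo, hi in TMRCA_BINS:
        if lo <= genetic_length_cM < hi:
            return label
    raise ValueError(f"invalid genetic length {genetic_length_cM}")


def recombination_windows(cohort: Cohort, window_kb: float = 500.0) -> pd.DataFrame:
    """Mean recombination rate (cM/Mb) in non-overlapping physical tiles;
    tiles with fewer than two mapped SNPs get NaN."""
    w_bp = int(window_kb * 1e3)
    rows = []
    for chrom, sub in cohort.snps.groupby("chrom", sort=True):
        bp = sub["bp"].to_numpy()
        cm = sub["cM"].to_numpy(dtype=float)
        mapped = ~np.isnan(cm)
        tiles = (bp - 1) // w_bp
        for t in np.unique(tiles):
            sel = (tiles == t) & mapped
            if sel.sum() < 2:
                rate = np.nan
            else:
                b, c = bp[sel], cm[sel]
                rate = (c[-1] - c[0]) / ((b[-1] - b[0]) / 1e6)
            rows.append(
                {
                    "chrom": chrom,
                    "tile_start_bp": int(t * w_bp + 1),
                    "tile_end_bp": int((t + 1) * w_bp),
                    "n_snps": int((tiles == t).sum()),
                    "cM_per_Mb": rate,
                }
            )
    return pd.DataFrame(rows)
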