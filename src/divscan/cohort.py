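"""In-memory cohort model shared by every analysis stage.

A :class:`Cohort` bundles a genotype dosage matrix (individuals x SNPs,
counting copies of the cohort-wide minor allele), the SNP map (chromosome,
physical bp, optional genetic cM), per-individual breed labels and an
optional pedigree.  All downstream stages (QC, ROH, inbreeding, FST, Ne)
consume and return this one container.

Conventions
-----------
* genotype codes: 0, 1, 2 = minor-allele dosage; ``MISSING`` (-1) = no call
* coordinates: 1-based inclusive bp; intervals downstream are closed
  ``[start_bp, end_bp]``
* autosomes: integer chromosome labels ``1..n_autosomes`` (26 for sheep)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING: int = -1

#: sentinel used for unknown parents in pedigree tables
UNKNOWN_PARENT: str = "0"

SNP_COLUMNS = ["snp_id", "chrom", "bp", "cM"]
SAMPLE_COLUMNS = ["id", "breed"]
PEDIGREE_COLUMNS = ["id", "sire", "dam", "breed"]


class CohortFormatError(ValueError):
    """Raised when an input file or table violates the cohort contracts."""


@dataclass
class Cohort:
    """Genotypes + SNP map + breed labels (+ optional pedigree).

    Parameters
    ----------
    calls:
        ``(n_individuals, n_snps)`` int8 array of minor-allele dosages with
        ``MISSING`` (-1) for no-calls.
    snps:
        DataFrame with columns ``snp_id, chrom, bp, cM`` sorted by
        ``(chrom, bp)``; ``cM`` is NaN where no genetic position is known.
    samples:
        DataFrame with columns ``id, breed``.
    pedigree:
        Optional DataFrame with columns ``id, sire, dam, breed``; unknown
        parents are ``UNKNOWN_PARENT``.
    n_autosomes:
        Number of autosomes in the karyotype (sheep: 26).  Chromosome labels
        outside ``1..n_autosomes`` are treated as non-autosomal by QC.
    """

    calls: np.ndarray
    snps: pd.DataFrame
    samples: pd.DataFrame
    pedigree: pd.DataFrame | None = None
    n_autosomes: int = 26

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise CohortFormatError("calls must be 2-D (individuals x snps)")
        self.snps = self.snps.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise CohortFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} individuals x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise CohortFormatError("genotype codes must be in {0,1,2,missing}")
        self._validate_map()

    def _validate_map(self) -> None:
        for col in SNP_COLUMNS:
            if col not in self.snps.columns:
                raise CohortFormatError(f"SNP table lacks column {col!r}")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            if (bp < 1).any():
                raise CohortFormatError(f"chromosome {chrom}: bp positions must be >= 1")
            if not np.all(np.diff(bp) > 0):
                raise CohortFormatError(
                    f"chromosome {chrom}: SNPs must be strictly increasing in bp"
                )
            cm = sub["cM"].to_numpy(dtype=float)
            known = cm[~np.isnan(cm)]
            if known.size and not np.all(np.diff(known) >= -1e-9):
                raise CohortFormatError(
                    f"chromosome {chrom}: genetic positions must be non-decreasing"
                )

    # ------------------------------------------------------------------ views
    @property
    def n_individuals(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def breeds(self) -> list[str]:
        """Breed labels in first-appearance order."""
        return list(dict.fromkeys(self.samples["breed"]))

    @property
    def breed_index(self) -> dict[str, np.ndarray]:
        """Map breed -> array of row indices into ``calls``."""
        idx: dict[str, np.ndarray] = {}
        breeds = self.samples["breed"].to_numpy()
        for b in self.breeds:
            idx[b] = np.flatnonzero(breeds == b)
        return idx

    def subset(
        self,
        individuals: np.ndarray | Iterable[int] | None = None,
        snps: np.ndarray | Iterable[int] | None = None,
    ) -> "Cohort":
        """Return a new cohort restricted to the given row/column indices."""
        rows = np.arange(self.n_individuals) if individuals is None else np.asarray(list(individuals))
        cols = np.arange(self.n_snps) if snps is None else np.asarray(list(snps))
        return replace(
            self,
            calls=self.calls[np.ix_(rows, cols)],
            snps=self.snps.iloc[cols],
            samples=self.samples.iloc[rows],
        )

    def breed_view(self, breed: str) -> "Cohort":
        idx = self.breed_index.get(breed)
        if idx is None:
            raise KeyError(f"unknown breed {breed!r}")
        return self.subset(individuals=idx)

    # ------------------------------------------------------------- statistics
    def allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Frequency of the counted (minor-at-read-time) allele per SNP.

        Missing genotypes are excluded; SNPs with no typed individual get NaN.
        """
        calls = self.calls if rows is None else self.calls[rows]
        typed = calls != MISSING
        dose = np.where(typed, calls, 0).sum(axis=0, dtype=np.float64)
        n = typed.sum(axis=0, dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def minor_allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Computed from integer allele counts so the result is exactly
        invariant under allele relabeling."""
        calls = self.calls if rows is None else self.calls[rows]
        typed = calls != MISSING
        dose = np.where(typed, calls, 0).sum(axis=0, dtype=np.int64)
        n2 = 2 * typed.sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n2 > 0, np.minimum(dose, n2 - dose) / np.maximum(n2, 1), np.nan)

    def call_rates(self, axis: int) -> np.ndarray:
        """Fraction of non-missing calls per individual (axis=1) or SNP (axis=0)."""
        return (self.calls != MISSING).mean(axis=axis)

    def is_autosomal(self) -> np.ndarray:
        chrom = self.snps["chrom"].to_numpy()
        return (chrom >= 1) & (chrom <= self.n_autosomes)

    def map_span_bp(self) -> int:
        """Total autosome length implied by the SNP map: sum over chromosomes
        of (last SNP bp - first SNP bp)."""
        span = 0
        for _, sub in self.snps.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            span += int(bp[-1] - bp[0])
        return span


def make_snp_table(
    snp_ids: Iterable[str],
    chrom: Iterable[int],
    bp: Iterable[int],
    cM: Iterable[float] | None = None,
) -> pd.DataFrame:
    tbl = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": np.asarray(list(chrom), dtype=np.int64),
            "bp": np.asarray(list(bp), dtype=np.int64),
        }
    )
    tbl["cM"] = np.nan if cM is None else np.asarray(list(cM), dtype=float)
    return tbl


def make_sample_table(ids: Iterable[str], breeds: Iterable[str]) -> pd.DataFrame:
    return pd.DataFrame({"id": list(ids), "breed": list(breeds)})


def validate_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Check acyclicity and return rows in topological (parents-first) order.

    Parents that never appear as individuals are implicit founders.
    """
    for col in PEDIGREE_COLUMNS:
        if col not in pedigree.columns:
            raise CohortFormatError(f"pedigree lacks column {col!r}")
    ped = pedigree.reset_index(drop=True).copy()
    for col in ("id", "sire", "dam"):
        ped[col] = ped[col].astype(str)
    ped.loc[ped["sire"].isin(("", "nan", "NA")), "sire"] = UNKNOWN_PARENT
    ped.loc[ped["dam"].isin(("", "nan", "NA")), "dam"] = UNKNOWN_PARENT
    if ped["id"].duplicated().any():
        dup = ped.loc[ped["id"].duplicated(), "id"].iloc[0]
        raise CohortFormatError(f"duplicate individual {dup!r} in pedigree")

    parents: Mapping[str, tuple[str, str]] = {
        r.id: (r.sire, r.dam) for r in ped.itertuples()
    }
    order: list[str] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    for root in ped["id"]:
        if state.get(root) == 1:
            continue
        stack = [(root, False)]
        path: list[str] = []
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 1
                order.append(node)
                path.pop()
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                cycle = path[path.index(node):] + [node]
                raise CohortFormatError(
                    "pedigree contains a cycle: " + " -> ".join(cycle)
                )
            state[node] = 0
            path.append(node)
            stack.append((node, True))
            for par in parents.get(node, (UNKNOWN_PARENT, UNKNOWN_PARENT)):
                if par != UNKNOWN_PARENT and par in parents:
                    stack.append((par, False))
    rank = {ind: i for i, ind in enumerate(order)}
    return ped.iloc[np.argsort([rank[i] for i in ped["id"]], kind="stable")].reset_index(
        drop=True
    )
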