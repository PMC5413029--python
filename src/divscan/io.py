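"""Readers and writers for PLINK-dialect genotype files, pedigrees and
linkage maps.

Supported formats
-----------------
* PED/MAP text (4-column MAP: chrom, snp_id, cM, bp; PED: 6 metadata
  columns + two allele columns per SNP, ``0`` = missing allele)
* BED/BIM/FAM binary (SNP-major, 2 bits per genotype)
* pedigree CSV/TSV with header ``id,sire,dam,breed``
* linkage-map TSV with header ``snp_id,chrom,cM``

On read, genotypes are recoded to dosages of the cohort-wide minor allele;
the counted/other allele labels are kept on the SNP table (columns
``allele_counted`` / ``allele_other``) so writers can reproduce the input.
The PED family id doubles as the breed label.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    MISSING,
    UNKNOWN_PARENT,
    Cohort,
    CohortFormatError,
    make_snp_table,
    validate_pedigree,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes((0x6C, 0x1B))
_SNP_MAJOR = 0x01


# --------------------------------------------------------------------- text
def read_plink_text(ped_path: str | Path, map_path: str | Path) -> Cohort:
    """Read a PED/MAP pair into a :class:`Cohort`.

    Alleles are recoded so the cohort-wide minor allele is counted; ``0 0``
    pairs become missing.  A MAP whose cM column is all zero is taken to
    carry no genetic positions.
    """
    snps = _read_map(map_path)
    m = len(snps)

    fids: list[str] = []
    iids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise CohortFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"(6 metadata + 2 alleles x {m} SNPs), got {len(parts)}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            allele_rows.append(parts[6:])

    n = len(iids)
    a = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty(
        (0, m, 2), dtype=object
    )
    calls, counted, other = _recode_alleles(a, snps["snp_id"])
    snps["allele_counted"] = counted
    snps["allele_other"] = other
    samples = pd.DataFrame({"id": iids, "breed": fids})
    calls, snps = _canonical_snp_order(calls, snps)
    return Cohort(calls=calls, snps=snps, samples=samples)


def _canonical_snp_order(calls: np.ndarray, snps: pd.DataFrame):
    """Sort SNPs by (chrom, bp), keeping calls columns aligned."""
    order = np.lexsort((snps["bp"].to_numpy(), snps["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(snps))):
        calls = calls[:, order]
        snps = snps.iloc[order].reset_index(drop=True)
    return calls, snps


def _read_map(map_path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cM", "bp"],
        dtype={"chrom": str, "snp_id": str, "cM": float, "bp": np.int64},
    )
    chrom = pd.to_numeric(raw["chrom"], errors="coerce")
    if chrom.isna().any():
        # non-numeric labels (X, MT, ...) map to 0 = non-autosomal
        chrom = chrom.fillna(0)
    snps = make_snp_table(raw["snp_id"], chrom.astype(np.int64), raw["bp"], raw["cM"])
    if (snps["cM"] == 0).all():
        snps["cM"] = np.nan  # all-zero cM column: no genetic map provided
    return snps


def _recode_alleles(
    alleles: np.ndarray, snp_ids: pd.Series
) -> tuple[np.ndarray, list[str], list[str]]:
    """Map an (n, m, 2) allele-symbol array to minor-allele dosages."""
    n, m, _ = alleles.shape
    calls = np.full((n, m), MISSING, dtype=np.int8)
    counted: list[str] = []
    other: list[str] = []
    for j in range(m):
        col = alleles[:, j, :]
        present = col != "0"
        symbols, counts = np.unique(col[present], return_counts=True)
        if len(symbols) > 2:
            raise CohortFormatError(
                f"SNP {snp_ids.iloc[j]!r} has >2 alleles: {sorted(symbols)}"
            )
        if len(symbols) == 0:
            counted.append("0")
            other.append("0")
            continue
        if len(symbols) == 1:
            # monomorphic: the minor allele is the absent one, dosage 0
            counted.append("0")
            other.append(str(symbols[0]))
            both_called = present.all(axis=1)
            calls[both_called, j] = 0
            continue
        else:
            # minor = rarer symbol; lexicographic tie-break for determinism
            order = np.lexsort((symbols, counts))
            minor, major = symbols[order[0]], symbols[order[1]]
        counted.append(str(minor))
        other.append(str(major))
        both_called = present.all(axis=1)
        dose = (col == minor).sum(axis=1)
        calls[both_called, j] = dose[both_called]
    return calls, counted, other


def write_plink_text(cohort: Cohort, ped_path: str | Path, map_path: str | Path) -> None:
    snps = cohort.snps
    cm = snps["cM"].fillna(0.0)
    with open(map_path, "w") as fh:
        for chrom, sid, c, bp in zip(snps["chrom"], snps["snp_id"], cm, snps["bp"]):
            fh.write(f"{chrom}\t{sid}\t{c:g}\t{bp}\n")

    counted = snps.get("allele_counted", pd.Series(["A"] * len(snps))).to_numpy()
    other = snps.get("allele_other", pd.Series(["B"] * len(snps))).to_numpy()
    # a monomorphic column read back keeps its single symbol
    other = np.where(other == "0", counted, other)
    with open(ped_path, "w") as fh:
        for i, (iid, breed) in enumerate(zip(cohort.samples["id"], cohort.samples["breed"])):
            fields = [str(breed), str(iid), "0", "0", "0", "-9"]
            row = cohort.calls[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [other[j], other[j]]
                elif g == 1:
                    fields += [counted[j], other[j]]
                else:
                    fields += [counted[j], counted[j]]
            fh.write(" ".join(fields) + "\n")


# ------------------------------------------------------------------- binary
def read_plink_binary(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> Cohort:
    """Read a BED/BIM/FAM triple (SNP-major) into a :class:`Cohort`.

    Produces the same cohort as :func:`read_plink_text` on equivalent data:
    dosages are re-anchored to the cohort-wide minor allele after decoding.
    """
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cM", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "cM": float, "bp": np.int64, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)

    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if len(header) < 3 or header[:2] != _BED_MAGIC:
            raise CohortFormatError(f"{bed_path}: bad BED magic bytes")
        if header[2] != _SNP_MAJOR:
            raise CohortFormatError(f"{bed_path}: not SNP-major (mode byte {header[2]:#x})")
        payload = np.frombuffer(fh.read(), dtype=np.uint8)

    bytes_per_snp = (n + 3) // 4
    if payload.size != bytes_per_snp * m:
        raise CohortFormatError(
            f"{bed_path}: payload size {payload.size} != {bytes_per_snp} bytes x {m} SNPs"
        )
    calls_a1 = _unpack_bed(payload, n, m)

    chrom = pd.to_numeric(bim["chrom"], errors="coerce").fillna(0).astype(np.int64)
    snps = make_snp_table(bim["snp_id"], chrom, bim["bp"], bim["cM"])
    if (snps["cM"] == 0).all():
        snps["cM"] = np.nan

    # re-anchor to the cohort-wide minor allele so text and binary agree
    calls = calls_a1.copy()
    counted = bim["a1"].to_numpy(dtype=object)
    other = bim["a2"].to_numpy(dtype=object)
    typed = calls_a1 != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            typed.sum(axis=0) > 0,
            np.where(typed, calls_a1, 0).sum(axis=0) / (2.0 * np.maximum(typed.sum(axis=0), 1)),
            0.0,
        )
    flip = freq > 0.5
    calls[:, flip] = np.where(typed[:, flip], 2 - calls_a1[:, flip], MISSING)
    counted[flip], other[flip] = other[flip].copy(), counted[flip].copy()
    snps["allele_counted"] = counted
    snps["allele_other"] = other

    samples = pd.DataFrame({"id": fam["iid"], "breed": fam["fid"]})
    calls, snps = _canonical_snp_order(calls, snps)
    return Cohort(calls=calls, snps=snps, samples=samples)


_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)  # 2-bit code -> a1 dosage
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _unpack_bed(payload: np.ndarray, n: int, m: int) -> np.ndarray:
    bytes_per_snp = (n + 3) // 4
    mat = payload.reshape(m, bytes_per_snp)
    # little-endian within byte: individual k sits at bit pair 2*(k%4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (mat[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    return _BED_DECODE[codes].T.copy()  # (n, m)


def write_plink_binary(
    cohort: Cohort, bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> None:
    snps = cohort.snps
    counted = snps.get("allele_counted", pd.Series(["A"] * len(snps))).to_numpy(dtype=object)
    other = snps.get("allele_other", pd.Series(["B"] * len(snps))).to_numpy(dtype=object)
    other = np.where(other == "0", counted, other)
    cm = snps["cM"].fillna(0.0)
    with open(bim_path, "w") as fh:
        for chrom, sid, c, bp, a1, a2 in zip(
            snps["chrom"], snps["snp_id"], cm, snps["bp"], counted, other
        ):
            fh.write(f"{chrom}\t{sid}\t{c:g}\t{bp}\t{a1}\t{a2}\n")
    with open(fam_path, "w") as fh:
        for iid, breed in zip(cohort.samples["id"], cohort.samples["breed"]):
            fh.write(f"{breed} {iid} 0 0 0 -9\n")

    n, m = cohort.n_individuals, cohort.n_snps
    bytes_per_snp = (n + 3) // 4
    out = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    enc = np.full(256, _BED_ENCODE[MISSING], dtype=np.uint8)
    for dose, code in _BED_ENCODE.items():
        enc[np.int8(dose).view(np.uint8)] = code
    codes = enc[cohort.calls.T.astype(np.uint8)]  # (m, n)
    out[:, :n] = codes
    packed = (
        out.reshape(m, bytes_per_snp, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    ).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# -------------------------------------------------------------- linkage map
def attach_linkage_map(cohort: Cohort, linkage_map: pd.DataFrame) -> Cohort:
    """Attach genetic positions from a (snp_id, chrom, cM) table.

    SNPs named in the map get their exact cM; unnamed SNPs are linearly
    interpolated on bp between flanking mapped SNPs, and SNPs outside the
    mapped span take the terminal cM value (constant extrapolation).
    Chromosomes with fewer than two mapped SNPs keep cM absent.
    """
    lm = linkage_map.rename(columns=str.lower)
    for col in ("snp_id", "chrom", "cm"):
        if col not in lm.columns:
            raise CohortFormatError(f"linkage map lacks column {col!r}")
    exact = dict(zip(lm["snp_id"], lm["cm"].astype(float)))

    snps = cohort.snps.copy()
    cm_out = np.full(len(snps), np.nan)
    for chrom, sub in snps.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        bp = sub["bp"].to_numpy(dtype=float)
        mapped = np.array([exact.get(s, np.nan) for s in sub["snp_id"]])
        known = ~np.isnan(mapped)
        if known.sum() < 2:
            logger.warning(
                "chromosome %s: %d mapped SNP(s) in linkage map, cM left absent",
                chrom,
                int(known.sum()),
            )
            continue
        # np.interp extrapolates by clamping to terminal values
        cm_out[idx] = np.interp(bp, bp[known], mapped[known])
        cm_out[idx[known]] = mapped[known]
    snps["cM"] = cm_out
    return Cohort(
        calls=cohort.calls,
        snps=snps,
        samples=cohort.samples,
        pedigree=cohort.pedigree,
        n_autosomes=cohort.n_autosomes,
    )


def read_linkage_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------- pedigree
def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a delimited pedigree file with header ``id,sire,dam,breed``.

    Unknown parents (empty, ``0``, ``NA``) are normalized to a single
    sentinel; the result is validated acyclic and returned parents-first.
    """
    ped = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna(UNKNOWN_PARENT)
    ped.columns = [c.strip().lower() for c in ped.columns]
    return validate_pedigree(ped)


def write_pedigree(pedigree: pd.DataFrame, path: str | Path) -> None:
    pedigree.to_csv(path, index=False)
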