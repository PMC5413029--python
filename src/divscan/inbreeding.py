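"""Inbreeding coefficients and their comparison.

Four per-individual measures:

* ``F_ROH``: summed ROH length above a minimum-length threshold (1/5/10 Mb)
  divided by the autosomal length (the SNP-map span, or a fixed override
  such as 2.44 Gb for the ovine 50K panel).
* ``F_PED``: pedigree inbreeding via the Meuwissen & Luo algorithm — the
  diagonal of the numerator relationship matrix minus one, computed by
  tracing each animal's ancestor list.
* ``F_GRM``: VanRaden genomic-relationship diagonal minus one,
  ``sum_j (x_ij - 2 p_j)^2 / (2 sum_j p_j (1 - p_j)) - 1`` over typed SNPs.
* ``F_HOM``: excess homozygosity, ``(O - E) / (m - E)`` with ``E`` the
  Hardy-Weinberg expected homozygote count.

Pedigree depth is measured in complete generation equivalents (CGE), the
sum over known ancestor slots of ``(1/2)^generation``; the comparison report
(Pearson correlations, OLS regressions of each F_ROH on F_PED) is restricted
to animals with CGE at or above a cut-off (default 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, UNKNOWN_PARENT, Cohort, validate_pedigree

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------- F_ROH
def f_roh(
    segments: pd.DataFrame,
    individual_id: str,
    min_length_mb: float,
    autosome_length_bp: float,
) -> float:
    """Summed length of one individual's ROH >= ``min_length_mb``, as a
    fraction of the autosome length."""
    seg = segments[
        (segments["individual_id"] == individual_id)
        & (segments["length_mb"] >= min_length_mb)
    ]
    return float((seg["end_bp"] - seg["start_bp"] + 1).sum() / autosome_length_bp)


def f_roh_all(
    segments: pd.DataFrame,
    cohort: Cohort,
    thresholds_mb: tuple[float, ...] = (1.0, 5.0, 10.0),
    autosome_length_bp: float | None = None,
) -> pd.DataFrame:
    """F_ROH at each threshold for every individual (zero where no ROH)."""
    denom = float(autosome_length_bp or cohort.map_span_bp())
    if denom <= 0:
        raise ValueError("autosome length must be positive")
    out = pd.DataFrame({"individual_id": cohort.samples["id"].to_numpy()})
    lengths = segments["end_bp"] - segments["start_bp"] + 1
    for t in thresholds_mb:
        mask = segments["length_mb"] >= t
        sums = lengths[mask].groupby(segments.loc[mask, "individual_id"]).sum()
        out[f"f_roh_{t:g}mb"] = (
            out["individual_id"].map(sums).fillna(0.0).astype(float) / denom
        )
    return out


# ------------------------------------------------------------------- F_PED
def f_ped_meuwissen_luo(pedigree: pd.DataFrame) -> dict[str, float]:
    """Pedigree inbreeding coefficients by the Meuwissen & Luo algorithm.

    For each animal the L-coefficients of its ancestors are accumulated by
    tracing the pedigree upwards, and ``F_i = sum_j L_ij^2 D_j - 1`` where
    ``D_j`` is the within-family Mendelian-sampling variance.  Founders and
    unknown-parent slots have F = 0.
    """
    ped = validate_pedigree(pedigree)
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    f: dict[str, float] = {}

    def f_of(ind: str) -> float:
        return f.get(ind, 0.0)  # unknown / un-listed parents are founders

    order: dict[str, int] = {ind: i for i, ind in enumerate(ped["id"])}

    def d_of(ind: str) -> float:
        # Mendelian-sampling variance: 1, 0.75 or 0.5-ish by parents known
        s, d = sire.get(ind, UNKNOWN_PARENT), dam.get(ind, UNKNOWN_PARENT)
        if s == UNKNOWN_PARENT and d == UNKNOWN_PARENT:
            return 1.0
        if s == UNKNOWN_PARENT or d == UNKNOWN_PARENT:
            known = d if s == UNKNOWN_PARENT else s
            return 0.75 - 0.25 * f_of(known)
        return 0.5 - 0.25 * (f_of(s) + f_of(d))

    for ind in ped["id"]:
        s, d = sire[ind], dam[ind]
        if s == UNKNOWN_PARENT or d == UNKNOWN_PARENT:
            f[ind] = 0.0
            continue
        # accumulate L coefficients over the ancestor closure, youngest first
        coeff: dict[str, float] = {ind: 1.0}
        a_ii = 0.0
        while coeff:
            j = max(coeff, key=lambda k: order.get(k, -1))
            lj = coeff.pop(j)
            a_ii += lj * lj * d_of(j)
            for par in (sire.get(j, UNKNOWN_PARENT), dam.get(j, UNKNOWN_PARENT)):
                if par != UNKNOWN_PARENT:
                    coeff[par] = coeff.get(par, 0.0) + 0.5 * lj
        f[ind] = a_ii - 1.0
    return {ind: f[ind] for ind in ped["id"]}


def complete_generation_equivalents(pedigree: pd.DataFrame) -> dict[str, float]:
    """CGE per individual: sum over known ancestor slots of (1/2)^g.

    Both parents known contributes 1; two complete generations contribute 2.
    Repeated ancestors count once per pedigree slot.
    """
    ped = validate_pedigree(pedigree)
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    contrib: dict[str, float] = {}

    for ind in ped["id"]:  # parents-first order: memo is complete
        total = 0.0
        for par in (sire[ind], dam[ind]):
            if par != UNKNOWN_PARENT:
                total += 0.5 * (1.0 + contrib.get(par, 0.0))
        contrib[ind] = total
    return {ind: contrib[ind] for ind in ped["id"]}


# ------------------------------------------------------------ genomic F's
def f_grm_vanraden(cohort: Cohort, rows: np.ndarray | None = None) -> dict[str, float]:
    """VanRaden genomic inbreeding F = G_ii - 1.

    Allele frequencies come from the analyzed set (all rows, or the given
    subset, e.g. one breed).  Per individual the sums run over its typed
    SNPs only; SNPs fixed in the analyzed set are excluded.
    """
    sub = cohort if rows is None else cohort.subset(individuals=rows)
    p = sub.allele_frequencies()
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    calls = sub.calls[:, usable]
    pj = p[usable]
    var = 2.0 * pj * (1.0 - pj)
    typed = calls != MISSING
    dev2 = np.where(typed, (np.where(typed, calls, 0) - 2.0 * pj) ** 2, 0.0)
    num = dev2.sum(axis=1)
    den = (typed * var).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_ii = np.where(den > 0, num / den, np.nan)
    return dict(zip(sub.samples["id"], g_ii - 1.0))


def f_hom(cohort: Cohort, rows: np.ndarray | None = None) -> dict[str, float]:
    """Excess-homozygosity inbreeding F = (O - E) / (m - E) per individual,
    with E the HWE-expected homozygote count over that individual's typed
    SNPs.  NaN (flagged) when every typed SNP is fixed (m = E)."""
    sub = cohort if rows is None else cohort.subset(individuals=rows)
    p = sub.allele_frequencies()
    usable = ~np.isnan(p)
    calls = sub.calls[:, usable]
    pj = p[usable]
    e_hom_j = 1.0 - 2.0 * pj * (1.0 - pj)
    typed = calls != MISSING
    obs = ((calls == 0) | (calls == 2)).sum(axis=1, dtype=float)
    exp = (typed * e_hom_j).sum(axis=1)
    m = typed.sum(axis=1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(m - exp) > 1e-12, (obs - exp) / (m - exp), np.nan)
    n_flagged = int(np.isnan(out).sum())
    if n_flagged:
        logger.warning("f_hom: %d individual(s) undefined (all typed SNPs fixed)", n_flagged)
    return dict(zip(sub.samples["id"], out))


# ------------------------------------------------------------------ report
@dataclass
class InbreedingTables:
    records: pd.DataFrame          # one row per individual, all coefficients
    correlations: pd.DataFrame     # Pearson r + p per coefficient pair, per scope
    regressions: pd.DataFrame      # OLS of each F_ROH measure on F_PED


MEASURES = ["f_roh_1mb", "f_roh_5mb", "f_roh_10mb", "f_ped", "f_grm", "f_hom"]


def inbreeding_records(
    cohort: Cohort,
    segments: pd.DataFrame,
    pedigree: pd.DataFrame | None = None,
    autosome_length_bp: float | None = None,
    frequency_scope: str = "pooled",
) -> pd.DataFrame:
    """Assemble all coefficients (and CGE where a pedigree is given) into one
    per-individual table.  ``frequency_scope`` chooses pooled vs per-breed
    allele frequencies for F_GRM/F_HOM."""
    rec = f_roh_all(segments, cohort, autosome_length_bp=autosome_length_bp)
    rec["breed"] = cohort.samples["breed"].to_numpy()

    if frequency_scope == "pooled":
        grm = f_grm_vanraden(cohort)
        hom = f_hom(cohort)
    elif frequency_scope == "per_breed":
        grm, hom = {}, {}
        for breed, rows in cohort.breed_index.items():
            grm.update(f_grm_vanraden(cohort, rows))
            hom.update(f_hom(cohort, rows))
    else:
        raise ValueError("frequency_scope must be 'pooled' or 'per_breed'")
    rec["f_grm"] = rec["individual_id"].map(grm)
    rec["f_hom"] = rec["individual_id"].map(hom)

    if pedigree is not None:
        fped = f_ped_meuwissen_luo(pedigree)
        cge = complete_generation_equivalents(pedigree)
        rec["f_ped"] = rec["individual_id"].map(fped)
        rec["cge"] = rec["individual_id"].map(cge)
    else:
        rec["f_ped"] = np.nan
        rec["cge"] = np.nan
    return rec


def inbreeding_report(records: pd.DataFrame, min_cge: float = 6.0) -> InbreedingTables:
    """Pearson correlations among all measures and OLS regressions of each
    F_ROH measure on F_PED, restricted to individuals with CGE >= min_cge
    (pooled and within breed)."""
    eligible = records[records["cge"] >= min_cge] if records["cge"].notna().any() else records
    if len(eligible) < 3:
        raise ValueError(f"need >=3 individuals with CGE >= {min_cge}, have {len(eligible)}")

    scopes: list[tuple[str, pd.DataFrame]] = [("pooled", eligible)]
    scopes += [(b, g) for b, g in eligible.groupby("breed") if len(g) >= 3]

    corr_rows, reg_rows = [], []
    measures = [m for m in MEASURES if m in records.columns]
    for scope, grp in scopes:
        for i, m1 in enumerate(measures):
            for m2 in measures[i + 1:]:
                x, y = grp[m1].to_numpy(float), grp[m2].to_numpy(float)
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                    r = p = np.nan  # zero variance or too few: undefined
                else:
                    r, p = stats.pearsonr(x[ok], y[ok])
                corr_rows.append(
                    {"scope": scope, "measure_1": m1, "measure_2": m2,
                     "n": int(ok.sum()), "pearson_r": r, "p_value": p}
                )
        if "f_ped" in grp:
            for m in ("f_roh_1mb", "f_roh_5mb", "f_roh_10mb"):
                x, y = grp["f_ped"].to_numpy(float), grp[m].to_numpy(float)
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3 or x[ok].std() == 0:
                    slope = intercept = np.nan
                else:
                    res = stats.linregress(x[ok], y[ok])
                    slope, intercept = res.slope, res.intercept
                reg_rows.append(
                    {"scope": scope, "response": m, "predictor": "f_ped",
                     "n": int(ok.sum()), "slope": slope, "intercept": intercept}
                )
    return InbreedingTables(
        records=records,
        correlations=pd.DataFrame(corr_rows),
        regressions=pd.DataFrame(reg_rows),
    )
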