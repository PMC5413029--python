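"""End-to-end orchestration: qc -> roh -> inbreeding -> fst -> ne.

A :class:`RunConfig` (YAML-serializable) carries the input paths and every
stage's parameter block; :func:`run_pipeline` executes the stages in
dependency order, writes one TSV per output table under the run directory
(``qc/``, ``roh/``, ``inbreeding/``, ``fst/``, ``ne/``, ``report/``) and
records a manifest — on success or failure — with row counts per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort
from .io import attach_linkage_map, read_linkage_map, read_pedigree, read_plink_binary, read_plink_text
from .ne import NeParams, ne_trajectory
from .qc import QcParams, ld_prune, run_qc_chain
from .roh import (
    RohScanParams,
    call_hotspots,
    chromosome_roh_fraction,
    recombination_windows,
    scan_roh,
    snp_roh_incidence,
    summarize_length_classes,
    tmrca_bins,
)
from .fst import call_signatures, correlate_snp_stat_with_incidence, mean_genomic_fst, wc_theta, window_average
from .inbreeding import inbreeding_records, inbreeding_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    ped_path: str | None = None
    map_path: str | None = None
    bed_path: str | None = None
    bim_path: str | None = None
    fam_path: str | None = None
    pedigree_path: str | None = None
    linkage_map_path: str | None = None
    out_dir: str = "divscan_run"
    seed: int = 0
    log_level: str = "INFO"
    apply_ld_prune: bool = False
    autosome_length_bp: float | None = None
    min_cge: float = 6.0
    fst_top_call: float = 0.001
    fst_top_extend: float = 0.05
    fst_window_snps: int = 5
    hotspot_top_fraction: float = 0.01
    qc: QcParams = field(default_factory=QcParams)
    roh: RohScanParams = field(default_factory=RohScanParams)
    ne: NeParams = field(default_factory=NeParams)

    # ------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, typ in (("qc", QcParams), ("roh", RohScanParams), ("ne", NeParams)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _write(df: pd.DataFrame, path: Path) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return len(df)


def load_cohort(config: RunConfig) -> Cohort:
    if config.ped_path and config.map_path:
        cohort = read_plink_text(config.ped_path, config.map_path)
    elif config.bed_path and config.bim_path and config.fam_path:
        cohort = read_plink_binary(config.bed_path, config.bim_path, config.fam_path)
    else:
        raise ValueError("config must name either PED/MAP or BED/BIM/FAM inputs")
    if config.linkage_map_path:
        cohort = attach_linkage_map(cohort, read_linkage_map(config.linkage_map_path))
    if config.pedigree_path:
        cohort.pedigree = read_pedigree(config.pedigree_path)
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to
    ``<out_dir>/manifest.json``)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "status": "running",
    }
    t0 = time.time()
    try:
        _run_stages(config, out, manifest)
        manifest["status"] = "ok"
    except Exception as exc:  # manifest must record the failure point
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["traceback"] = traceback.format_exc()
        raise
    finally:
        manifest["wall_time_s"] = round(time.time() - t0, 2)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    cohort = load_cohort(config)
    manifest["stages"]["input"] = {
        "individuals": cohort.n_individuals,
        "snps": cohort.n_snps,
    }

    cohort, qc_report = run_qc_chain(cohort, config.qc)
    if config.apply_ld_prune:
        cohort = ld_prune(cohort, config.qc)
    _write(qc_report.to_frame(), out / "qc" / "qc_report.tsv")
    manifest["stages"]["qc"] = {
        "individuals": cohort.n_individuals,
        "snps": cohort.n_snps,
    }

    segments = scan_roh(cohort, config.roh)
    _write(segments, out / "roh" / "segments.tsv")
    classes = summarize_length_classes(segments, cohort)
    _write(classes, out / "roh" / "length_classes.tsv")
    incidence = snp_roh_incidence(segments, cohort)
    inc_tbl = cohort.snps[["snp_id", "chrom", "bp"]].copy()
    inc_tbl["incidence"] = incidence
    for breed in cohort.breeds:
        inc_tbl[f"incidence_{breed}"] = snp_roh_incidence(segments, cohort, breed)
    _write(inc_tbl, out / "roh" / "incidence.tsv")
    hotspots = call_hotspots(incidence, cohort, config.hotspot_top_fraction)
    _write(hotspots, out / "roh" / "hotspots.tsv")
    _write_bed(hotspots, out / "roh" / "hotspots.bed")
    _write(chromosome_roh_fraction(segments, cohort), out / "roh" / "chromosome_fraction.tsv")
    tmrca = tmrca_bins(segments, cohort) if segments["genetic_length_cM"].notna().any() else pd.DataFrame()
    _write(tmrca, out / "roh" / "tmrca_bins.tsv")
    if cohort.snps["cM"].notna().any():
        _write(recombination_windows(cohort), out / "roh" / "recombination_windows.tsv")
    manifest["stages"]["roh"] = {"segments": len(segments), "hotspots": len(hotspots)}

    records = inbreeding_records(
        cohort, segments, cohort.pedigree, autosome_length_bp=config.autosome_length_bp
    )
    _write(records, out / "inbreeding" / "records.tsv")
    if cohort.pedigree is not None and (records["cge"] >= config.min_cge).sum() >= 3:
        tables = inbreeding_report(records, config.min_cge)
        _write(tables.correlations, out / "inbreeding" / "correlations.tsv")
        _write(tables.regressions, out / "inbreeding" / "regressions.tsv")
        manifest["stages"]["inbreeding"] = {"records": len(records)}
    else:
        manifest["stages"]["inbreeding"] = {
            "records": len(records),
            "note": "pedigree absent or too shallow: correlation report skipped",
        }

    if len(cohort.breeds) >= 2:
        fst_records = window_average(wc_theta(cohort), config.fst_window_snps)
        _write(fst_records, out / "fst" / "per_snp.tsv")
        signatures = call_signatures(fst_records, config.fst_top_call, config.fst_top_extend)
        _write(signatures, out / "fst" / "signatures.tsv")
        _write_bed(signatures, out / "fst" / "signatures.bed")
        stage = {
            "mean_genomic_fst": mean_genomic_fst(fst_records),
            "signatures": len(signatures),
        }
        try:
            r, p = correlate_snp_stat_with_incidence(fst_records, incidence)
            stage["incidence_fst_r"] = r
            stage["incidence_fst_p"] = p
        except ValueError as exc:
            stage["incidence_fst_note"] = str(exc)
        manifest["stages"]["fst"] = stage
    else:
        manifest["stages"]["fst"] = {"note": "single breed: F_ST skipped"}
        fst_records = None
        signatures = None

    ne_tables = {}
    for breed in cohort.breeds:
        traj = ne_trajectory(cohort, breed, config.ne)
        ne_tables[breed] = traj
        _write(traj, out / "ne" / f"trajectory_{breed}.tsv")
    manifest["stages"]["ne"] = {b: len(t) for b, t in ne_tables.items()}

    report = make_report(
        length_classes=classes,
        inbreeding_correlations=(
            tables.correlations
            if "tables" in locals() and cohort.pedigree is not None
            else None
        ),
        hotspots=hotspots,
        signatures=signatures,
        ne_tables=ne_tables,
    )
    (out / "report").mkdir(parents=True, exist_ok=True)
    (out / "report" / "summary.md").write_text(report)


def _write_bed(regions: pd.DataFrame | None, path: Path) -> None:
    """Half-open 0-based export of closed 1-based regions."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if regions is not None:
            for row in regions.itertuples():
                fh.write(f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\n")


def make_report(
    length_classes: pd.DataFrame | None = None,
    inbreeding_correlations: pd.DataFrame | None = None,
    hotspots: pd.DataFrame | None = None,
    signatures: pd.DataFrame | None = None,
    ne_tables: dict[str, pd.DataFrame] | None = None,
) -> str:
    """Assemble the five summary tables into one markdown document; missing
    sections get a placeholder."""
    parts = ["# divscan run summary\n"]

    def section(title: str, df: pd.DataFrame | None) -> None:
        parts.append(f"\n## {title}\n")
        if df is None:
            parts.append("_not available for this run_\n")
        elif len(df) == 0:
            parts.append("(no rows)\n")
        else:
            parts.append("```\n" + df.round(4).to_string(index=False) + "\n```\n")

    section("ROH length classes (mean sum per animal, Mb)", length_classes)
    section("Inbreeding coefficient correlations", inbreeding_correlations)
    section("ROH hotspots", hotspots)
    section("Selection signatures (windowed F_ST)", signatures)
    if ne_tables:
        for breed, t in ne_tables.items():
            section(f"Effective population size: {breed}", t)
    else:
        section("Effective population size", None)
    return "".join(parts)
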