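import math

import numpy as np
import pandas as pd
import pytest

import divscan as ds
from divscan.cohort import MISSING
from divscan.roh import (
    RohScanParams,
    call_hotspots,
    chromosome_roh_fraction,
    lencz_min_snps,
    recombination_windows,
    snp_roh_incidence,
    summarize_length_classes,
    tmrca_bin_label,
    tmrca_bins,
)


def _cohort(calls, spacing_bp=50_000, cm_per_mb=1.0, breeds=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    bp = np.arange(m) * spacing_bp + 1
    snps = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chrom": 1, "bp": bp,
         "cM": bp / 1e6 * cm_per_mb}
    )
    samples = pd.DataFrame(
        {"id": [f"i{k}" for k in range(n)],
         "breed": breeds if breeds is not None else ["X"] * n}
    )
    return ds.Cohort(calls=calls, snps=snps, samples=samples)


class TestLencz:
    def test_panel_scale_value(self):
        # ceil(ln(0.05 / (42,182 * 3,191)) / ln(0.65)) = 51
        assert lencz_min_snps(42_182, 3_191, 0.05, 0.35) == 51

    def test_monotone_decreasing_in_heterozygosity(self):
        values = [lencz_min_snps(40_000, 3_000, 0.05, h) for h in (0.1, 0.3, 0.5, 0.9)]
        assert values == sorted(values, reverse=True)

    def test_monotone_in_alpha(self):
        assert lencz_min_snps(40_000, 3_000, 1.0, 0.35) <= lencz_min_snps(
            40_000, 3_000, 0.05, 0.35
        )

    def test_degenerate_heterozygosity_raises(self):
        with pytest.raises(ValueError):
            lencz_min_snps(1000, 10, 0.05, 0.0)


class TestScan:
    def test_fully_homozygous_chromosome_is_one_segment(self):
        calls = np.zeros((1, 60), dtype=np.int8)
        seg = ds.scan_roh(_cohort(calls), RohScanParams(min_snps=30))
        assert len(seg) == 1
        row = seg.iloc[0]
        assert row["n_snps"] == 60
        assert (row["start_bp"], row["end_bp"]) == (1, 59 * 50_000 + 1)

    def test_regular_heterozygotes_abolish_all_windows(self):
        calls = np.zeros((1, 60), dtype=np.int8)
        calls[0, ::10] = 1  # one het every 10 SNPs: >=5 per 50-SNP window
        seg = ds.scan_roh(_cohort(calls), RohScanParams(min_snps=30))
        assert len(seg) == 0

    def test_large_gap_splits_run(self):
        calls = np.zeros((1, 120), dtype=np.int8)
        cohort = _cohort(calls)
        snps = cohort.snps.copy()
        snps.loc[60:, "bp"] += 2_000_000  # 2-Mb hole in the middle
        snps.loc[60:, "cM"] += 2.0
        cohort = ds.Cohort(calls=calls, snps=snps, samples=cohort.samples)
        seg = ds.scan_roh(cohort, RohScanParams(min_snps=30))
        assert len(seg) == 2

    def test_min_length_monotonicity(self, genedrop_cohort):
        cohort, _, _ = genedrop_cohort
        counts = [
            len(ds.scan_roh(cohort, RohScanParams(min_length_mb=t)))
            for t in (1.0, 2.0, 5.0, 10.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_emitted_segments_satisfy_invariants(self, genedrop_cohort):
        cohort, _, _ = genedrop_cohort
        params = RohScanParams()
        seg = ds.scan_roh(cohort, params)
        assert len(seg) > 0
        assert (seg["end_bp"] >= seg["start_bp"]).all()
        assert (seg["length_mb"] >= params.min_length_mb).all()
        density_kb = (seg["end_bp"] - seg["start_bp"] + 1) / 1e3 / seg["n_snps"]
        assert (density_kb <= params.min_density_kb_per_snp).all()

    def test_short_chromosome_skipped_with_warning(self, caplog):
        calls = np.zeros((1, 10), dtype=np.int8)
        with caplog.at_level("WARNING"):
            seg = ds.scan_roh(_cohort(calls), RohScanParams(min_snps=5))
        assert len(seg) == 0
        assert "skipped" in caplog.text


class TestSummaries:
    def _segments(self, rows):
        return pd.DataFrame(
            rows,
            columns=["individual_id", "breed", "chrom", "start_bp", "end_bp",
                     "n_snps", "length_mb", "genetic_length_cM"],
        )

    def test_length_class_mean_over_all_animals(self):
        cohort = _cohort(np.zeros((2, 10), dtype=np.int8))
        seg = self._segments([("i0", "X", 1, 1, 3_000_000, 50, 3.0, 3.0)])
        tbl = summarize_length_classes(seg, cohort)
        first = tbl[tbl["length_class_mb"] == "[1,5)"]
        assert first["mean_sum_mb"].item() == pytest.approx(1.5)

    def test_boundary_segment_of_5mb_falls_in_5_10(self):
        cohort = _cohort(np.zeros((1, 10), dtype=np.int8))
        seg = self._segments([("i0", "X", 1, 1, 5_000_000, 60, 5.0, 5.0)])
        tbl = summarize_length_classes(seg, cohort)
        assert tbl.loc[tbl["length_class_mb"] == "[5,10)", "mean_sum_mb"].item() == 5.0
        assert tbl.loc[tbl["length_class_mb"] == "[1,5)", "mean_sum_mb"].item() == 0.0

    def test_no_segments_gives_zero_table(self):
        cohort = _cohort(np.zeros((3, 10), dtype=np.int8))
        tbl = summarize_length_classes(self._segments([]), cohort)
        assert (tbl["mean_sum_mb"] == 0).all()

    def test_incidence_fractions(self):
        cohort = _cohort(np.zeros((10, 20), dtype=np.int8))
        seg = self._segments(
            [(f"i{k}", "X", 1, 1, 100_001, 3, 0.1, 0.1) for k in range(3)]
        )
        inc = snp_roh_incidence(seg, cohort)
        assert inc[0] == pytest.approx(0.3)   # covered in 3 of 10
        assert inc[-1] == 0.0

    def test_incidence_invariant_to_individual_order(self, genedrop_cohort):
        cohort, _, _ = genedrop_cohort
        seg = ds.scan_roh(cohort)
        perm = np.random.default_rng(0).permutation(cohort.n_individuals)
        shuffled = cohort.subset(individuals=perm)
        np.testing.assert_allclose(
            snp_roh_incidence(seg, cohort), snp_roh_incidence(seg, shuffled)
        )

    def test_chromosome_fraction_full_and_empty(self):
        cohort = _cohort(np.zeros((2, 11), dtype=np.int8))
        span = 10 * 50_000
        seg = self._segments(
            [("i0", "X", 1, 1, span + 1, 11, span / 1e6, 0.5),
             ("i1", "X", 1, 1, span + 1, 11, span / 1e6, 0.5)]
        )
        tbl = chromosome_roh_fraction(seg, cohort)
        assert tbl["roh_fraction"].item() == pytest.approx(1.0, rel=1e-4)
        empty = chromosome_roh_fraction(self._segments([]), cohort)
        assert empty["roh_fraction"].item() == 0.0


class TestHotspots:
    def test_contiguous_top_snps_merge(self):
        cohort = _cohort(np.zeros((1, 1000), dtype=np.int8))
        inc = np.full(1000, 0.1)
        inc[100:110] = 0.9
        hs = call_hotspots(inc, cohort, top_fraction=0.01)
        assert len(hs) == 1
        assert hs["n_snps"].item() == 10

    def test_alternating_top_snps_stay_singletons(self):
        cohort = _cohort(np.zeros((1, 1000), dtype=np.int8))
        inc = np.full(1000, 0.1)
        inc[100:110:2] = 0.9  # 5 selected SNPs, none adjacent
        hs = call_hotspots(inc, cohort, top_fraction=0.005)
        assert len(hs) == 5
        assert (hs["n_snps"] == 1).all()

    def test_zero_incidence_yields_no_hotspots(self):
        cohort = _cohort(np.zeros((1, 100), dtype=np.int8))
        assert len(call_hotspots(np.zeros(100), cohort)) == 0


class TestTmrca:
    @pytest.mark.parametrize(
        "cm,label",
        [(12.0, "<=5 generations"), (10.0, "<=5 generations"),
         (7.0, "5-10 generations"), (4.0, "10-20 generations"),
         (2.5, "10-20 generations"), (1.0, ">20 generations")],
    )
    def test_bin_edges_from_map_length_formula(self, cm, label):
        # l = 100/(2g) cM puts the g = 5, 10, 20 edges at 10, 5, 2.5 cM
        assert tmrca_bin_label(cm) == label

    def test_mean_sum_per_breed(self):
        cohort = _cohort(np.zeros((2, 10), dtype=np.int8))
        seg = pd.DataFrame(
            [("i0", "X", 1, 1, 100, 5, 0.1, 12.0), ("i0", "X", 1, 200, 300, 5, 0.1, 4.0)],
            columns=["individual_id", "breed", "chrom", "start_bp", "end_bp",
                     "n_snps", "length_mb", "genetic_length_cM"],
        )
        tbl = tmrca_bins(seg, cohort)
        assert tbl.loc[tbl["tmrca_bin"] == "<=5 generations", "mean_sum_cM"].item() == 6.0
        assert tbl.loc[tbl["tmrca_bin"] == "10-20 generations", "mean_sum_cM"].item() == 2.0


class TestRecombinationWindows:
    def test_uniform_map_rate_is_one(self):
        cohort = _cohort(np.zeros((1, 100), dtype=np.int8), cm_per_mb=1.0)
        tbl = recombination_windows(cohort, window_kb=500)
        assert tbl["cM_per_Mb"].dropna().to_numpy() == pytest.approx(1.0)

    def test_plateau_rate_is_zero(self):
        cohort = _cohort(np.zeros((1, 100), dtype=np.int8))
        snps = cohort.snps.copy()
        snps["cM"] = 5.0  # flat genetic map
        cohort = ds.Cohort(calls=cohort.calls, snps=snps, samples=cohort.samples)
        tbl = recombination_windows(cohort, window_kb=500)
        assert tbl["cM_per_Mb"].dropna().to_numpy() == pytest.approx(0.0)

    def test_single_snp_tile_is_absent(self):
        calls = np.zeros((1, 3), dtype=np.int8)
        snps = pd.DataFrame(
            {"snp_id": ["a", "b", "c"], "chrom": 1,
             "bp": [100, 200, 600_000], "cM": [0.0, 0.1, 0.6]}
        )
        cohort = ds.Cohort(calls=calls, snps=snps,
                           samples=pd.DataFrame({"id": ["i0"], "breed": ["X"]}))
        tbl = recombination_windows(cohort, window_kb=500)
        assert np.isnan(tbl.loc[tbl["tile_start_bp"] == 500_001, "cM_per_Mb"].item())
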