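import numpy as np
import pandas as pd
import pytest

import divscan as ds
from divscan.cohort import UNKNOWN_PARENT
from divscan.inbreeding import (
    complete_generation_equivalents,
    f_grm_vanraden,
    f_hom,
    f_ped_meuwissen_luo,
    f_roh_all,
    inbreeding_records,
    inbreeding_report,
)
from oracles import kinship_tabular, random_pedigree


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "breed"]).assign(breed="X")


def _hwe_cohort(n=500, m=400, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=m)
    calls = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    snps = pd.DataFrame(
        {"snp_id": [f"s{j}" for j in range(m)], "chrom": 1,
         "bp": np.arange(1, m + 1) * 1000, "cM": np.nan}
    )
    samples = pd.DataFrame({"id": [f"i{k}" for k in range(n)], "breed": "X"})
    return ds.Cohort(calls=calls, snps=snps, samples=samples)


class TestFroh:
    def test_no_segments_is_zero_and_fixed_denominator(self):
        cohort = _hwe_cohort(n=2, m=10)
        seg = pd.DataFrame(
            [("i0", "X", 1, 1, 244_000_000, 100, 244.0, np.nan)],
            columns=["individual_id", "breed", "chrom", "start_bp", "end_bp",
                     "n_snps", "length_mb", "genetic_length_cM"],
        )
        tbl = f_roh_all(seg, cohort, autosome_length_bp=2.44e9)
        assert tbl.loc[tbl["individual_id"] == "i0", "f_roh_1mb"].item() == pytest.approx(0.1)
        assert tbl.loc[tbl["individual_id"] == "i1", "f_roh_1mb"].item() == 0.0

    def test_threshold_monotonicity(self, genedrop_cohort):
        cohort, _, _ = genedrop_cohort
        seg = ds.scan_roh(cohort)
        tbl = f_roh_all(seg, cohort)
        assert (tbl["f_roh_10mb"] <= tbl["f_roh_5mb"] + 1e-12).all()
        assert (tbl["f_roh_5mb"] <= tbl["f_roh_1mb"] + 1e-12).all()
        assert (tbl["f_roh_1mb"] <= 1.0).all()


class TestFped:
    def test_offspring_of_unrelated_founders_is_zero(self):
        ped = _ped([("A", "0", "0", ""), ("B", "0", "0", ""), ("C", "A", "B", "")])
        assert f_ped_meuwissen_luo(ped)["C"] == 0.0

    def test_full_sib_offspring_quarter(self):
        ped = _ped(
            [("A", "0", "0", ""), ("B", "0", "0", ""),
             ("S1", "A", "B", ""), ("S2", "A", "B", ""), ("X", "S1", "S2", "")]
        )
        assert f_ped_meuwissen_luo(ped)["X"] == pytest.approx(0.25)

    def test_half_sib_offspring_eighth(self):
        ped = _ped(
            [("A", "0", "0", ""), ("B", "0", "0", ""), ("C", "0", "0", ""),
             ("H1", "A", "B", ""), ("H2", "A", "C", ""), ("X", "H1", "H2", "")]
        )
        assert f_ped_meuwissen_luo(ped)["X"] == pytest.approx(0.125)

    def test_matches_tabular_kinship_on_random_pedigrees(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            ped = random_pedigree(rng, int(rng.integers(5, 50)))
            got = f_ped_meuwissen_luo(ped)
            want = kinship_tabular(ped)
            for ind in want:
                assert got[ind] == pytest.approx(want[ind], abs=1e-12), ind

    def test_cycle_raises(self):
        ped = _ped([("A", "B", "0", ""), ("B", "A", "0", "")])
        with pytest.raises(Exception, match="cycle"):
            f_ped_meuwissen_luo(ped)


class TestCge:
    def test_known_parent_slots(self):
        ped = _ped(
            [("A", "0", "0", ""), ("B", "0", "0", ""), ("C", "0", "0", ""),
             ("D", "0", "0", ""),
             ("S", "A", "B", ""), ("E", "C", "D", ""),
             ("X", "S", "E", ""),       # two complete generations
             ("Y", "S", "0", "")]       # one parent known only
        )
        cge = complete_generation_equivalents(ped)
        assert cge["S"] == 1.0
        assert cge["X"] == 2.0
        assert cge["Y"] == pytest.approx(0.5 * (1 + 1.0))  # parent + its parents

    def test_single_parent_half(self):
        ped = _ped([("A", "0", "0", ""), ("Y", "A", "0", "")])
        assert complete_generation_equivalents(ped)["Y"] == 0.5


class TestGenomicF:
    def test_hwe_population_means_near_zero(self):
        cohort = _hwe_cohort()
        grm = np.array(list(f_grm_vanraden(cohort).values()))
        hom = np.array(list(f_hom(cohort).values()))
        for values in (grm, hom):
            se = values.std(ddof=1) / np.sqrt(values.size)
            assert abs(values.mean()) < 3 * se + 1e-3

    def test_rare_allele_homozygote_is_positive(self):
        rng = np.random.default_rng(1)
        calls = rng.binomial(2, 0.1, size=(100, 200)).astype(np.int8)
        calls[0] = 2  # homozygous for the rare allele everywhere
        cohort = _hwe_cohort(n=1, m=1)
        snps = pd.DataFrame(
            {"snp_id": [f"s{j}" for j in range(200)], "chrom": 1,
             "bp": np.arange(1, 201) * 1000, "cM": np.nan}
        )
        samples = pd.DataFrame({"id": [f"i{k}" for k in range(100)], "breed": "X"})
        cohort = ds.Cohort(calls=calls, snps=snps, samples=samples)
        assert f_grm_vanraden(cohort)["i0"] > 0
        assert f_hom(cohort)["i0"] == pytest.approx(1.0)

    def test_duplicate_individual_identical_value(self):
        cohort = _hwe_cohort(n=50, m=100, seed=3)
        calls = cohort.calls.copy()
        calls[1] = calls[0]
        dup = ds.Cohort(calls=calls, snps=cohort.snps, samples=cohort.samples)
        grm = f_grm_vanraden(dup)
        assert grm["i0"] == grm["i1"]

    def test_f_hom_zero_when_observed_equals_expected(self):
        # circulant of (0,2,1,1): every column has p = 0.5 (E = 2 homozygotes
        # per individual over 4 SNPs) and every row observes exactly 2
        base = [0, 2, 1, 1]
        calls = np.array([base[-k:] + base[:-k] for k in range(4)], dtype=np.int8)
        snps = pd.DataFrame({"snp_id": list("abcd"), "chrom": 1,
                             "bp": [1, 2, 3, 4], "cM": np.nan})
        samples = pd.DataFrame({"id": [f"i{k}" for k in range(4)], "breed": "X"})
        cohort = ds.Cohort(calls=calls, snps=snps, samples=samples)
        hom = f_hom(cohort)
        assert all(v == pytest.approx(0.0) for v in hom.values())


class TestReport:
    def test_identical_columns_give_perfect_fit(self, genedrop_cohort):
        cohort, _, ped = genedrop_cohort
        seg = ds.scan_roh(cohort)
        rec = inbreeding_records(cohort, seg, ped)
        rec["cge"] = 10.0
        rec["f_ped"] = rec["f_roh_1mb"]  # duplicated column
        tables = inbreeding_report(rec, min_cge=6.0)
        pooled = tables.correlations.query(
            "scope == 'pooled' and measure_1 == 'f_roh_1mb' and measure_2 == 'f_ped'"
        )
        assert pooled["pearson_r"].item() == pytest.approx(1.0)
        reg = tables.regressions.query("scope == 'pooled' and response == 'f_roh_1mb'")
        assert reg["slope"].item() == pytest.approx(1.0)
        assert reg["intercept"].item() == pytest.approx(0.0, abs=1e-12)

    def test_independent_columns_near_zero_r(self):
        rng = np.random.default_rng(9)
        rec = pd.DataFrame(
            {"individual_id": [f"i{k}" for k in range(400)],
             "breed": "X",
             "f_roh_1mb": rng.random(400), "f_roh_5mb": rng.random(400),
             "f_roh_10mb": rng.random(400), "f_ped": rng.random(400),
             "f_grm": rng.random(400), "f_hom": rng.random(400),
             "cge": 10.0}
        )
        tables = inbreeding_report(rec)
        pooled = tables.correlations.query(
            "scope == 'pooled' and measure_1 == 'f_roh_1mb' and measure_2 == 'f_ped'"
        )
        assert abs(pooled["pearson_r"].item()) < 0.15

    def test_too_few_eligible_raises(self):
        rec = pd.DataFrame(
            {"individual_id": ["a", "b"], "breed": "X", "f_roh_1mb": [0.1, 0.2],
             "f_roh_5mb": [0.1, 0.2], "f_roh_10mb": [0.0, 0.1],
             "f_ped": [0.1, 0.2], "f_grm": [0.1, 0.2], "f_hom": [0.1, 0.2],
             "cge": [7.0, 7.0]}
        )
        with pytest.raises(ValueError):
            inbreeding_report(rec)


def test_estimators_track_true_autozygosity(genedrop_cohort):
    """Each genomic estimator correlates better with the gene-drop truth
    than with independent noise."""
    cohort, truth, ped = genedrop_cohort
    auto = truth.attrs["autozygosity"]
    ids = cohort.samples["id"]
    y = np.array([auto[i] for i in ids])
    seg = ds.scan_roh(cohort)
    rec = inbreeding_records(cohort, seg, ped)
    noise = np.random.default_rng(4).random(len(ids))
    for col in ("f_roh_1mb", "f_grm", "f_hom"):
        x = rec[col].to_numpy(float)
        r_true = np.corrcoef(x, y)[0, 1]
        r_noise = np.corrcoef(x, noise)[0, 1]
        assert r_true > abs(r_noise), col
    assert np.corrcoef(rec["f_roh_1mb"], y)[0, 1] > 0.8
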