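"""SBS1 counting, the subsampled age regression and the rate comparison."""

import numpy as np
import pandas as pd
import pytest

from metprime import clocklike
from metprime.config import Config
from metprime.simulate import simulate_clock_points


def sbs_record(context, ref="C", alt="T", likelihood=0.1, variant_class="SBS"):
    return {"sample_id": "S", "chrom": "1", "pos": 1, "ref": ref, "alt": alt,
            "variant_class": variant_class, "context": context,
            "subclonal_likelihood": likelihood}


class TestSbs1Counting:
    def test_ncg_contexts_counted(self):
        muts = pd.DataFrame([sbs_record("ACG"), sbs_record("CCG"),
                             sbs_record("GCG")])
        assert clocklike.count_sbs1(muts, "breast") == 3

    def test_tcg_always_excluded(self):
        muts = pd.DataFrame([sbs_record("TCG")])
        assert clocklike.count_sbs1(muts, "breast") == 0

    def test_melanoma_additionally_excludes_ccg(self):
        muts = pd.DataFrame([sbs_record("CCG")])
        assert clocklike.count_sbs1(muts, "skin melanoma") == 0
        assert clocklike.count_sbs1(muts, "breast") == 1

    def test_non_ct_substitutions_ignored(self):
        muts = pd.DataFrame([sbs_record("ACG", alt="G"),
                             sbs_record("ACG", variant_class="ID")])
        assert clocklike.count_sbs1(muts, "breast") == 0


class TestHypermutatorFilter:
    def make(self, tmb, sbs1):
        return pd.DataFrame([{"sample_id": "S", "tmb": tmb, "sbs1_count": sbs1}])

    def test_tmb_just_above_threshold_excluded(self):
        assert clocklike.filter_clock_samples(self.make(30_001, 100)).empty

    def test_boundary_values_retained(self):
        assert len(clocklike.filter_clock_samples(self.make(30_000, 5_000))) == 1

    def test_sbs1_just_above_threshold_excluded(self):
        assert clocklike.filter_clock_samples(self.make(100, 5_001)).empty


class TestBootstrapRegression:
    def test_collinear_points_recovered_exactly(self):
        ages = np.linspace(30, 80, 40)
        fit = clocklike.bootstrap_regression(ages, 3 * ages + 10, seed=5)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(10.0)
        assert fit.ci_lower_slope == pytest.approx(fit.ci_upper_slope)

    def test_deterministic_given_seed(self, rng):
        ages = rng.uniform(30, 80, 60)
        counts = 4 * ages + rng.normal(0, 30, 60)
        f1 = clocklike.bootstrap_regression(ages, counts, seed=7)
        f2 = clocklike.bootstrap_regression(ages, counts, seed=7)
        f3 = clocklike.bootstrap_regression(ages, counts, seed=8)
        assert (f1.slope, f1.intercept) == (f2.slope, f2.intercept)
        assert (f1.slope, f1.intercept) != (f3.slope, f3.intercept)

    def test_slope_recovery_under_noise(self, rng):
        ages = rng.uniform(30, 80, 200)
        counts = 4 * ages + rng.normal(0, 30, 200)
        fit = clocklike.bootstrap_regression(ages, counts, seed=1)
        assert 3.6 <= fit.slope <= 4.4

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            clocklike.bootstrap_regression([1.0] * 5, [1.0] * 5)


def make_fit(slope, intercept, r=0.9):
    return clocklike.RegressionFit(slope=slope, intercept=intercept, pearson_r=r,
                                   ci_lower_slope=slope, ci_lower_intercept=intercept,
                                   ci_upper_slope=slope, ci_upper_intercept=intercept,
                                   n_samples=100)


class TestFoldChangeAndDiff:
    def test_constant_ratio(self):
        assert clocklike.mean_fold_change(make_fit(4, 0), make_fit(2, 0)) \
            == pytest.approx(2.0)
        literal = Config(literal_1_over_40=True)
        assert clocklike.mean_fold_change(make_fit(4, 0), make_fit(2, 0), literal) \
            == pytest.approx(2.05)

    def test_identical_fits(self):
        assert clocklike.mean_fold_change(make_fit(2, 5), make_fit(2, 5)) \
            == pytest.approx(1.0)
        assert clocklike.mean_burden_diff(make_fit(2, 5), make_fit(2, 5)) == 0.0

    def test_offset_fold_change_by_direct_summation(self):
        # M: 2a+40, P: 2a -> mean over ages 40..80 of 1 + 20/a
        expected = np.mean([1 + 20 / a for a in range(40, 81)])
        got = clocklike.mean_fold_change(make_fit(2, 40), make_fit(2, 0))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(1.3473, abs=1e-4)

    def test_constant_offset_burden_diff(self):
        assert clocklike.mean_burden_diff(make_fit(2, 40), make_fit(2, 0)) \
            == pytest.approx(40.0)

    def test_slope_difference_burden_diff_is_mean_age(self):
        assert clocklike.mean_burden_diff(make_fit(3, 0), make_fit(2, 0)) \
            == pytest.approx(60.0)

    def test_scale_invariance(self):
        met, pri = make_fit(4.4, 17), make_fit(3.1, 9)
        scaled = clocklike.mean_fold_change(make_fit(4.4 * 3, 17 * 3),
                                            make_fit(3.1 * 3, 9 * 3))
        assert scaled == pytest.approx(clocklike.mean_fold_change(met, pri))
        assert clocklike.mean_burden_diff(make_fit(4.4 * 3, 17 * 3),
                                          make_fit(3.1 * 3, 9 * 3)) \
            == pytest.approx(3 * clocklike.mean_burden_diff(met, pri))

    def test_nonpositive_primary_prediction_rejected(self):
        with pytest.raises(ValueError):
            clocklike.mean_fold_change(make_fit(2, 0), make_fit(1, -100))


class TestCompareRates:
    def points(self, slope, n, seed, noise=30.0, intercept=0.0):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(30, 80, n)
        return ages, np.clip(slope * ages + intercept + rng.normal(0, noise, n), 0, None)

    def test_pearson_gate_blocks_flat_regression(self):
        pri = make_fit(4, 0, r=0.05)
        met = make_fit(8, 50, r=0.9)
        ages = np.linspace(30, 80, 30)
        comp = clocklike.compare_rates(pri, met, (ages, 4 * ages),
                                       (ages, 8 * ages + 50))
        assert not comp.gate_passed and not comp.significant

    def test_shifted_cohort_detected(self):
        pri_ages, pri_counts = self.points(4, 250, seed=1)
        met_ages, met_counts = self.points(6, 250, seed=2)
        pri_fit = clocklike.bootstrap_regression(pri_ages, pri_counts, seed=3)
        met_fit = clocklike.bootstrap_regression(met_ages, met_counts, seed=4)
        comp = clocklike.compare_rates(pri_fit, met_fit, (pri_ages, pri_counts),
                                       (met_ages, met_counts))
        assert comp.gate_passed and comp.significant
        assert comp.mean_fold_change > 1.2

    def test_null_not_significant(self):
        pri_ages, pri_counts = self.points(4, 250, seed=5)
        met_ages, met_counts = self.points(4, 250, seed=6)
        pri_fit = clocklike.bootstrap_regression(pri_ages, pri_counts, seed=7)
        met_fit = clocklike.bootstrap_regression(met_ages, met_counts, seed=8)
        comp = clocklike.compare_rates(pri_fit, met_fit, (pri_ages, pri_counts),
                                       (met_ages, met_counts))
        assert not comp.significant


class TestMlAssignment:
    def test_only_nonzero_exposure_wins(self):
        assert clocklike.assign_clocklike_ml(
            "A[C>T]G", {"SBS5": 100.0, "SBS1": 0.0},
            {"SBS5": 0.01, "SBS1": 0.5}) == "SBS5"

    def test_zero_profile_probability_loses(self):
        assert clocklike.assign_clocklike_ml(
            "X", {"A": 100.0, "B": 100.0}, {"A": 0.0, "B": 0.2}) == "B"

    def test_product_arithmetic(self):
        winner = clocklike.assign_clocklike_ml(
            "X", {"SBS5": 100.0, "SBS1": 300.0}, {"SBS5": 0.02, "SBS1": 0.01})
        assert winner == "SBS1"  # 3.0 > 2.0

    def test_all_zero_unassigned(self):
        assert clocklike.assign_clocklike_ml("X", {"A": 0.0}, {"A": 0.5}) is None


class TestClonalityRatio:
    def make(self, sbs1_clonal, sbs1_total, other_clonal, other_total):
        rows = []
        for i in range(sbs1_total):
            rows.append(sbs_record("ACG", likelihood=0.1 if i < sbs1_clonal else 0.95))
        for i in range(other_total):
            rows.append(sbs_record("ACA", likelihood=0.1 if i < other_clonal else 0.95))
        return pd.DataFrame(rows)

    def test_equal_proportions_give_one(self):
        muts = self.make(4, 5, 4, 5)
        assert clocklike.sbs1_clonality_ratio(muts, "breast") == pytest.approx(1.0)

    def test_formula(self):
        # SBS1 clonal 0.6; overall 0.8 (SBS1 3/5 + other 5/5) -> 0.75
        muts = self.make(3, 5, 5, 5)
        assert clocklike.sbs1_clonality_ratio(muts, "breast") == pytest.approx(0.75)

    def test_no_sbs1_returns_none(self):
        muts = pd.DataFrame([sbs_record("ACA")])
        assert clocklike.sbs1_clonality_ratio(muts, "breast") is None


class TestRateVsFoldChange:
    def test_perfectly_antimonotone(self):
        rates = pd.DataFrame({"cancer_type": list("abcd"), "rate": [1, 2, 3, 4]})
        fcs = pd.DataFrame({"cancer_type": list("abcd"),
                            "mean_fold_change": [4, 3, 2, 1]})
        res = clocklike.rate_vs_foldchange(rates, fcs)
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_input_returns_none(self):
        rates = pd.DataFrame({"cancer_type": list("abcd"), "rate": [1, 2, 3, 4]})
        fcs = pd.DataFrame({"cancer_type": list("abcd"),
                            "mean_fold_change": [2, 2, 2, 2]})
        assert clocklike.rate_vs_foldchange(rates, fcs) is None

    def test_random_pairing_uncorrelated_on_average(self, rng):
        rhos = []
        for _ in range(100):
            rates = pd.DataFrame({"cancer_type": list("abcdefgh"),
                                  "rate": rng.uniform(1, 5, 8)})
            fcs = pd.DataFrame({"cancer_type": list("abcdefgh"),
                                "mean_fold_change": rng.uniform(1, 2, 8)})
            rhos.append(clocklike.rate_vs_foldchange(rates, fcs).statistic)
        assert abs(np.mean(rhos)) < 0.15

    def test_too_few_types_rejected(self):
        rates = pd.DataFrame({"cancer_type": list("abc"), "rate": [1, 2, 3]})
        fcs = pd.DataFrame({"cancer_type": list("abc"),
                            "mean_fold_change": [1, 2, 3]})
        with pytest.raises(ValueError):
            clocklike.rate_vs_foldchange(rates, fcs)


def test_ploidy_correction_commutes(rng):
    """Dividing counts by ploidy then regressing equals regressing the
    pre-corrected table."""
    samples = pd.DataFrame([{
        "sample_id": f"S{i}", "cohort": "primary", "cancer_type": "breast",
        "age_at_biopsy": float(a), "genome_ploidy": 2.0 + (i % 3)}
        for i, a in enumerate(rng.uniform(30, 80, 30))])
    muts = pd.DataFrame([sbs_record("ACG") | {"sample_id": f"S{i}"}
                         for i in range(30) for _ in range(rng.integers(5, 50))])
    table = clocklike.build_clock_table(muts, samples, ploidy_correct=True)
    raw = clocklike.build_clock_table(muts, samples, ploidy_correct=False)
    merged = raw.merge(samples[["sample_id", "genome_ploidy"]], on="sample_id")
    np.testing.assert_allclose(
        table.sort_values("sample_id")["sbs1_count"].to_numpy(),
        (merged.sort_values("sample_id")["sbs1_count"]
         / merged.sort_values("sample_id")["genome_ploidy"]).to_numpy())
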