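"""Karyotype scoring, WGD normalization and the instability indicators."""

import numpy as np
import pandas as pd
import pytest

from metprime import karyotype
from metprime.config import Config
from metprime.simulate import SimulationConfig, simulate_cohort
from metprime.stats import fisher_exact_two_sided

ARM = {"chrom": "5", "arm": "p", "start": 0, "end": 1000}


def segments_for(spans, sample_id="S1", chrom="5"):
    """spans: list of (start, end, cn_total) tuples."""
    return pd.DataFrame([
        {"sample_id": sample_id, "chrom": chrom, "start": s, "end": e,
         "cn_total": cn, "cn_minor": min(1.0, cn / 2), "cn_major": max(cn / 2, cn - 1)}
        for s, e, cn in spans])


class TestArmModalPloidy:
    def test_worked_coverage_example(self):
        # 60% of the arm at CN 2, 30% at CN 1, 10% at CN 3 -> arm ploidy 2
        seg = segments_for([(0, 600, 2.0), (600, 900, 1.0), (900, 1000, 3.0)])
        assert karyotype.arm_modal_ploidy(seg, ARM) == 2

    def test_uniform_noninteger_cn_rounds(self):
        seg = segments_for([(0, 1000, 3.4)])
        assert karyotype.arm_modal_ploidy(seg, ARM) == 3

    def test_half_rounds_away_from_zero(self):
        assert karyotype.round_half_away(2.5) == 3
        assert karyotype.round_half_away(2.49) == 2

    def test_coverage_tie_breaks_to_lower_cn(self):
        seg = segments_for([(0, 500, 2.0), (500, 1000, 3.0)])
        assert karyotype.arm_modal_ploidy(seg, ARM) == 2
        assert karyotype.arm_modal_ploidy(seg, ARM, tie_lower=False) == 3

    def test_no_overlap_is_an_error_naming_the_arm(self):
        seg = segments_for([(0, 100, 2.0)], chrom="7")
        with pytest.raises(ValueError, match="5p"):
            karyotype.arm_modal_ploidy(seg, ARM)


class TestExpectedGenomePloidy:
    @pytest.mark.parametrize("wgd,observed,expected", [
        (False, 3, 2), (False, 2, 2),
        (True, 5, 4), (True, 3, 4),
        (True, 6, 8), (True, 8, 8),
    ])
    def test_rule_table(self, wgd, observed, expected):
        assert karyotype.expected_genome_ploidy(wgd, observed) == expected

    def test_observed_above_eight_rejected(self):
        with pytest.raises(ValueError):
            karyotype.expected_genome_ploidy(True, 9)


@pytest.mark.parametrize("arm_ploidy,expected,cls", [
    (3, 2, 1), (2, 2, 0), (1, 4, -1), (4, 4, 0), (6, 4, 1),
])
def test_normalized_arm_class(arm_ploidy, expected, cls):
    assert karyotype.normalized_arm_class(arm_ploidy, expected) == cls


def test_wgd_normalization_leaves_classes_invariant(rng):
    """Doubling every CN with wgd=true must not change any arm class."""
    arms = pd.DataFrame([{"chrom": str(c), "arm": a, "start": 0, "end": 1000}
                         for c in range(1, 11) for a in ("p", "q")])
    for _ in range(100):
        ploidies = {f"{r['chrom']}{r['arm']}": int(rng.integers(1, 4))
                    for _, r in arms.iterrows()}
        seg_rows, seg_rows_2x = [], []
        for _, r in arms.iterrows():
            cn = ploidies[f"{r['chrom']}{r['arm']}"]
            base = {"sample_id": "S", "chrom": r["chrom"], "start": 0, "end": 1000,
                    "cn_minor": 1.0}
            seg_rows.append({**base, "cn_total": float(cn), "cn_major": float(cn)})
            seg_rows_2x.append({**base, "cn_total": float(2 * cn),
                                "cn_major": float(2 * cn)})
        seg, seg2 = pd.DataFrame(seg_rows), pd.DataFrame(seg_rows_2x)
        classes, classes2 = [], []
        obs = karyotype.observed_genome_ploidy(ploidies, seg)
        ploidies2 = {k: 2 * v for k, v in ploidies.items()}
        obs2 = karyotype.observed_genome_ploidy(ploidies2, seg2)
        exp = karyotype.expected_genome_ploidy(False, obs)
        exp2 = karyotype.expected_genome_ploidy(True, obs2)
        if exp2 != 2 * exp:  # observed >= 6 pushes to the 8n tier; rule changes
            continue
        for name in ploidies:
            classes.append(karyotype.normalized_arm_class(ploidies[name], exp))
            classes2.append(karyotype.normalized_arm_class(ploidies2[name], exp2))
        # doubling shifts deviations by a factor 2, so gains stay gains and
        # losses stay losses; neutral arms stay neutral
        for c1, c2 in zip(classes, classes2):
            assert np.sign(c1) == np.sign(c2) or (c1 == 0) == (c2 == 0)


class TestAneuploidyAndLoh:
    def test_aneuploidy_counts_deviating_arms(self):
        prof = pd.DataFrame({
            "arm_ploidy": [2, 2, 3, 1, 2, 3, 3, 3, 3, 1, 1],
            "expected_genome_ploidy": [2] * 11,
        })
        # 5 gains + 3 losses
        assert karyotype.aneuploidy_score(prof) == 8
        assert karyotype.aneuploidy_score(prof) == int(
            np.abs(np.sign(prof["arm_ploidy"] - prof["expected_genome_ploidy"])).sum())

    def test_loh_definition_and_boundaries(self):
        def seg(minor, major, length=100):
            return pd.DataFrame([{"sample_id": "S", "chrom": "1", "start": 0,
                                  "end": length, "cn_total": minor + major,
                                  "cn_minor": minor, "cn_major": major}])
        assert karyotype.loh_fraction(seg(0.1, 1.0), 1000) == pytest.approx(0.1)
        assert karyotype.loh_fraction(seg(0.25, 1.0), 1000) == 0.0  # minor < 0.25 strict
        assert karyotype.loh_fraction(seg(0.1, 0.79), 1000) == 0.0  # major >= 0.8

    def test_loh_invariant_to_segment_splitting(self):
        whole = pd.DataFrame([{"sample_id": "S", "chrom": "1", "start": 0,
                               "end": 200, "cn_total": 1.0, "cn_minor": 0.1,
                               "cn_major": 0.9}])
        halves = pd.DataFrame([
            {"sample_id": "S", "chrom": "1", "start": 0, "end": 77,
             "cn_total": 1.0, "cn_minor": 0.1, "cn_major": 0.9},
            {"sample_id": "S", "chrom": "1", "start": 77, "end": 200,
             "cn_total": 1.0, "cn_minor": 0.1, "cn_major": 0.9}])
        assert karyotype.loh_fraction(whole, 1000) == karyotype.loh_fraction(
            halves, 1000)


class TestWgdCall:
    def make(self, n_high, cn_high=1.6):
        values = [cn_high] * n_high + [1.0] * (22 - n_high)
        return pd.Series(values, index=[str(i) for i in range(1, 23)])

    def test_eleven_autosomes_above_threshold_is_wgd(self):
        assert karyotype.call_wgd(self.make(11)) is True

    def test_ten_autosomes_is_not_wgd(self):
        assert karyotype.call_wgd(self.make(10)) is False

    def test_diploid_genome_is_not_wgd(self):
        assert karyotype.call_wgd(self.make(0)) is False

    def test_cn_exactly_at_threshold_does_not_count(self):
        assert karyotype.call_wgd(self.make(11, cn_high=1.5)) is False


def test_arm_comparison_identical_cohorts_no_hits(toy_samples):
    samples = toy_samples(5, 5)
    prof = pd.DataFrame([{"sample_id": s, "arm": a, "arm_ploidy": 2,
                          "observed_genome_ploidy": 2, "expected_genome_ploidy": 2,
                          "normalized_class": 0}
                         for s in samples["sample_id"] for a in ("1p", "1q")])
    result = karyotype.compare_arm_profiles(prof, samples)
    assert not result["significant"].any()


def test_arm_comparison_exact_boundary_difference_not_significant(toy_samples):
    samples = toy_samples(8, 8)
    rows = []
    for i, s in enumerate(samples[samples["cohort"] == "metastatic"]["sample_id"]):
        cls = -1 if i < 2 else 0  # mean -0.25 exactly
        rows.append({"sample_id": s, "arm": "5q", "arm_ploidy": 2 + cls,
                     "observed_genome_ploidy": 2, "expected_genome_ploidy": 2,
                     "normalized_class": cls})
    for s in samples[samples["cohort"] == "primary"]["sample_id"]:
        rows.append({"sample_id": s, "arm": "5q", "arm_ploidy": 2,
                     "observed_genome_ploidy": 2, "expected_genome_ploidy": 2,
                     "normalized_class": 0})
    result = karyotype.compare_arm_profiles(pd.DataFrame(rows), samples)
    assert result["mean_difference"].iloc[0] == pytest.approx(-0.25)
    assert not result["significant"].any()  # needs |diff| strictly > 0.25


def test_simulated_arm_loss_recovered():
    """A 5q loss at 45% metastatic vs 10% primary prevalence is detected."""
    cfg = SimulationConfig(seed=3, n_primary=80, n_metastatic=80,
                           cancer_types=("breast",))
    ds = simulate_cohort(cfg)
    profiles = karyotype.build_arm_profiles(ds.segments, ds.samples,
                                            ds.arm_definitions)
    result = karyotype.compare_arm_profiles(profiles, ds.samples)
    hit = result[(result["arm"] == "5q")]
    assert hit["significant"].iloc[0]
    assert hit["mean_difference"].iloc[0] < -0.25


def test_instability_comparison_fisher_matches_stats_core(toy_samples):
    samples = toy_samples(10, 10)
    rng = np.random.default_rng(5)
    indicators = pd.DataFrame({
        "sample_id": samples["sample_id"],
        "aneuploidy_score": rng.integers(0, 10, size=20),
        "loh_fraction": rng.uniform(0, 0.3, size=20),
        "wgd": [True] * 7 + [False] * 3 + [True] * 2 + [False] * 8,
        "tp53_altered": [True] * 6 + [False] * 4 + [True] * 1 + [False] * 9,
    })
    result = karyotype.compare_instability(indicators, samples)
    tp53_row = result[result["indicator"] == "tp53_altered"].iloc[0]
    expected = fisher_exact_two_sided([[6, 4], [1, 9]])
    assert tp53_row["p_value"] == pytest.approx(expected.p_value)
    assert tp53_row["statistic"] == pytest.approx(expected.statistic)
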