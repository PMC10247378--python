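"""Driver counting, enrichment and the treatment-enriched-driver test."""

import numpy as np
import pandas as pd
import pytest

from metprime import drivers
from metprime.config import Config
from metprime.stats import mann_whitney_two_sided


def event(sample_id="S1", gene="TP53", alteration_type="mutation", likelihood=0.9):
    return {"sample_id": sample_id, "gene": gene,
            "alteration_type": alteration_type, "driver_likelihood": likelihood}


class TestDriverCounting:
    def test_same_gene_different_types_counted_once(self):
        events = pd.DataFrame([event(), event(alteration_type="deletion")])
        assert drivers.driver_count_per_patient(events) == 1

    def test_likelihood_boundary_strict(self):
        assert drivers.driver_count_per_patient(pd.DataFrame([event(likelihood=0.5)])) == 0
        assert drivers.driver_count_per_patient(pd.DataFrame([event(likelihood=0.51)])) == 1

    def test_empty_is_zero(self):
        empty = pd.DataFrame(columns=["sample_id", "gene", "alteration_type",
                                      "driver_likelihood"])
        assert drivers.driver_count_per_patient(empty) == 0

    def test_idempotent_under_duplication(self):
        events = pd.DataFrame([event()] * 5)
        assert drivers.driver_count_per_patient(events) == 1


class TestDriverCountComparison:
    def test_statistic_matches_stats_core(self, toy_samples):
        samples = toy_samples(3, 3)
        counts = pd.DataFrame({"sample_id": samples["sample_id"],
                               "n_drivers": [5, 6, 7, 1, 2, 3]})
        out = drivers.compare_driver_counts(counts, samples)
        ref = mann_whitney_two_sided([5, 6, 7], [1, 2, 3])
        assert out["statistic_u"].iloc[0] == ref.statistic
        assert out["p_value"].iloc[0] == ref.p_value

    def test_shifted_cohort_detected(self, toy_samples):
        rng = np.random.default_rng(0)
        samples = toy_samples(100, 100)
        counts = pd.DataFrame({
            "sample_id": samples["sample_id"],
            "n_drivers": np.concatenate([rng.poisson(6, 100), rng.poisson(4, 100)])})
        out = drivers.compare_driver_counts(counts, samples)
        assert out["significant"].iloc[0]
        assert out["mean_difference"].iloc[0] > 0


class TestFrequencyEnrichment:
    def test_min_mutated_filter(self, toy_samples):
        samples = toy_samples(50, 50)
        events = [event(f"M{i}", "RARE") for i in range(4)] + \
                 [event(f"P{i}", "RARE") for i in range(4)]
        out = drivers.driver_frequency_enrichment(pd.DataFrame(events), samples)
        assert out.empty

    def test_fisher_arithmetic_example(self, toy_samples):
        samples = toy_samples(100, 100)
        events = [event(f"M{i}", "G") for i in range(30)] + \
                 [event(f"P{i}", "G") for i in range(5)]
        out = drivers.driver_frequency_enrichment(pd.DataFrame(events), samples)
        assert out["odds_ratio"].iloc[0] == pytest.approx((30 * 95) / (70 * 5))
        assert out["significant"].iloc[0]

    def test_homozygous_disruption_counts_as_deletion(self, toy_samples):
        samples = toy_samples(10, 10)
        events = [event(f"M{i}", "G", "homozygous_disruption") for i in range(6)]
        out = drivers.driver_frequency_enrichment(pd.DataFrame(events), samples)
        assert (out["category"] == "deletion").all()


class TestTreatmentGroups:
    def make_treatments(self, n, mech="platinum"):
        return pd.DataFrame([
            {"sample_id": f"M{i}", "drug_name": f"{mech}_drug",
             "mechanism_group": mech, "pre_biopsy": True} for i in range(n)])

    def test_small_group_excluded(self, toy_samples):
        samples = toy_samples(12, 0)
        groups = drivers.build_treatment_groups(self.make_treatments(9), samples)
        assert groups == []

    def test_mechanism_map_merges_drugs(self, toy_samples):
        samples = toy_samples(12, 0)
        treatments = pd.DataFrame([
            {"sample_id": f"M{i}", "drug_name": "cisplatin" if i % 2 else "oxaliplatin",
             "mechanism_group": "", "pre_biopsy": True} for i in range(12)])
        groups = drivers.build_treatment_groups(
            treatments, samples,
            {"cisplatin": "platinum", "oxaliplatin": "platinum"})
        assert len(groups) == 1 and groups[0].mechanism_group == "platinum"
        assert groups[0].n_patients == 12

    def test_patient_in_multiple_groups(self, toy_samples):
        samples = toy_samples(12, 0)
        rows = []
        for i in range(12):
            for mech in ("platinum", "taxane"):
                rows.append({"sample_id": f"M{i}", "drug_name": mech,
                             "mechanism_group": mech, "pre_biopsy": True})
        groups = drivers.build_treatment_groups(pd.DataFrame(rows), samples)
        assert len(groups) == 2
        assert groups[0].patients == groups[1].patients


class TestGeneCnStatus:
    def test_amplification_strict_boundary(self):
        assert drivers.gene_cn_status(5.6, 3.0) == "amplified"
        assert drivers.gene_cn_status(5.5, 3.0) == "neutral"  # exactly +2.5

    def test_deletion_boundary(self):
        assert drivers.gene_cn_status(0.29, 2.0) == "deleted"
        assert drivers.gene_cn_status(0.30, 2.0) == "neutral"


class TestTedTest:
    def run(self, t_mut, n_t, u_mut, n_u):
        group = drivers.TreatmentGroup("breast", "platinum",
                                       frozenset(f"T{i}" for i in range(n_t)))
        untreated = frozenset(f"U{i}" for i in range(n_u))
        altered = {("G", "mutation"): frozenset(
            [f"T{i}" for i in range(t_mut)] + [f"U{i}" for i in range(u_mut)])}
        cands = pd.DataFrame([{"gene": "G", "alteration_category": "mutation"}])
        return drivers.ted_test(cands, group, untreated, altered)

    def test_odds_ratio_arithmetic(self):
        res = self.run(10, 20, 1, 40)
        assert res[0].odds_ratio == pytest.approx((10 * 39) / (10 * 1))

    def test_exclusivity_boundary(self):
        assert self.run(10, 20, 2, 40)[0].label == "treatment_enriched"   # 5%
        assert self.run(10, 20, 1, 40)[0].label == "treatment_exclusive"  # 2.5%

    def test_noncoding_needs_three_mutated(self):
        group = drivers.TreatmentGroup("breast", "platinum",
                                       frozenset(f"T{i}" for i in range(20)))
        untreated = frozenset(f"U{i}" for i in range(40))
        altered = {("NC", "noncoding"): frozenset(["T0", "T1"])}
        cands = pd.DataFrame([{"gene": "NC", "alteration_category": "noncoding"}])
        assert drivers.ted_test(cands, group, untreated, altered) == []

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            self.run(3, 5, 1, 40)


class TestPeakMergingAndPrioritization:
    def peaks(self, rows):
        return pd.DataFrame([{"cancer_type": "breast", "peak_type": "amplification",
                              "chrom": "8", **r} for r in rows])

    def test_overlapping_peaks_union(self):
        out = drivers.merge_cn_peaks(self.peaks([
            {"start": 1, "end": 100, "summit": 50, "gene": "A",
             "treatment": "t1", "q_value": 0.01},
            {"start": 50, "end": 150, "summit": 90, "gene": "B",
             "treatment": "t2", "q_value": 0.001}]))
        assert len(out) == 1
        assert out["start"].iloc[0] == 1 and out["end"].iloc[0] == 150
        assert out["treatment"].iloc[0] == "t2"  # lowest q wins

    def test_disjoint_peaks_unchanged(self):
        out = drivers.merge_cn_peaks(self.peaks([
            {"start": 1, "end": 100, "summit": 50, "gene": "A",
             "treatment": "t1", "q_value": 0.01},
            {"start": 200, "end": 300, "summit": 250, "gene": "B",
             "treatment": "t2", "q_value": 0.001}]))
        assert len(out) == 2

    def test_amp_and_del_peaks_processed_separately(self):
        peaks = pd.concat([
            self.peaks([{"start": 1, "end": 100, "summit": 10, "gene": "A",
                         "treatment": "t", "q_value": 0.01}]),
            self.peaks([{"start": 50, "end": 150, "summit": 60, "gene": "B",
                         "treatment": "t", "q_value": 0.01}]).assign(
                peak_type="deletion")])
        assert len(drivers.merge_cn_peaks(peaks)) == 2

    def make_ted(self, mech, q, significant=True):
        return drivers.TedResult(
            gene="G", alteration_category="mutation", cancer_type="breast",
            mechanism_group=mech, n_treated_mutated=5, n_treated=20,
            n_untreated_mutated=1, n_untreated=40, odds_ratio=10.0,
            p_value=q / 2, q_value=q, significant=significant)

    def test_most_significant_treatment_kept(self):
        out = drivers.prioritize_teds([self.make_ted("a", 0.01),
                                       self.make_ted("b", 0.001)])
        assert len(out) == 1 and out[0].mechanism_group == "b"

    def test_curated_pairing_overrides(self):
        out = drivers.prioritize_teds(
            [self.make_ted("a", 0.01), self.make_ted("b", 0.001)],
            curated_pairs={("G", "breast", "a")})
        assert out[0].mechanism_group == "a" and out[0].known_resistance


class TestRecount:
    def test_empty_catalogue_leaves_counts(self, toy_samples):
        samples = toy_samples(3, 3)
        events = pd.DataFrame([event("M0"), event("P0", "PIK3CA")])
        empty = pd.DataFrame(columns=["cancer_type", "gene", "alteration_category"])
        out = drivers.recount_excluding_teds(events, samples, empty)
        before = out.set_index("cohort")["mean_drivers_before"]
        after = out.set_index("cohort")["mean_drivers_after"]
        assert (before == after).all()

    def test_all_drivers_ted_gives_zero(self, toy_samples):
        samples = toy_samples(3, 3)
        events = pd.DataFrame([event(f"M{i}") for i in range(3)])
        ted = pd.DataFrame([{"cancer_type": "breast", "gene": "TP53",
                             "alteration_category": "mutation"}])
        out = drivers.recount_excluding_teds(events, samples, ted)
        met = out.set_index("cohort").loc["metastatic"]
        assert met["mean_drivers_before"] == 1.0
        assert met["mean_drivers_after"] == 0.0
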