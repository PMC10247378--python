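"""Driver-landscape comparison and treatment-enriched drivers (TEDs).

Driver events with likelihood above 0.5 are deduplicated per gene (a
mutation plus a deletion of the same gene is one driver) and counted per
patient; cohorts are compared per cancer type by Mann-Whitney (q < 0.01)
and per (gene, alteration category) by Fisher exact test (min 5 mutated
samples in either cohort, BH within cancer type, q < 0.01).

The TED test asks, per cancer type and treatment-mechanism group with at
least ten treated patients, whether a driver element is more frequent in
treated than in untreated patients of the same cancer type: Fisher exact
with odds ratio, BH within (group x alteration category), significance at
q < 0.05 for coding and copy-number candidates and q < 0.1 for non-coding
ones (which also need >= 3 mutated samples). A significant driver is
"treatment exclusive" when its untreated frequency is below 5%. Per gene
and cancer type the most significant treatment is kept unless a curated
literature pairing pins another. Copy-number candidate peaks are merged per
genomic region first. Finally the driver-per-patient comparison can be
recomputed with the TED catalogue excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .stats import adjust_pvalues, fisher_exact_two_sided, mann_whitney_two_sided

logger = logging.getLogger("metprime")

AMP_LIKE = {"amplification"}          # partial amplifications fold in upstream
DEL_LIKE = {"deletion", "homozygous_disruption"}


def retained_drivers(events: pd.DataFrame, config: Config = Config()) -> pd.DataFrame:
    """Drivers with likelihood strictly above ``driver_likelihood_min``."""
    return events[events["driver_likelihood"] > config.driver_likelihood_min]


def driver_count_per_patient(events: pd.DataFrame,
                             config: Config = Config()) -> int:
    """Unique driver genes among retained events of one sample."""
    return int(retained_drivers(events, config)["gene"].nunique())


def driver_counts_table(drivers: pd.DataFrame, samples: pd.DataFrame,
                        config: Config = Config()) -> pd.DataFrame:
    """Per-sample deduplicated driver counts (samples without events get 0)."""
    retained = retained_drivers(drivers, config)
    counts = retained.groupby("sample_id")["gene"].nunique()
    out = samples[["sample_id"]].copy()
    out["n_drivers"] = out["sample_id"].map(counts).fillna(0).astype(int)
    return out


def compare_driver_counts(counts: pd.DataFrame, samples: pd.DataFrame,
                          config: Config = Config()) -> pd.DataFrame:
    """Mann-Whitney on drivers/sample per cancer type; BH; q < 0.01."""
    merged = counts.merge(samples[["sample_id", "cohort", "cancer_type"]], on="sample_id")
    rows = []
    for cancer_type, sub in merged.groupby("cancer_type"):
        met = sub.loc[sub["cohort"] == "metastatic", "n_drivers"].to_numpy(dtype=float)
        pri = sub.loc[sub["cohort"] == "primary", "n_drivers"].to_numpy(dtype=float)
        if len(met) == 0 or len(pri) == 0:
            continue
        res = mann_whitney_two_sided(met, pri)
        rows.append({"cancer_type": cancer_type,
                     "mean_metastatic": met.mean(), "mean_primary": pri.mean(),
                     "mean_difference": met.mean() - pri.mean(),
                     "statistic_u": res.statistic, "p_value": res.p_value})
    result = pd.DataFrame(rows, columns=["cancer_type", "mean_metastatic",
                                         "mean_primary", "mean_difference",
                                         "statistic_u", "p_value"])
    if len(result):
        result["q_value"] = adjust_pvalues(result["p_value"], "bh")
        result["significant"] = result["q_value"] < config.driver_count_q
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


def _alteration_category(alteration_type: str) -> str:
    if alteration_type in AMP_LIKE:
        return "amplification"
    if alteration_type in DEL_LIKE:
        return "deletion"
    if alteration_type == "noncoding":
        return "noncoding"
    return "mutation"


def driver_frequency_enrichment(drivers: pd.DataFrame, samples: pd.DataFrame,
                                config: Config = Config()) -> pd.DataFrame:
    """Per-gene driver-frequency enrichment between cohorts.

    2x2 of (mutated, not) x (metastatic, primary) per gene, alteration
    category and cancer type; genes need >= ``gene_min_mutated`` mutated
    samples in either cohort; Fisher exact; BH within cancer type;
    significant iff q < ``driver_enrichment_q``.
    """
    retained = retained_drivers(drivers, config).copy()
    retained["category"] = retained["alteration_type"].map(_alteration_category)
    merged = retained.merge(samples[["sample_id", "cohort", "cancer_type"]],
                            on="sample_id")
    cohort_sizes = samples.groupby(["cancer_type", "cohort"])["sample_id"].nunique()
    results = []
    for cancer_type, ct_sub in merged.groupby("cancer_type"):
        try:
            n_met = int(cohort_sizes[(cancer_type, "metastatic")])
            n_pri = int(cohort_sizes[(cancer_type, "primary")])
        except KeyError:
            continue
        rows = []
        for (gene, category), sub in ct_sub.groupby(["gene", "category"]):
            met_mut = sub.loc[sub["cohort"] == "metastatic", "sample_id"].nunique()
            pri_mut = sub.loc[sub["cohort"] == "primary", "sample_id"].nunique()
            if max(met_mut, pri_mut) < config.gene_min_mutated:
                continue
            res = fisher_exact_two_sided(
                [[met_mut, n_met - met_mut], [pri_mut, n_pri - pri_mut]])
            rows.append({"cancer_type": cancer_type, "gene": gene,
                         "category": category, "n_metastatic_mutated": met_mut,
                         "n_primary_mutated": pri_mut,
                         "odds_ratio": res.statistic, "p_value": res.p_value})
        if not rows:
            continue
        block = pd.DataFrame(rows)
        block["q_value"] = adjust_pvalues(block["p_value"], "bh")
        block["significant"] = block["q_value"] < config.driver_enrichment_q
        results.append(block)
    columns = ["cancer_type", "gene", "category", "n_metastatic_mutated",
               "n_primary_mutated", "odds_ratio", "p_value", "q_value", "significant"]
    if not results:
        return pd.DataFrame(columns=columns)
    return pd.concat(results, ignore_index=True)[columns]


@dataclass
class TreatmentGroup:
    cancer_type: str
    mechanism_group: str
    patients: frozenset

    @property
    def n_patients(self) -> int:
        return len(self.patients)


def build_treatment_groups(treatments: pd.DataFrame, samples: pd.DataFrame,
                           mechanism_map: dict[str, str] | None = None,
                           config: Config = Config()) -> list[TreatmentGroup]:
    """(cancer type x mechanism) patient groups with >= 10 patients.

    ``mechanism_map`` optionally remaps drug names to mechanism groups
    (unknown drugs warn and fall into "other"); otherwise the table's own
    mechanism_group column is used. Patients may belong to several groups.
    Only pre-biopsy treatment records count.
    """
    pre = treatments[treatments["pre_biopsy"].astype(bool)].copy()
    if mechanism_map is not None:
        unknown = set(pre["drug_name"]) - set(mechanism_map)
        if unknown:
            logger.warning("drugs without mechanism mapping -> 'other': %s",
                           sorted(unknown)[:5])
        pre["mechanism_group"] = pre["drug_name"].map(
            lambda d: mechanism_map.get(d, "other"))
    meta = samples.set_index("sample_id")[["patient_id", "cancer_type"]]
    pre = pre.join(meta, on="sample_id")
    groups = []
    for (cancer_type, mech), sub in pre.groupby(["cancer_type", "mechanism_group"]):
        patients = frozenset(sub["patient_id"])
        if len(patients) >= config.ted_min_patients:
            groups.append(TreatmentGroup(cancer_type, mech, patients))
    return groups


def gene_cn_status(gene_ploidy: float, sample_mean_ploidy: float,
                   config: Config = Config()) -> str:
    """'amplified' iff gene ploidy exceeds the genome mean by more than 2.5
    (strict); 'deleted' iff gene ploidy below 0.3; else 'neutral'."""
    if gene_ploidy < 0 or sample_mean_ploidy < 0:
        raise ValueError("ploidies must be nonnegative")
    if gene_ploidy - sample_mean_ploidy > config.cn_amp_diff:
        return "amplified"
    if gene_ploidy < config.cn_del_below:
        return "deleted"
    return "neutral"


@dataclass
class TedResult:
    gene: str
    alteration_category: str
    cancer_type: str
    mechanism_group: str
    n_treated_mutated: int
    n_treated: int
    n_untreated_mutated: int
    n_untreated: int
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    label: str = "treatment_enriched"
    known_resistance: bool = False


def _untreated_patients(group: TreatmentGroup, treatments: pd.DataFrame,
                        samples: pd.DataFrame, config: Config) -> frozenset:
    """Untreated comparison group: annotated metastatic patients of the same
    cancer type outside the mechanism group (or with no treatment at all
    under ``untreated_strict``)."""
    met = samples[(samples["cohort"] == "metastatic")
                  & (samples["cancer_type"] == group.cancer_type)]
    annotated = met[met["sample_id"].isin(treatments["sample_id"])]
    candidates = set(annotated["patient_id"])
    pre = treatments[treatments["pre_biopsy"].astype(bool)]
    if config.untreated_strict:
        pre_treated = set(met.loc[met["sample_id"].isin(pre["sample_id"]),
                                  "patient_id"])
        return frozenset(candidates - pre_treated)
    return frozenset(candidates - group.patients)


def ted_test(candidates: pd.DataFrame, group: TreatmentGroup,
             untreated_patients: frozenset, altered_patients: dict,
             config: Config = Config()) -> list[TedResult]:
    """Fisher enrichment of candidate elements in the treated group.

    ``candidates`` has columns gene and alteration_category;
    ``altered_patients`` maps (gene, category) to the set of altered
    patients. BH runs within each alteration category; thresholds
    ``ted_q_coding`` for coding/CN and ``ted_q_noncoding`` for non-coding
    (the latter also need ``ted_noncoding_min_mutated`` treated-altered
    patients). Elements with untreated frequency below
    ``exclusive_max_frequency`` are labelled treatment_exclusive.
    """
    if group.n_patients < config.ted_min_patients:
        raise ValueError("treated group below the minimum patient count")
    if not untreated_patients:
        raise ValueError("untreated comparison group is empty")
    results: list[TedResult] = []
    for _, cand in candidates.iterrows():
        key = (cand["gene"], cand["alteration_category"])
        altered = set(altered_patients.get(key, frozenset()))
        t_mut = len(altered & group.patients)
        u_mut = len(altered & untreated_patients)
        if cand["alteration_category"] == "noncoding" \
                and t_mut < config.ted_noncoding_min_mutated:
            continue
        n_t, n_u = group.n_patients, len(untreated_patients)
        res = fisher_exact_two_sided([[t_mut, n_t - t_mut], [u_mut, n_u - u_mut]])
        results.append(TedResult(
            gene=cand["gene"], alteration_category=cand["alteration_category"],
            cancer_type=group.cancer_type, mechanism_group=group.mechanism_group,
            n_treated_mutated=t_mut, n_treated=n_t,
            n_untreated_mutated=u_mut, n_untreated=n_u,
            odds_ratio=res.statistic, p_value=res.p_value,
            label=("treatment_exclusive" if u_mut / n_u < config.exclusive_max_frequency
                   else "treatment_enriched"),
        ))
    for category in {r.alteration_category for r in results}:
        block = [r for r in results if r.alteration_category == category]
        qs = adjust_pvalues([r.p_value for r in block], "bh")
        threshold = (config.ted_q_noncoding if category == "noncoding"
                     else config.ted_q_coding)
        for r, q in zip(block, qs):
            r.q_value = float(q)
            r.significant = bool(q < threshold)
    return results


def merge_cn_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping CN peaks per cancer type into one peak per region.

    ``peaks``: columns cancer_type, peak_type {amplification, deletion},
    chrom, start, end, summit, gene, treatment, q_value. Amplification and
    deletion peaks merge separately; the merged peak keeps the gene nearest
    the summit of its most significant member and the lowest-q treatment.
    """
    merged_rows = []
    for (cancer_type, peak_type, chrom), sub in peaks.groupby(
            ["cancer_type", "peak_type", "chrom"]):
        sub = sub.sort_values("start")
        cluster: list[pd.Series] = []
        cur_start, cur_end = None, None
        def flush():
            if not cluster:
                return
            block = pd.DataFrame(cluster)
            best = block.loc[block["q_value"].idxmin()]
            merged_rows.append({
                "cancer_type": cancer_type, "peak_type": peak_type, "chrom": chrom,
                "start": int(block["start"].min()), "end": int(block["end"].max()),
                "gene": best["gene"], "treatment": best["treatment"],
                "q_value": float(best["q_value"]),
            })
        for _, row in sub.iterrows():
            if cur_end is None or row["start"] < cur_end:  # overlap (half-open)
                cluster.append(row)
                cur_start = row["start"] if cur_start is None else cur_start
                cur_end = row["end"] if cur_end is None else max(cur_end, row["end"])
            else:
                flush()
                cluster = [row]
                cur_start, cur_end = row["start"], row["end"]
        flush()
    return pd.DataFrame(merged_rows, columns=["cancer_type", "peak_type", "chrom",
                                              "start", "end", "gene", "treatment",
                                              "q_value"])


def prioritize_teds(ted_results: list[TedResult],
                    curated_pairs: set[tuple[str, str, str]] | None = None
                    ) -> list[TedResult]:
    """One treatment association per (gene, cancer type, category).

    The minimum-q association wins unless ``curated_pairs`` pins a
    literature-reported (gene, cancer_type, mechanism_group) pairing.
    Curated winners are flagged ``known_resistance``.
    """
    curated_pairs = curated_pairs or set()
    significant = [r for r in ted_results if r.significant]
    chosen: dict[tuple, TedResult] = {}
    for r in significant:
        key = (r.gene, r.cancer_type, r.alteration_category)
        pinned = (r.gene, r.cancer_type, r.mechanism_group) in curated_pairs
        if pinned:
            r.known_resistance = True
        current = chosen.get(key)
        if current is None:
            chosen[key] = r
        elif pinned and not current.known_resistance:
            chosen[key] = r
        elif not pinned and not current.known_resistance \
                and r.q_value < current.q_value:
            chosen[key] = r
    return sorted(chosen.values(), key=lambda r: (r.cancer_type, r.gene, r.q_value))


def ted_catalogue_frame(results: list[TedResult]) -> pd.DataFrame:
    cols = ["gene", "alteration_category", "cancer_type", "mechanism_group",
            "n_treated_mutated", "n_treated", "n_untreated_mutated", "n_untreated",
            "odds_ratio", "p_value", "q_value", "significant", "label",
            "known_resistance"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results],
                        columns=cols)


def recount_excluding_teds(drivers: pd.DataFrame, samples: pd.DataFrame,
                           ted_catalogue: pd.DataFrame,
                           config: Config = Config()) -> pd.DataFrame:
    """Per-cohort mean drivers/sample before and after TED exclusion.

    TEDs are excluded in a cancer-type-, gene- and alteration-category-
    specific manner before recounting.
    """
    retained = retained_drivers(drivers, config).copy()
    retained["category"] = retained["alteration_type"].map(_alteration_category)
    merged = retained.merge(samples[["sample_id", "cohort", "cancer_type"]],
                            on="sample_id")
    if len(ted_catalogue):
        ted_keys = set(zip(ted_catalogue["cancer_type"], ted_catalogue["gene"],
                           ted_catalogue["alteration_category"]))
        keys = list(zip(merged["cancer_type"], merged["gene"], merged["category"]))
        kept = merged[[k not in ted_keys for k in keys]]
    else:
        kept = merged
    rows = []
    for cohort, cohort_samples in samples.groupby("cohort"):
        n = len(cohort_samples)
        before = merged[merged["cohort"] == cohort].groupby("sample_id")["gene"].nunique()
        after = kept[kept["cohort"] == cohort].groupby("sample_id")["gene"].nunique()
        rows.append({"cohort": cohort,
                     "mean_drivers_before": float(before.sum()) / n if n else np.nan,
                     "mean_drivers_after": float(after.sum()) / n if n else np.nan})
    return pd.DataFrame(rows, columns=["cohort", "mean_drivers_before",
                                       "mean_drivers_after"])


def candidate_elements(drivers: pd.DataFrame, samples: pd.DataFrame,
                       group: TreatmentGroup,
                       config: Config = Config()) -> tuple[pd.DataFrame, dict]:
    """Frequency-based stand-in for formal driver discovery.

    Candidates are (gene, category) pairs altered in at least
    ``ted_candidate_min_altered`` treated patients. Externally produced
    candidate lists (e.g. from dedicated coding/non-coding/CN driver
    discovery tools) can be passed straight to :func:`ted_test` instead.
    Returns the candidate table plus the (gene, category) -> altered-patient
    mapping for the whole cancer type.
    """
    retained = retained_drivers(drivers, config).copy()
    retained["category"] = retained["alteration_type"].map(_alteration_category)
    merged = retained.merge(samples[["sample_id", "patient_id", "cancer_type"]],
                            on="sample_id")
    merged = merged[merged["cancer_type"] == group.cancer_type]
    altered: dict[tuple, frozenset] = {
        key: frozenset(sub["patient_id"])
        for key, sub in merged.groupby(["gene", "category"])
    }
    rows = [{"gene": gene, "alteration_category": category}
            for (gene, category), patients in sorted(altered.items())
            if len(patients & group.patients) >= config.ted_candidate_min_altered]
    return pd.DataFrame(rows, columns=["gene", "alteration_category"]), altered


def run_ted_analysis(dataset, config: Config = Config(),
                     mechanism_map: dict[str, str] | None = None,
                     curated_pairs: set | None = None):
    """Full TED screen over all qualifying treatment groups."""
    samples, treatments, drivers = dataset.samples, dataset.treatments, dataset.drivers
    if treatments is None or drivers is None:
        raise ValueError("TED analysis needs treatments and drivers tables")
    groups = build_treatment_groups(treatments, samples, mechanism_map, config)
    all_results: list[TedResult] = []
    for group in groups:
        untreated = _untreated_patients(group, treatments, samples, config)
        if not untreated:
            logger.warning("no untreated comparison group for %s/%s",
                           group.cancer_type, group.mechanism_group)
            continue
        cands, altered = candidate_elements(drivers, samples, group, config)
        if cands.empty:
            continue
        all_results.extend(ted_test(cands, group, untreated, altered, config))
    catalogue = prioritize_teds(all_results, curated_pairs)
    return ted_catalogue_frame(all_results), ted_catalogue_frame(catalogue)
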