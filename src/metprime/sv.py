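"""Structural-variant burden: seven-class taxonomy, cohort comparison and
the three-linear-model feature-association screen.

Upstream SV clusters arrive with a resolved type. Deletions and
duplications with intrachromosomal breakpoints are split at 10 kb
(small/large); complex, inversion and translocation types are pooled as
"complex" and split at 20 breakpoint junctions; LINE insertions form their
own class. Burden per class is compared between cohorts (Mann-Whitney,
Bonferroni, significant at q < 0.05 with fold change outside [0.8, 1.2] on
pseudocounted medians).

Where the metastatic burden is significantly increased, log10(burden+1) is
regressed on genomic and treatment features with three ordinary
least-squares models — combined, metastatic-only and primary-only — and a
feature "explains" the increase only when it passes the combined model's
filters (regression P < 0.01, coefficient P < 0.01, coefficient > 0) AND
repeats the positive association within a single cohort, which screens out
features that merely differ between cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import Config
from .stats import adjust_pvalues, cliffs_delta, mann_whitney_two_sided, signed_cramers_v

logger = logging.getLogger("metprime")

SV_TYPES = ("del_small", "del_large", "dup_small", "dup_large",
            "complex_small", "complex_large", "line")

COMPLEX_TOKENS = frozenset({
    "COMPLEX",
    "INV", "FB_INV_PAIR", "RECIP_INV", "RECIP_INV_DEL_DUP", "RECIP_INV_DUPS",
    "RECIP_TRANS", "RECIP_TRANS_DEL_DUP", "RECIP_TRANS_DUPS",
    "UNBAL_TRANS", "UNBAL_TRANS_TI",
})


def classify_sv_cluster(resolved_type: str, n_sv: int, chrom_start: str,
                        chrom_end: str, length_bp: int,
                        config: Config = Config()) -> str | None:
    """Map one SV cluster to one of the seven burden classes.

    DEL/DUP require intrachromosomal breakpoints; small means length below
    ``sv_small_max_bp``. Complex covers COMPLEX plus all inversion and
    translocation tokens; large means ``n_sv`` at or above
    ``sv_complex_large_min``. Returns None for unclassified tokens (dropped
    from the seven counts and the total).
    """
    token = str(resolved_type).upper()
    if token in ("DEL", "DUP"):
        if str(chrom_start) != str(chrom_end):
            return None
        size = "small" if length_bp < config.sv_small_max_bp else "large"
        return f"{'del' if token == 'DEL' else 'dup'}_{size}"
    if token in COMPLEX_TOKENS:
        return f"complex_{'large' if n_sv >= config.sv_complex_large_min else 'small'}"
    if token == "LINE":
        return "line"
    return None


def sv_type_counts(sv_clusters: pd.DataFrame, sample_ids,
                   config: Config = Config()) -> pd.DataFrame:
    """Per-sample counts of the seven SV classes plus the total.

    Samples without clusters get zero counts.
    """
    classes = [
        classify_sv_cluster(r.resolved_type, r.n_sv, r.chrom_start, r.chrom_end,
                            r.length_bp, config)
        for r in sv_clusters.itertuples()
    ]
    tab = sv_clusters.assign(sv_class=classes).dropna(subset=["sv_class"])
    counts = (tab.groupby(["sample_id", "sv_class"]).size().unstack(fill_value=0)
              .reindex(columns=SV_TYPES, fill_value=0)
              .reindex(pd.Index(sample_ids, name="sample_id"), fill_value=0))
    counts["total"] = counts[list(SV_TYPES)].sum(axis=1)
    return counts.reset_index()


def compare_sv_burden(counts: pd.DataFrame, samples: pd.DataFrame,
                      config: Config = Config()) -> pd.DataFrame:
    """Metastatic vs primary burden per cancer type and SV class.

    Two-sided Mann-Whitney per (cancer type, class); Bonferroni over all
    tests. Relative enrichment = log10(median_met+1) - log10(median_pri+1);
    fold change = (median_met+1)/(median_pri+1); the '>' display flag marks
    a zero primary median. Significant iff q < ``sv_q`` and fold change
    >= ``sv_fc_high`` or <= ``sv_fc_low``.
    """
    merged = counts.merge(samples[["sample_id", "cohort", "cancer_type"]], on="sample_id")
    rows = []
    for cancer_type, sub in merged.groupby("cancer_type"):
        met = sub[sub["cohort"] == "metastatic"]
        pri = sub[sub["cohort"] == "primary"]
        if len(met) == 0 or len(pri) == 0:
            continue
        for sv_type in SV_TYPES:
            x = met[sv_type].to_numpy(dtype=float)
            y = pri[sv_type].to_numpy(dtype=float)
            res = mann_whitney_two_sided(x, y)
            med_m, med_p = float(np.median(x)), float(np.median(y))
            fold = (med_m + 1) / (med_p + 1)
            rows.append({
                "cancer_type": cancer_type, "sv_type": sv_type,
                "median_metastatic": med_m, "median_primary": med_p,
                "relative_enrichment": np.log10(med_m + 1) - np.log10(med_p + 1),
                "fold_change": fold, "fold_change_gt_flag": med_p == 0,
                "statistic_u": res.statistic, "p_value": res.p_value,
            })
    result = pd.DataFrame(rows, columns=["cancer_type", "sv_type", "median_metastatic",
                                         "median_primary", "relative_enrichment",
                                         "fold_change", "fold_change_gt_flag",
                                         "statistic_u", "p_value"])
    if len(result):
        result["q_value"] = adjust_pvalues(result["p_value"], "bonferroni")
        result["significant"] = (result["q_value"] < config.sv_q) & (
            (result["fold_change"] >= config.sv_fc_high)
            | (result["fold_change"] <= config.sv_fc_low)
        )
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


def build_feature_matrix(samples: pd.DataFrame,
                         treatments: pd.DataFrame | None,
                         drivers: pd.DataFrame | None,
                         gene_list: list[str] | None = None,
                         config: Config = Config()) -> pd.DataFrame:
    """Sample x feature design for the SV regressions.

    Numeric features: genome_ploidy, n_treatments. Boolean (0/1): hrd, msi,
    one column per treatment mechanism group, and gene status per gene
    (restricted to ``gene_list`` when given — the fragile-site-excluded
    catalogue is supplied as data, not code). Treatment features are forced
    to zero for primaries and for metastatic samples without treatment
    records.
    """
    idx = pd.Index(samples["sample_id"], name="sample_id")
    feat = pd.DataFrame(index=idx)
    feat["genome_ploidy"] = samples.set_index("sample_id")["genome_ploidy"]
    feat["hrd"] = samples.set_index("sample_id")["hrd"].astype(int)
    feat["msi"] = samples.set_index("sample_id")["msi"].astype(int)
    cohort = samples.set_index("sample_id")["cohort"]
    feat["n_treatments"] = 0
    if treatments is not None and len(treatments):
        pre = treatments[treatments["pre_biopsy"].astype(bool)]
        n_mech = pre.groupby("sample_id")["mechanism_group"].nunique()
        feat.loc[feat.index.isin(n_mech.index), "n_treatments"] = n_mech
        for mech, grp in pre.groupby("mechanism_group"):
            col = f"treat_{mech}"
            feat[col] = 0
            feat.loc[feat.index.isin(grp["sample_id"]), col] = 1
        treat_cols = ["n_treatments"] + [c for c in feat.columns if c.startswith("treat_")]
        feat.loc[cohort == "primary", treat_cols] = 0  # primaries deemed untreated
    if drivers is not None and len(drivers):
        retained = drivers[drivers["driver_likelihood"] > config.driver_likelihood_min]
        genes = gene_list if gene_list is not None else sorted(retained["gene"].unique())
        for gene in genes:
            col = f"gene_{gene}"
            feat[col] = 0
            feat.loc[feat.index.isin(
                retained.loc[retained["gene"] == gene, "sample_id"]), col] = 1
    return feat.fillna(0)


@dataclass
class LmAssociation:
    feature: str
    coefficient: float
    coefficient_p: float
    passed_combined: bool
    passed_cohort_specific: bool
    effect_size: float
    explains_met_increase: bool


def _prevalence_filter(features: pd.DataFrame, min_gene_true: int,
                       min_frac: float) -> pd.DataFrame:
    """Drop sparse boolean features; numeric features always kept."""
    keep = []
    n = len(features)
    for col in features.columns:
        values = features[col]
        is_bool = set(np.unique(values)) <= {0, 1}
        if not is_bool:
            keep.append(col)
            continue
        n_true = int(values.sum())
        if col.startswith("gene_") and n_true < min_gene_true:
            continue
        if n_true < min_frac * n:
            continue
        keep.append(col)
    return features[keep]


def _fit_ols(y: np.ndarray, x: pd.DataFrame):
    """OLS with intercept; aliased (constant or collinear) columns dropped."""
    x = x.loc[:, x.std() > 0]
    design = sm.add_constant(x.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.OLS(y, design).fit()
    return model, list(x.columns)


def fit_three_lms(burden: pd.Series, features: pd.DataFrame, cohort: pd.Series,
                  config: Config = Config()) -> list[LmAssociation]:
    """The combined / metastatic-only / primary-only regression screen.

    ``burden`` are raw counts (log10(x+1) applied here); all three inputs
    are indexed by sample_id. Returns one association record per feature
    surviving the combined model's prevalence filter.
    """
    if len(burden) < config.lm_min_samples:
        raise ValueError(f"need at least {config.lm_min_samples} samples")
    y_all = np.log10(burden.to_numpy(dtype=float) + 1)
    feats = features.loc[burden.index]
    cohort = cohort.loc[burden.index]
    if config.standardize_numeric:
        for col in feats.columns:
            if set(np.unique(feats[col])) - {0, 1} and feats[col].std() > 0:
                feats[col] = (feats[col] - feats[col].mean()) / feats[col].std()

    combined_feats = _prevalence_filter(feats, config.gene_min_true_combined,
                                        config.bool_min_true_fraction)
    model_c, cols_c = _fit_ols(y_all, combined_feats)
    regression_ok = model_c.f_pvalue < config.lm_regression_p

    cohort_models = {}
    for label in ("metastatic", "primary"):
        mask = (cohort == label).to_numpy()
        if mask.sum() < 3:
            continue
        sub_feats = _prevalence_filter(feats[mask], config.gene_min_true_cohort,
                                       config.bool_min_true_fraction)
        if sub_feats.shape[1] == 0:
            continue
        cohort_models[label] = _fit_ols(y_all[mask], sub_feats)

    met_mask = (cohort == "metastatic").to_numpy()
    out = []
    for col in cols_c:
        coef = float(model_c.params[col])
        coef_p = float(model_c.pvalues[col])
        passed_combined = bool(regression_ok and coef_p < config.lm_coef_p and coef > 0)
        passed_cohort = False
        for label, (model, cols) in cohort_models.items():
            if col in cols and float(model.pvalues[col]) < config.lm_coef_p \
                    and float(model.params[col]) > 0:
                passed_cohort = True
                break
        values = feats[col]
        met_vals = values[met_mask].to_numpy(dtype=float)
        pri_vals = values[~met_mask].to_numpy(dtype=float)
        effect = feature_effect_direction(met_vals, pri_vals)
        out.append(LmAssociation(
            feature=col, coefficient=coef, coefficient_p=coef_p,
            passed_combined=passed_combined, passed_cohort_specific=passed_cohort,
            effect_size=effect,
            explains_met_increase=bool(passed_combined and passed_cohort and effect > 0),
        ))
    return out


def feature_effect_direction(met_values: np.ndarray, pri_values: np.ndarray) -> float:
    """Cohort-enrichment effect size: Cliff's delta for numeric features,
    signed Cramér's V for booleans; positive = metastatic-enriched."""
    met_values = np.asarray(met_values, dtype=float)
    pri_values = np.asarray(pri_values, dtype=float)
    pooled = np.unique(np.concatenate([met_values, pri_values]))
    if set(pooled) <= {0.0, 1.0}:
        table = [[int(met_values.sum()), int((met_values == 0).sum())],
                 [int(pri_values.sum()), int((pri_values == 0).sum())]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return signed_cramers_v(table)
    return cliffs_delta(met_values, pri_values)


def run_sv_analysis(dataset, config: Config = Config(),
                    gene_list: list[str] | None = None):
    """Burden comparison plus the LM screen for significantly increased
    (cancer type, SV class) pairs. Returns (counts, comparison, associations)."""
    samples = dataset.samples
    counts = sv_type_counts(dataset.sv_clusters, samples["sample_id"], config)
    comparison = compare_sv_burden(counts, samples, config)
    features = build_feature_matrix(samples, dataset.treatments, dataset.drivers,
                                    gene_list, config)
    cohort = samples.set_index("sample_id")["cohort"]
    assoc_rows = []
    increased = comparison[comparison["significant"]
                           & (comparison["fold_change"] >= config.sv_fc_high)]
    for _, hit in increased.iterrows():
        ct_samples = samples.loc[samples["cancer_type"] == hit["cancer_type"], "sample_id"]
        burden = counts.set_index("sample_id").loc[ct_samples, hit["sv_type"]]
        try:
            assocs = fit_three_lms(burden, features, cohort, config)
        except ValueError as exc:
            logger.warning("sv lm %s/%s: %s", hit["cancer_type"], hit["sv_type"], exc)
            continue
        for a in assocs:
            if a.explains_met_increase:
                assoc_rows.append({"cancer_type": hit["cancer_type"],
                                   "sv_type": hit["sv_type"], **a.__dict__})
    associations = pd.DataFrame(
        assoc_rows, columns=["cancer_type", "sv_type", "feature", "coefficient",
                             "coefficient_p", "passed_combined",
                             "passed_cohort_specific", "effect_size",
                             "explains_met_increase"])
    return counts, comparison, associations
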