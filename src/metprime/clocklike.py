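"""Clock-like SBS1 mutation-rate analysis.

SBS1 mutations (C>T at NpCpG, deamination of methylated cytosine)
accumulate roughly linearly with age. Per cancer type and cohort, SBS1
burden is regressed on age at biopsy via a subsampling scheme: 100 ordinary
least-squares fits on random 75% subsets, the fit with the median slope
kept as representative and the 1st/99th percentile fits as confidence
bands. Cohorts whose regressions both show a positive trend (Pearson r >
0.1) are compared by Mann-Whitney on the residuals of both cohorts against
the *primary* fit; a shift is called significant at P < 0.01 when the
metastatic intercept also exceeds the primary one. Effect sizes are the
mean prediction ratio (fold change) and difference over ages 40..80.

SBS1 counting excludes the TpCpG peak (shared with APOBEC/SBS2) and, for
skin melanoma, also CpCpG (shared with UV/SBS7a). Hypermutators (TMB >
30,000 or SBS1 > 5,000) are excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .config import Config
from .stats import TestResult, mann_whitney_two_sided

logger = logging.getLogger("metprime")

SBS1_CONTEXTS = ("ACG", "CCG", "GCG")  # NpCpG minus the TCG (APOBEC) peak
MELANOMA_EXTRA_EXCLUDED = ("CCG",)     # overlaps the UV SBS7a peak
MELANOMA_TYPES = frozenset({"skin melanoma", "melanoma", "skin_melanoma"})


def sbs1_contexts_for(cancer_type: str) -> tuple[str, ...]:
    contexts = SBS1_CONTEXTS
    if cancer_type.strip().lower() in MELANOMA_TYPES:
        contexts = tuple(c for c in contexts if c not in MELANOMA_EXTRA_EXCLUDED)
    return contexts


def count_sbs1(mutations: pd.DataFrame, cancer_type: str) -> int:
    """Count C>T mutations in the SBS1-characteristic NpCpG contexts."""
    contexts = sbs1_contexts_for(cancer_type)
    sbs = mutations[mutations["variant_class"] == "SBS"]
    mask = (sbs["ref"] == "C") & (sbs["alt"] == "T") & sbs["context"].isin(contexts)
    return int(mask.sum())


def filter_clock_samples(table: pd.DataFrame, config: Config = Config()) -> pd.DataFrame:
    """Drop hypermutators: TMB > 30,000 or SBS1 burden > 5,000 (both strict).

    ``table`` needs columns tmb and sbs1_count.
    """
    keep = (table["tmb"] <= config.tmb_exclude_above) & (
        table["sbs1_count"] <= config.sbs1_exclude_above
    )
    return table[keep]


@dataclass
class RegressionFit:
    """Representative subsampled age regression for one cancer type/cohort."""

    slope: float            # mutations per year
    intercept: float        # mutations at age 0
    pearson_r: float        # Pearson r of burden vs age on all points
    ci_lower_slope: float
    ci_lower_intercept: float
    ci_upper_slope: float
    ci_upper_intercept: float
    n_samples: int

    def predict(self, ages) -> np.ndarray:
        return self.slope * np.asarray(ages, dtype=float) + self.intercept


def bootstrap_regression(ages, counts, n_boot: int = 100, frac: float = 0.75,
                         seed: int | np.random.Generator = 0,
                         min_points: int = 20) -> RegressionFit:
    """Subsampled linear regression of mutation count on age.

    ``n_boot`` OLS fits on random ``frac`` subsets drawn without
    replacement; the representative fit is the one with the median slope
    (lower median for even counts), so it is always an actually fitted
    line. Confidence bands come from the fits at the 1st and 99th slope
    percentiles. Deterministic given the seed.
    """
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if ages.shape != counts.shape or ages.ndim != 1:
        raise ValueError("ages and counts must be equal-length 1-D arrays")
    n = ages.size
    if n < min_points:
        raise ValueError(f"need at least {min_points} points, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = max(2, int(round(frac * n)))
    fits = np.empty((n_boot, 2))
    for i in range(n_boot):
        idx = rng.choice(n, size=k, replace=False)
        slope, intercept = np.polyfit(ages[idx], counts[idx], 1)
        fits[i] = slope, intercept
    order = np.argsort(fits[:, 0], kind="stable")
    median_idx = order[(n_boot - 1) // 2]          # lower median for even n_boot
    lo_idx = order[int(np.floor(0.01 * (n_boot - 1)))]
    hi_idx = order[int(np.ceil(0.99 * (n_boot - 1)))]
    if np.all(ages == ages[0]) or np.all(counts == counts[0]):
        r = 0.0
    else:
        r = float(scipy.stats.pearsonr(ages, counts)[0])
    return RegressionFit(
        slope=float(fits[median_idx, 0]), intercept=float(fits[median_idx, 1]),
        pearson_r=r,
        ci_lower_slope=float(fits[lo_idx, 0]), ci_lower_intercept=float(fits[lo_idx, 1]),
        ci_upper_slope=float(fits[hi_idx, 0]), ci_upper_intercept=float(fits[hi_idx, 1]),
        n_samples=n,
    )


def _age_grid(config: Config) -> np.ndarray:
    return np.arange(config.fc_age_min, config.fc_age_max + 1)


def _divisor(config: Config) -> float:
    # the published equations print a 1/40 coefficient over the 41 integer
    # ages 40..80; the default uses the true mean (divide by 41)
    n_terms = config.fc_age_max - config.fc_age_min + 1
    return float(config.fc_age_max - config.fc_age_min) if config.literal_1_over_40 \
        else float(n_terms)


def mean_fold_change(met_fit: RegressionFit, pri_fit: RegressionFit,
                     config: Config = Config()) -> float:
    """Mean ratio of metastatic to primary predicted burden over ages 40..80."""
    ages = _age_grid(config)
    pri = pri_fit.predict(ages)
    if (pri <= 0).any():
        raise ValueError("primary prediction non-positive within the age range")
    return float(np.sum(met_fit.predict(ages) / pri) / _divisor(config))


def mean_burden_diff(met_fit: RegressionFit, pri_fit: RegressionFit,
                     config: Config = Config()) -> float:
    """Mean difference of predicted burdens over ages 40..80."""
    ages = _age_grid(config)
    return float(np.sum(met_fit.predict(ages) - pri_fit.predict(ages)) / _divisor(config))


@dataclass
class ClockRateComparison:
    cancer_type: str
    gate_passed: bool
    mw_p: float
    significant: bool
    mean_fold_change: float
    mean_burden_diff: float
    primary_fit: RegressionFit | None = None
    metastatic_fit: RegressionFit | None = None


def compare_rates(pri_fit: RegressionFit, met_fit: RegressionFit,
                  pri_points: tuple[np.ndarray, np.ndarray],
                  met_points: tuple[np.ndarray, np.ndarray],
                  cancer_type: str = "", config: Config = Config()) -> ClockRateComparison:
    """Test for a metastatic upward shift of the SBS1-age regression.

    Gate: both cohort regressions must show Pearson r > ``pearson_gate``.
    Both cohorts' residuals are taken against the PRIMARY fit and compared
    two-sided by Mann-Whitney; significant iff the gate passed, P <
    ``clock_p_threshold`` and the metastatic intercept exceeds the primary.
    """
    gate = (pri_fit.pearson_r > config.pearson_gate
            and met_fit.pearson_r > config.pearson_gate)
    pri_ages, pri_counts = (np.asarray(a, dtype=float) for a in pri_points)
    met_ages, met_counts = (np.asarray(a, dtype=float) for a in met_points)
    res_pri = pri_counts - pri_fit.predict(pri_ages)
    res_met = met_counts - pri_fit.predict(met_ages)
    mw = mann_whitney_two_sided(res_met, res_pri)
    significant = bool(gate and mw.p_value < config.clock_p_threshold
                       and met_fit.intercept > pri_fit.intercept)
    try:
        fc = mean_fold_change(met_fit, pri_fit, config)
    except ValueError:
        fc = float("nan")
    return ClockRateComparison(
        cancer_type=cancer_type, gate_passed=bool(gate), mw_p=mw.p_value,
        significant=significant, mean_fold_change=fc,
        mean_burden_diff=mean_burden_diff(met_fit, pri_fit, config),
        primary_fit=pri_fit, metastatic_fit=met_fit,
    )


def assign_clocklike_ml(channel: str, exposures: dict[str, float],
                        channel_probs: dict[str, float]) -> str | None:
    """Maximum-likelihood assignment of one mutation to a signature.

    ``exposures`` maps signature name to the sample's exposure;
    ``channel_probs`` maps signature name to that signature's probability of
    the mutation's channel. The winner maximises exposure x channel
    probability; ties break lexicographically; returns None when every
    likelihood is zero.
    """
    scores = {name: exposures.get(name, 0.0) * channel_probs.get(name, 0.0)
              for name in exposures}
    best = max(sorted(scores), key=lambda k: scores[k], default=None)
    if best is None or scores[best] <= 0.0:
        return None
    return best


def sbs1_clonality_ratio(mutations: pd.DataFrame, cancer_type: str,
                         threshold: float = 0.8) -> float | None:
    """(clonal SBS1 / SBS1) divided by (clonal total / total).

    Returns None (sample excluded) when the sample has no SBS1 mutations,
    no mutations at all, or no clonal mutations.
    """
    if mutations.empty:
        return None
    contexts = sbs1_contexts_for(cancer_type)
    clonal = mutations["subclonal_likelihood"] < threshold
    sbs = mutations["variant_class"] == "SBS"
    is_sbs1 = sbs & (mutations["ref"] == "C") & (mutations["alt"] == "T") & \
        mutations["context"].isin(contexts)
    n_sbs1 = int(is_sbs1.sum())
    n_total = len(mutations)
    if n_sbs1 == 0 or n_total == 0:
        return None
    overall = clonal.sum() / n_total
    if overall == 0:
        return None
    return float((clonal & is_sbs1).sum() / n_sbs1 / overall)


def rate_vs_foldchange(primary_rates: pd.DataFrame,
                       fold_changes: pd.DataFrame) -> TestResult | None:
    """Spearman correlation of primary SBS1 yearly rate vs metastatic fold change.

    ``primary_rates``: columns cancer_type, rate (mean per-sample SBS1/age
    among primaries). ``fold_changes``: columns cancer_type,
    mean_fold_change. Requires at least 4 shared cancer types; returns None
    with a warning when the correlation is undefined (constant input).
    """
    merged = primary_rates.merge(fold_changes, on="cancer_type")
    if len(merged) < 4:
        raise ValueError("need at least 4 cancer types for the rate correlation")
    x = merged["rate"].to_numpy(dtype=float)
    y = merged["mean_fold_change"].to_numpy(dtype=float)
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("rate correlation undefined on constant input")
        return None
    rho, p = scipy.stats.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), effect_size=float(rho))


def primary_sbs1_rates(clock_table: pd.DataFrame,
                       config: Config = Config()) -> pd.DataFrame:
    """Per-cancer-type mean of per-sample SBS1 count / age among primaries.

    ``clock_table`` has columns sample_id, cohort, cancer_type,
    age_at_biopsy, sbs1_count, tmb. The hypermutator filter applies.
    """
    pri = clock_table[clock_table["cohort"] == "primary"]
    pri = filter_clock_samples(pri, config)
    pri = pri[pri["age_at_biopsy"] > 0]
    rates = pri.assign(rate=pri["sbs1_count"] / pri["age_at_biopsy"])
    return rates.groupby("cancer_type", as_index=False)["rate"].mean()


def build_clock_table(mutations: pd.DataFrame, samples: pd.DataFrame,
                      ploidy_correct: bool = False) -> pd.DataFrame:
    """Per-sample SBS1 count and total mutation burden for the regression.

    With ``ploidy_correct`` the counts are divided by the sample's genome
    ploidy (correction commutes with the regression assembly).
    """
    rows = []
    meta = samples.set_index("sample_id")
    for sample_id, sub in mutations.groupby("sample_id"):
        if sample_id not in meta.index:
            continue
        info = meta.loc[sample_id]
        sbs1 = count_sbs1(sub, str(info["cancer_type"]))
        tmb = len(sub)
        denom = float(info["genome_ploidy"]) if ploidy_correct else 1.0
        rows.append({"sample_id": sample_id, "cohort": info["cohort"],
                     "cancer_type": info["cancer_type"],
                     "age_at_biopsy": float(info["age_at_biopsy"]),
                     "sbs1_count": sbs1 / denom, "tmb": tmb})
    return pd.DataFrame(rows, columns=["sample_id", "cohort", "cancer_type",
                                       "age_at_biopsy", "sbs1_count", "tmb"])


def run_clock_analysis(clock_table: pd.DataFrame, config: Config = Config(),
                       seed: int = 0) -> tuple[pd.DataFrame, list[ClockRateComparison]]:
    """Per-cancer-type SBS1-age regression comparison.

    ``clock_table`` columns: sample_id, cohort, cancer_type, age_at_biopsy,
    sbs1_count, tmb. Returns a tidy fit/comparison table plus the raw
    comparison objects.
    """
    filtered = filter_clock_samples(clock_table, config)
    rows, comparisons = [], []
    rng = np.random.default_rng(seed)
    for cancer_type, sub in filtered.groupby("cancer_type"):
        fits = {}
        points = {}
        for cohort in ("primary", "metastatic"):
            grp = sub[sub["cohort"] == cohort]
            points[cohort] = (grp["age_at_biopsy"].to_numpy(dtype=float),
                              grp["sbs1_count"].to_numpy(dtype=float))
            try:
                fits[cohort] = bootstrap_regression(
                    *points[cohort], n_boot=config.n_bootstrap,
                    frac=config.bootstrap_fraction, seed=rng,
                    min_points=config.min_clock_points)
            except ValueError as exc:
                logger.warning("clock %s/%s: %s", cancer_type, cohort, exc)
        if len(fits) < 2:
            continue
        comp = compare_rates(fits["primary"], fits["metastatic"],
                             points["primary"], points["metastatic"],
                             cancer_type, config)
        comparisons.append(comp)
        rows.append({
            "cancer_type": cancer_type,
            "primary_slope": fits["primary"].slope,
            "primary_intercept": fits["primary"].intercept,
            "primary_r": fits["primary"].pearson_r,
            "metastatic_slope": fits["metastatic"].slope,
            "metastatic_intercept": fits["metastatic"].intercept,
            "metastatic_r": fits["metastatic"].pearson_r,
            "gate_passed": comp.gate_passed, "mw_p": comp.mw_p,
            "significant": comp.significant,
            "mean_fold_change": comp.mean_fold_change,
            "mean_burden_diff": comp.mean_burden_diff,
        })
    columns = ["cancer_type", "primary_slope", "primary_intercept", "primary_r",
               "metastatic_slope", "metastatic_intercept", "metastatic_r",
               "gate_passed", "mw_p", "significant", "mean_fold_change",
               "mean_burden_diff"]
    return pd.DataFrame(rows, columns=columns), comparisons
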