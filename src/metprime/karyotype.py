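"""Arm-level karyotype scoring with WGD normalization, plus the four
genomic-instability indicators.

Karyotype scoring proceeds in four steps per sample:

1. *Arm-level ploidy*: each purity/ploidy-adjusted copy-number segment is
   rounded to the nearest integer CN (half away from zero); the arm ploidy
   is the integer CN covering the largest fraction of the arm.
2. *Observed genome ploidy*: the most recurrent arm ploidy across all arms.
3. *Expected genome ploidy*: 2 without whole-genome duplication (WGD); with
   WGD, 4 when the observed genome ploidy is below six and 8 otherwise.
4. *Normalized arm class*: the arm ploidy minus the expected genome ploidy,
   thresholded to -1 (loss), 0, +1 (gain).

The four instability indicators are the aneuploidy score (arms deviating
from the expected genome ploidy), the LOH fraction (genome share with minor
allele CN < 0.25 and major allele CN >= 0.8), WGD status (more than 10
autosomes with chromosome CN above 1.5) and TP53 driver status.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .config import Config
from .stats import adjust_pvalues, fisher_exact_two_sided, mann_whitney_two_sided

logger = logging.getLogger("metprime")

AUTOSOMES = tuple(str(i) for i in range(1, 23))


def round_half_away(x: float) -> int:
    """2.5 -> 3, 3.5 -> 4; deterministic alternative to banker's rounding."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def arm_modal_ploidy(segments: pd.DataFrame, arm: pd.Series | dict,
                     tie_lower: bool = True) -> int:
    """Integer CN with the highest base coverage across a chromosome arm.

    Segment CNs are rounded to integers first; coverage is the overlapped
    base fraction of the arm. Coverage ties break toward the lower CN by
    default (conservative against calling gains).
    """
    arm_chrom, arm_start, arm_end = str(arm["chrom"]), int(arm["start"]), int(arm["end"])
    on_chrom = segments[segments["chrom"].astype(str) == arm_chrom]
    starts = np.maximum(on_chrom["start"].to_numpy(), arm_start)
    ends = np.minimum(on_chrom["end"].to_numpy(), arm_end)
    lengths = np.clip(ends - starts, 0, None)
    mask = lengths > 0
    if not mask.any():
        raise ValueError(f"no segment overlaps arm {arm_chrom}{arm['arm']}")
    cns = np.array([round_half_away(v) for v in on_chrom["cn_total"].to_numpy()[mask]])
    coverage: dict[int, int] = {}
    for cn, length in zip(cns, lengths[mask]):
        coverage[cn] = coverage.get(cn, 0) + int(length)
    best = max(coverage.values())
    candidates = sorted(cn for cn, cov in coverage.items() if cov == best)
    return candidates[0] if tie_lower else candidates[-1]


def observed_genome_ploidy(arm_ploidies: dict[str, int],
                           segments: pd.DataFrame) -> int:
    """Most recurrent arm ploidy across arms.

    Ties break toward the value nearest the segment-length-weighted mean
    total CN (then toward the lower value).
    """
    values, counts = np.unique(list(arm_ploidies.values()), return_counts=True)
    best = counts.max()
    candidates = sorted(values[counts == best])
    if len(candidates) == 1:
        return int(candidates[0])
    lengths = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    mean_cn = float(np.average(segments["cn_total"].to_numpy(), weights=lengths))
    return int(min(candidates, key=lambda v: (abs(v - mean_cn), v)))


def expected_genome_ploidy(wgd: bool, observed: int) -> int:
    """Expected genome ploidy: 2 (no WGD), 4 (WGD, observed < 6), 8 (>= 6)."""
    if observed < 0:
        raise ValueError("observed genome ploidy must be nonnegative")
    if observed > 8:
        raise ValueError(f"observed genome ploidy {observed} exceeds the supported 8")
    if not wgd:
        return 2
    return 8 if observed >= 6 else 4


def normalized_arm_class(arm_ploidy: int, expected: int) -> int:
    """+1 for gains (diff >= 1), -1 for losses (diff <= -1), else 0."""
    diff = arm_ploidy - expected
    if diff >= 1:
        return 1
    if diff <= -1:
        return -1
    return 0


def build_arm_profiles(segments: pd.DataFrame, samples: pd.DataFrame,
                       arm_table: pd.DataFrame, config: Config = Config()) -> pd.DataFrame:
    """Per-sample, per-arm karyotype table.

    Columns: sample_id, arm (e.g. '5p'), arm_ploidy, observed_genome_ploidy,
    expected_genome_ploidy, normalized_class. Arms with no overlapping
    segment for a sample are skipped with a warning.
    """
    wgd_by_sample = samples.set_index("sample_id")["wgd"].to_dict()
    rows = []
    for sample_id, seg in segments.groupby("sample_id"):
        arm_ploidies: dict[str, int] = {}
        for _, arm in arm_table.iterrows():
            name = f"{arm['chrom']}{arm['arm']}"
            try:
                arm_ploidies[name] = arm_modal_ploidy(seg, arm, config.modal_tie_lower)
            except ValueError:
                logger.warning("sample %s: no segments on arm %s", sample_id, name)
        if not arm_ploidies:
            continue
        observed = observed_genome_ploidy(arm_ploidies, seg)
        expected = expected_genome_ploidy(bool(wgd_by_sample[sample_id]), observed)
        for name, ploidy in arm_ploidies.items():
            rows.append({
                "sample_id": sample_id, "arm": name, "arm_ploidy": ploidy,
                "observed_genome_ploidy": observed,
                "expected_genome_ploidy": expected,
                "normalized_class": normalized_arm_class(ploidy, expected),
            })
    return pd.DataFrame(rows, columns=["sample_id", "arm", "arm_ploidy",
                                       "observed_genome_ploidy",
                                       "expected_genome_ploidy", "normalized_class"])


def compare_arm_profiles(profiles: pd.DataFrame, samples: pd.DataFrame,
                         config: Config = Config()) -> pd.DataFrame:
    """Per cancer type and arm: metastatic vs primary arm gains/losses.

    Mann-Whitney on the normalized classes (raw arm ploidies when
    ``raw_arm_ploidy``), BH across arms within cancer type; significant iff
    q < ``karyotype_q`` AND |mean(met) - mean(primary)| > ``arm_diff_threshold``
    (strict).
    """
    value_col = "arm_ploidy" if config.raw_arm_ploidy else "normalized_class"
    merged = profiles.merge(samples[["sample_id", "cohort", "cancer_type"]], on="sample_id")
    results = []
    for cancer_type, ct_sub in merged.groupby("cancer_type"):
        rows = []
        for arm_name, sub in ct_sub.groupby("arm"):
            met = sub.loc[sub["cohort"] == "metastatic", value_col].to_numpy(dtype=float)
            pri = sub.loc[sub["cohort"] == "primary", value_col].to_numpy(dtype=float)
            if len(met) == 0 or len(pri) == 0:
                continue
            res = mann_whitney_two_sided(met, pri)
            rows.append({
                "cancer_type": cancer_type, "arm": arm_name,
                "mean_metastatic": met.mean(), "mean_primary": pri.mean(),
                "mean_difference": met.mean() - pri.mean(),
                "statistic_u": res.statistic, "p_value": res.p_value,
            })
        if not rows:
            continue
        block = pd.DataFrame(rows)
        block["q_value"] = adjust_pvalues(block["p_value"], "bh")
        block["significant"] = (block["q_value"] < config.karyotype_q) & (
            block["mean_difference"].abs() > config.arm_diff_threshold
        )
        results.append(block)
    if not results:
        return pd.DataFrame(columns=["cancer_type", "arm", "mean_metastatic",
                                     "mean_primary", "mean_difference", "statistic_u",
                                     "p_value", "q_value", "significant"])
    return pd.concat(results, ignore_index=True)


def aneuploidy_score(profile: pd.DataFrame) -> int:
    """Number of arms whose ploidy deviates from the expected genome ploidy."""
    return int((profile["arm_ploidy"] != profile["expected_genome_ploidy"]).sum())


def loh_fraction(segments: pd.DataFrame, genome_length: float,
                 config: Config = Config()) -> float:
    """Genome fraction under loss of heterozygosity.

    A segment is LOH when minor allele CN < ``loh_minor_max`` (strict) and
    major allele CN >= ``loh_major_min``.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    loh = (segments["cn_minor"] < config.loh_minor_max) & (
        segments["cn_major"] >= config.loh_major_min
    )
    total = (segments.loc[loh, "end"] - segments.loc[loh, "start"]).sum()
    return float(total / genome_length)


def chromosome_level_cn(segments: pd.DataFrame) -> pd.Series:
    """Length-weighted mean total CN per chromosome."""
    seg = segments.assign(length=segments["end"] - segments["start"])
    seg = seg.assign(weighted=seg["cn_total"] * seg["length"])
    grouped = seg.groupby(seg["chrom"].astype(str))
    return grouped["weighted"].sum() / grouped["length"].sum()


def call_wgd(chromosome_cn: pd.Series, config: Config = Config()) -> bool:
    """WGD iff more than ``wgd_min_autosomes`` autosomes have CN above
    ``wgd_cn_threshold`` (both strict)."""
    auto = chromosome_cn[chromosome_cn.index.astype(str).isin(AUTOSOMES)]
    return bool((auto > config.wgd_cn_threshold).sum() > config.wgd_min_autosomes)


def build_instability_indicators(profiles: pd.DataFrame, segments: pd.DataFrame,
                                 samples: pd.DataFrame, drivers: pd.DataFrame | None,
                                 arm_table: pd.DataFrame,
                                 config: Config = Config()) -> pd.DataFrame:
    """Per-sample aneuploidy score, LOH fraction, WGD call and TP53 status.

    WGD here is recomputed from chromosome-level CN (the indicator
    definition) rather than taken from the sample annotation. TP53 status is
    any retained TP53 driver event (likelihood > ``driver_likelihood_min``).
    """
    genome_length = float(arm_table.groupby("chrom")["end"].max().sum())
    tp53_samples: set = set()
    if drivers is not None and len(drivers):
        retained = drivers[drivers["driver_likelihood"] > config.driver_likelihood_min]
        tp53_samples = set(retained.loc[retained["gene"] == "TP53", "sample_id"])
    rows = []
    for sample_id in samples["sample_id"]:
        prof = profiles[profiles["sample_id"] == sample_id]
        seg = segments[segments["sample_id"] == sample_id]
        if prof.empty or seg.empty:
            continue
        rows.append({
            "sample_id": sample_id,
            "aneuploidy_score": aneuploidy_score(prof),
            "loh_fraction": loh_fraction(seg, genome_length, config),
            "wgd": call_wgd(chromosome_level_cn(seg), config),
            "tp53_altered": sample_id in tp53_samples,
        })
    return pd.DataFrame(rows, columns=["sample_id", "aneuploidy_score", "loh_fraction",
                                       "wgd", "tp53_altered"])


def compare_instability(indicators: pd.DataFrame, samples: pd.DataFrame,
                        config: Config = Config()) -> pd.DataFrame:
    """Cohort comparison of the four indicators, per cancer type.

    Mann-Whitney for aneuploidy score and LOH fraction; Fisher exact for the
    WGD and TP53-altered fractions; BH across cancer types per indicator;
    significant iff q < ``instability_q``.
    """
    merged = indicators.merge(samples[["sample_id", "cohort", "cancer_type"]],
                              on="sample_id")
    rows = []
    for cancer_type, sub in merged.groupby("cancer_type"):
        met = sub[sub["cohort"] == "metastatic"]
        pri = sub[sub["cohort"] == "primary"]
        if len(met) == 0 or len(pri) == 0:
            continue
        for indicator in ("aneuploidy_score", "loh_fraction"):
            res = mann_whitney_two_sided(met[indicator].to_numpy(dtype=float),
                                         pri[indicator].to_numpy(dtype=float))
            rows.append({"cancer_type": cancer_type, "indicator": indicator,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "effect_size": np.nan})
        for indicator in ("wgd", "tp53_altered"):
            table = [
                [int(met[indicator].sum()), int((~met[indicator]).sum())],
                [int(pri[indicator].sum()), int((~pri[indicator]).sum())],
            ]
            res = fisher_exact_two_sided(table)
            rows.append({"cancer_type": cancer_type, "indicator": indicator,
                         "statistic": res.statistic, "p_value": res.p_value,
                         "effect_size": res.effect_size})
    result = pd.DataFrame(rows, columns=["cancer_type", "indicator", "statistic",
                                         "p_value", "effect_size"])
    if len(result):
        result["q_value"] = np.nan
        for indicator, idx in result.groupby("indicator").groups.items():
            result.loc[idx, "q_value"] = adjust_pvalues(result.loc[idx, "p_value"], "bh")
        result["significant"] = result["q_value"] < config.instability_q
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
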