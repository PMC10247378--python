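"""Tumour clonality: clonal/subclonal classification and cohort comparison.

Each small variant carries an upstream subclonal likelihood; variants at or
above the subclonal threshold (default 0.8) are subclonal, the rest clonal.
A sample's clonal fraction is the clonal share of its total mutation burden
(SBS + MNV + ID). Cohorts are compared per cancer type with a two-sided
Mann-Whitney test, Benjamini-Hochberg corrected across cancer types
(significant at q < 0.05); metastatic biopsy-site groups (local / lymph /
distant) are compared pairwise among groups with at least five samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Config
from .stats import adjust_pvalues, mann_whitney_two_sided

logger = logging.getLogger("metprime")

CLONALITY_CLASSES = ("SBS", "MNV", "ID")  # classes counted in the total burden


@dataclass
class ClonalitySummary:
    sample_id: str
    n_clonal: int
    n_total: int

    @property
    def clonal_fraction(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_clonal / self.n_total


def classify_clonality(likelihood: float, threshold: float = 0.8) -> str:
    """'subclonal' iff subclonal likelihood >= threshold, else 'clonal'."""
    if not 0.0 <= likelihood <= 1.0:
        raise ValueError(f"subclonal likelihood out of [0,1]: {likelihood}")
    return "subclonal" if likelihood >= threshold else "clonal"


def sample_clonal_fractions(
    mutations: pd.DataFrame, threshold: float = 0.8
) -> pd.DataFrame:
    """Per-sample clonal fraction over SBS + MNV + ID records.

    Returns columns sample_id, n_clonal, n_total, clonal_fraction; samples
    with zero counted mutations get a null fraction and are excluded from
    the comparisons downstream.
    """
    counted = mutations[mutations["variant_class"].isin(CLONALITY_CLASSES)]
    grouped = counted.groupby("sample_id")["subclonal_likelihood"].agg(
        n_total="size", n_clonal=lambda s: int((s < threshold).sum())
    )
    grouped = grouped.reset_index()[["sample_id", "n_clonal", "n_total"]]
    grouped["clonal_fraction"] = np.where(
        grouped["n_total"] > 0, grouped["n_clonal"] / grouped["n_total"], np.nan
    )
    return grouped


def compare_clonality(
    fractions: pd.DataFrame, samples: pd.DataFrame, config: Config = Config()
) -> pd.DataFrame:
    """Primary vs metastatic clonal fraction, per cancer type.

    Two-sided Mann-Whitney, BH correction across cancer types; significant
    iff q < ``clonality_q``. Also reports log2(metastatic mean / primary
    mean). Cancer types present in only one cohort are skipped with a
    warning; samples with undefined fractions are dropped.
    """
    merged = fractions.merge(
        samples[["sample_id", "cohort", "cancer_type"]], on="sample_id"
    ).dropna(subset=["clonal_fraction"])
    rows = []
    for cancer_type, sub in merged.groupby("cancer_type"):
        met = sub.loc[sub["cohort"] == "metastatic", "clonal_fraction"].to_numpy()
        pri = sub.loc[sub["cohort"] == "primary", "clonal_fraction"].to_numpy()
        if len(met) < 2 or len(pri) < 2:
            logger.warning(
                "clonality: skipping %s (needs >=2 samples per cohort)", cancer_type
            )
            continue
        res = mann_whitney_two_sided(met, pri)
        ratio = np.log2(met.mean() / pri.mean()) if pri.mean() > 0 else np.nan
        rows.append({
            "cancer_type": cancer_type,
            "n_metastatic": len(met),
            "n_primary": len(pri),
            "statistic_u": res.statistic,
            "p_value": res.p_value,
            "log2_clonality_ratio": ratio,
        })
    result = pd.DataFrame(
        rows, columns=["cancer_type", "n_metastatic", "n_primary", "statistic_u",
                       "p_value", "log2_clonality_ratio"],
    )
    if len(result):
        result["q_value"] = adjust_pvalues(result["p_value"], "bh")
        result["significant"] = result["q_value"] < config.clonality_q
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


def compare_biopsy_sites(
    fractions: pd.DataFrame, samples: pd.DataFrame, config: Config = Config()
) -> pd.DataFrame:
    """Pairwise clonality comparison among metastatic biopsy-site groups.

    Only local / lymph / distant groups with at least ``biopsy_min_per_group``
    samples are compared (per cancer type); p-values are reported unadjusted
    unless ``biopsy_adjust`` is set.
    """
    met = samples[samples["cohort"] == "metastatic"]
    merged = fractions.merge(
        met[["sample_id", "cancer_type", "biopsy_site_class"]], on="sample_id"
    ).dropna(subset=["clonal_fraction"])
    merged = merged[merged["biopsy_site_class"].isin(("local", "lymph", "distant"))]
    rows = []
    for cancer_type, sub in merged.groupby("cancer_type"):
        groups = {
            site: g["clonal_fraction"].to_numpy()
            for site, g in sub.groupby("biopsy_site_class")
            if len(g) >= config.biopsy_min_per_group
        }
        for a, b in itertools.combinations(sorted(groups), 2):
            res = mann_whitney_two_sided(groups[a], groups[b])
            rows.append({
                "cancer_type": cancer_type, "group_a": a, "group_b": b,
                "n_a": len(groups[a]), "n_b": len(groups[b]),
                "statistic_u": res.statistic, "p_value": res.p_value,
            })
    result = pd.DataFrame(
        rows, columns=["cancer_type", "group_a", "group_b", "n_a", "n_b",
                       "statistic_u", "p_value"],
    )
    if config.biopsy_adjust and len(result):
        result["q_value"] = adjust_pvalues(result["p_value"], "bh")
    return result
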