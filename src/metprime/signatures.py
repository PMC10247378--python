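"""Mutational-signature aetiology assignment and cohort exposure comparison.

De novo signature profiles (consumed as input, one probability vector over
the 96/78/83 channels of their mutation type) are first matched against a
reference catalogue by cosine similarity (assigned when >= 0.85). Profiles
left unmatched are grouped by agglomerative hierarchical clustering on
cosine distance, cutting the tree at the cluster count that maximises the
mean silhouette. Per-sample exposures are then summed per aetiology and
compared between cohorts three ways: absolute contribution (Mann-Whitney +
Holm, significant at q < 0.05 with |log2 fold change| >= 0.4 on the
pseudocounted medians), relative contribution (share of the mutation-type
total; q < 0.05 with median difference >= 0.01), and hypermutator
prevalence (Fisher exact + Bonferroni on samples above the per-type
hypermutator thresholds, run only where either cohort has five or more
hypermutators).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .config import Config
from .stats import (
    adjust_pvalues,
    cosine_similarity,
    fisher_exact_two_sided,
    mann_whitney_two_sided,
    signed_cramers_v,
    silhouette_mean,
)

logger = logging.getLogger("metprime")


def profile_matrix(profiles: pd.DataFrame, mutation_type: str,
                   channels: list[str]) -> pd.DataFrame:
    """Pivot the long profile table into a (name x channel) matrix."""
    sub = profiles[profiles["mutation_type"] == mutation_type]
    mat = sub.pivot(index="name", columns="channel", values="prob")
    missing = [c for c in channels if c not in mat.columns]
    if missing:
        raise ValueError(f"profiles missing channels, e.g. {missing[:3]}")
    return mat[channels].fillna(0.0)


def match_to_reference(denovo: np.ndarray, reference: pd.DataFrame,
                       threshold: float = 0.85) -> tuple[str | None, float]:
    """Best-matching reference profile by cosine similarity.

    Returns (name, similarity) when the best similarity is at or above the
    threshold, else (None, best similarity).
    """
    if reference.empty:
        return None, 0.0
    sims = {name: cosine_similarity(denovo, row.to_numpy())
            for name, row in reference.iterrows()}
    best = max(sims, key=lambda k: (sims[k], k))
    if sims[best] >= threshold:
        return best, sims[best]
    return None, sims[best]


def cluster_unmatched(profiles: pd.DataFrame, linkage: str = "average") -> pd.Series:
    """Group unmatched profiles by hierarchical clustering on cosine distance.

    The tree is cut at every k in 2..n-1 and the k maximising the mean
    silhouette (cosine metric) is kept. Fewer than three profiles each get
    their own cluster; identical profiles (zero distances making the
    silhouette undefined) fall back to a single cluster with a warning.
    Returns integer labels indexed by profile name, deterministic and
    independent of input order.
    """
    mat = profiles.sort_index()
    n = len(mat)
    if n == 0:
        return pd.Series(dtype=int)
    if n <= 2:
        return pd.Series(range(n), index=mat.index, dtype=int)
    dist = ssd.pdist(mat.to_numpy(), metric="cosine")
    dist = np.clip(dist, 0.0, None)
    if np.allclose(dist, 0.0):
        warnings.warn("all profiles identical; falling back to one cluster")
        return pd.Series(0, index=mat.index, dtype=int)
    if linkage == "ward":
        tree = sch.linkage(mat.to_numpy(), method="ward")  # ward needs euclidean
    else:
        tree = sch.linkage(dist, method=linkage)
    best_k, best_score = None, -np.inf
    for k in range(2, n):
        labels = sch.fcluster(tree, k, criterion="maxclust")
        if np.unique(labels).size < 2:
            continue
        try:
            score = silhouette_mean(mat.to_numpy(), labels, metric="cosine")
        except ValueError:
            continue
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        warnings.warn("silhouette undefined at every cut; one cluster")
        return pd.Series(0, index=mat.index, dtype=int)
    labels = sch.fcluster(tree, best_k, criterion="maxclust")
    return pd.Series(labels - 1, index=mat.index, dtype=int)


def assign_aetiologies(profiles: pd.DataFrame, reference: pd.DataFrame,
                       reference_aetiology: dict[str, str] | None = None,
                       config: Config = Config()) -> pd.DataFrame:
    """Full aetiology map for a set of de novo profiles of one mutation type.

    ``profiles`` and ``reference`` are (name x channel) matrices. Matched
    profiles inherit the reference's aetiology (or its name); unmatched
    profiles are clustered and labelled ``<type>_denovo_clust_<i>`` for
    manual curation. Returns columns signature, aetiology, provenance,
    similarity.
    """
    reference_aetiology = reference_aetiology or {}
    rows, unmatched = [], []
    for name, row in profiles.iterrows():
        match, sim = match_to_reference(row.to_numpy(), reference,
                                        config.cosine_match_threshold)
        if match is not None:
            rows.append({"signature": name,
                         "aetiology": reference_aetiology.get(match, match),
                         "provenance": "reference_match", "similarity": sim})
        else:
            unmatched.append((name, sim))
    if unmatched:
        sub = profiles.loc[[name for name, _ in unmatched]]
        labels = cluster_unmatched(sub, config.clustering_linkage)
        sims = dict(unmatched)
        for name, label in labels.items():
            rows.append({"signature": name,
                         "aetiology": f"denovo_clust_{label}",
                         "provenance": "cluster_manual", "similarity": sims[name]})
    return pd.DataFrame(rows, columns=["signature", "aetiology", "provenance",
                                       "similarity"])


def aggregate_aetiology(exposures: pd.DataFrame, aetiology_map: pd.DataFrame) -> pd.DataFrame:
    """Sum per-sample exposures over signatures sharing an aetiology.

    ``exposures`` is long (sample_id, signature, exposure); the map must
    cover every signature present. Returns a long table (sample_id,
    aetiology, contribution).
    """
    mapping = aetiology_map.set_index("signature")["aetiology"]
    unknown = set(exposures["signature"]) - set(mapping.index)
    if unknown:
        raise ValueError(f"exposure signatures missing from aetiology map: "
                         f"{sorted(unknown)[:5]}")
    out = exposures.assign(aetiology=exposures["signature"].map(mapping))
    agg = out.groupby(["sample_id", "aetiology"], as_index=False)["exposure"].sum()
    return agg.rename(columns={"exposure": "contribution"})


def _cohort_arrays(contributions: pd.DataFrame, samples: pd.DataFrame,
                   value_col: str):
    merged = contributions.merge(
        samples[["sample_id", "cohort", "cancer_type"]], on="sample_id")
    for (cancer_type, aetiology), sub in merged.groupby(["cancer_type", "aetiology"]):
        met = sub.loc[sub["cohort"] == "metastatic", value_col].to_numpy(dtype=float)
        pri = sub.loc[sub["cohort"] == "primary", value_col].to_numpy(dtype=float)
        yield cancer_type, aetiology, met, pri


def compare_absolute(contributions: pd.DataFrame, samples: pd.DataFrame,
                     mutation_type: str, config: Config = Config()) -> pd.DataFrame:
    """Absolute aetiology contribution, metastatic vs primary.

    Per (cancer type, aetiology): two-sided Mann-Whitney; Holm correction
    within cancer type (one mutation type per call); log2 fold change of the
    pseudocounted medians; significant iff q < ``signature_q`` and |log2fc|
    >= ``log2fc_threshold``.
    """
    rows = []
    for cancer_type, aetiology, met, pri in _cohort_arrays(
            contributions, samples, "contribution"):
        if len(met) == 0 or len(pri) == 0:
            continue
        res = mann_whitney_two_sided(met, pri)
        log2fc = float(np.log2((np.median(met) + 1) / (np.median(pri) + 1)))
        rows.append({"cancer_type": cancer_type, "mutation_type": mutation_type,
                     "aetiology": aetiology, "n_metastatic": len(met),
                     "n_primary": len(pri), "median_metastatic": np.median(met),
                     "median_primary": np.median(pri), "log2_fold_change": log2fc,
                     "statistic_u": res.statistic, "p_value": res.p_value})
    result = pd.DataFrame(rows, columns=["cancer_type", "mutation_type", "aetiology",
                                         "n_metastatic", "n_primary",
                                         "median_metastatic", "median_primary",
                                         "log2_fold_change", "statistic_u", "p_value"])
    if not len(result):
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q_value"] = np.nan
    for ct, idx in result.groupby("cancer_type").groups.items():
        result.loc[idx, "q_value"] = adjust_pvalues(result.loc[idx, "p_value"], "holm")
    result["significant"] = (result["q_value"] < config.signature_q) & (
        result["log2_fold_change"].abs() >= config.log2fc_threshold
    )
    return result


def compare_relative(contributions: pd.DataFrame, totals: pd.DataFrame,
                     samples: pd.DataFrame, mutation_type: str,
                     config: Config = Config()) -> pd.DataFrame:
    """Relative aetiology contribution (share of the mutation-type total).

    ``totals`` has columns sample_id, total. Samples with zero total are
    excluded. Significant iff q < ``signature_q`` and the absolute median
    difference (metastatic - primary) >= ``relative_diff_threshold``.
    """
    merged = contributions.merge(totals, on="sample_id")
    merged = merged[merged["total"] > 0]
    merged = merged.assign(relative=merged["contribution"] / merged["total"])
    rows = []
    for cancer_type, aetiology, met, pri in _cohort_arrays(
            merged[["sample_id", "aetiology", "relative"]], samples, "relative"):
        if len(met) == 0 or len(pri) == 0:
            continue
        res = mann_whitney_two_sided(met, pri)
        diff = float(np.median(met) - np.median(pri))
        rows.append({"cancer_type": cancer_type, "mutation_type": mutation_type,
                     "aetiology": aetiology, "median_difference": diff,
                     "statistic_u": res.statistic, "p_value": res.p_value})
    result = pd.DataFrame(rows, columns=["cancer_type", "mutation_type", "aetiology",
                                         "median_difference", "statistic_u", "p_value"])
    if not len(result):
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q_value"] = np.nan
    for ct, idx in result.groupby("cancer_type").groups.items():
        result.loc[idx, "q_value"] = adjust_pvalues(result.loc[idx, "p_value"], "holm")
    result["significant"] = (result["q_value"] < config.signature_q) & (
        result["median_difference"].abs() >= config.relative_diff_threshold
    )
    return result


def hypermutator_threshold(mutation_type: str, config: Config = Config()) -> float:
    return {"SBS": config.hypermutator_sbs, "DBS": config.hypermutator_dbs,
            "ID": config.hypermutator_id}[mutation_type]


def hypermutator_enrichment(contributions: pd.DataFrame, samples: pd.DataFrame,
                            mutation_type: str,
                            config: Config = Config()) -> pd.DataFrame:
    """Hypermutator prevalence comparison with signed Cramér's V.

    A sample is a hypermutator for an aetiology when its contribution
    reaches the mutation-type threshold (SBS 10,000; DBS 500; ID 1,000).
    The Fisher test runs only where either cohort has at least
    ``hypermutator_min_samples`` hypermutators; Bonferroni correction over
    the tests performed.
    """
    threshold = hypermutator_threshold(mutation_type, config)
    rows = []
    for cancer_type, aetiology, met, pri in _cohort_arrays(
            contributions, samples, "contribution"):
        met_hyp, pri_hyp = int((met >= threshold).sum()), int((pri >= threshold).sum())
        if max(met_hyp, pri_hyp) < config.hypermutator_min_samples:
            continue
        table = [[met_hyp, len(met) - met_hyp], [pri_hyp, len(pri) - pri_hyp]]
        res = fisher_exact_two_sided(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = signed_cramers_v(table)
        rows.append({"cancer_type": cancer_type, "mutation_type": mutation_type,
                     "aetiology": aetiology, "n_hyper_metastatic": met_hyp,
                     "n_hyper_primary": pri_hyp, "odds_ratio": res.statistic,
                     "signed_cramers_v": v, "p_value": res.p_value})
    result = pd.DataFrame(rows, columns=["cancer_type", "mutation_type", "aetiology",
                                         "n_hyper_metastatic", "n_hyper_primary",
                                         "odds_ratio", "signed_cramers_v", "p_value"])
    if len(result):
        result["q_value"] = adjust_pvalues(result["p_value"], "bonferroni")
        result["significant"] = result["q_value"] < config.signature_q
    else:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
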