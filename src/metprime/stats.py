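"""Statistical primitives shared by every pipeline stage.

All cohort comparisons in the pipeline reduce to a small set of tests and
effect sizes: the two-sided Mann-Whitney U test for numeric burdens, the
two-sided Fisher exact test for binary prevalences, Benjamini-Hochberg /
Holm / Bonferroni multiple-testing corrections, Cliff's delta and a signed
Cramér's V as effect sizes, cosine similarity and mean silhouette for
signature matching and clustering, and non-negative least squares for
signature refitting. Each primitive is a thin, contract-checked layer over
scipy / statsmodels / scikit-learn with the conventions fixed once here.

Sign convention: in every 2x2 table the rows are (metastatic, primary) and
the columns are (feature-true, feature-false), so positive effect sizes mean
metastatic-enriched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import scipy.optimize
import scipy.stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

EXACT_MW_MAX_N = 12  # exact Mann-Whitney path for |x|+|y| at or below this


class Direction(str, Enum):
    METASTATIC_ENRICHED = "metastatic_enriched"
    PRIMARY_ENRICHED = "primary_enriched"
    NONE = "none"


@dataclass
class TestResult:
    """One hypothesis test: statistic, p, optional q and effect size."""

    statistic: float
    p_value: float
    q_value: float | None = None
    effect_size: float | None = None
    direction: Direction = Direction.NONE

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


def _as_1d(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    return arr


def mann_whitney_two_sided(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U for ``x``.

    Uses the exact null distribution when the pooled size is small
    (<= 12) and there are no ties; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = _as_1d("x", x)
    y = _as_1d("y", y)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    u = float(res.statistic)
    expected = x.size * y.size / 2.0
    if u > expected:
        direction = Direction.METASTATIC_ENRICHED
    elif u < expected:
        direction = Direction.PRIMARY_ENRICHED
    else:
        direction = Direction.NONE
    return TestResult(statistic=u, p_value=float(min(res.pvalue, 1.0)), direction=direction)


def _validate_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("2x2 table cells must be nonnegative")
    return t


def odds_ratio_2x2(table) -> float:
    """Sample odds ratio (a*d)/(b*c); +inf when b*c == 0 and a*d > 0."""
    a, b, c, d = _validate_2x2(table).ravel()
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact_two_sided(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p-value follows the standard "sum of tables at least as
    extreme" rule: all tables with the observed margins whose hypergeometric
    probability does not exceed the observed table's. Effect size is the
    sample odds ratio.
    """
    t = _validate_2x2(table)
    _, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    or_ = odds_ratio_2x2(t)
    if math.isnan(or_) or or_ == 1.0:
        direction = Direction.NONE
    elif or_ > 1.0:
        direction = Direction.METASTATIC_ENRICHED
    else:
        direction = Direction.PRIMARY_ENRICHED
    return TestResult(
        statistic=or_, p_value=float(min(p, 1.0)), effect_size=or_, direction=direction
    )


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing correction preserving input order; clipped to 1.

    ``method`` is one of ``bh`` (Benjamini-Hochberg FDR), ``holm`` or
    ``bonferroni``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    mapping = {"bh": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}
    if method not in mapping:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(mapping)}")
    _, q, _, _ = multipletests(p, method=mapping[method])
    return np.minimum(q, 1.0)


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|).

    Positive values mean enrichment in ``x`` (by convention, metastatic).
    """
    x = _as_1d("x", x)
    y = _as_1d("y", y)
    gt = (x[:, None] > y[None, :]).sum()
    lt = (x[:, None] < y[None, :]).sum()
    return float((gt - lt) / (x.size * y.size))


def signed_cramers_v(table) -> float:
    """Cramér's V of a 2x2 table signed by the log odds ratio.

    Returns 0 with a warning on degenerate margins. +1 means complete
    metastatic enrichment under the module's row/column convention.
    """
    t = _validate_2x2(table)
    n = t.sum()
    if n == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margin; signed Cramér's V set to 0", stacklevel=2)
        return 0.0
    chi2 = scipy.stats.chi2_contingency(t, correction=False)[0]
    v = math.sqrt(chi2 / n)
    or_ = odds_ratio_2x2(t)
    if math.isnan(or_) or or_ == 1.0:
        sign = 0.0 if v == 0 else 1.0  # OR==1 implies chi2==0, so v==0 anyway
    else:
        sign = 1.0 if or_ > 1.0 else -1.0
    return float(sign * v)


def cosine_similarity(u, v) -> float:
    u = _as_1d("u", u)
    v = _as_1d("v", v)
    if u.size != v.size:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def silhouette_mean(points, labels, metric: str = "euclidean") -> float:
    """Mean silhouette over all points; singleton clusters contribute 0."""
    pts = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least two clusters")
    return float(silhouette_score(pts, labels, metric=metric))


def nnls_fit(profiles, counts) -> np.ndarray:
    """Nonnegative least-squares signature refit.

    ``profiles`` is (n_signatures, n_channels) with rows summing to 1;
    ``counts`` the observed channel counts. Returns the exposure vector
    minimising ||counts - exposures @ profiles||_2 with exposures >= 0.
    """
    p = np.asarray(profiles, dtype=float)
    c = np.asarray(counts, dtype=float)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("profiles must be a non-empty (signatures x channels) matrix")
    if c.shape != (p.shape[1],):
        raise ValueError("counts length must match the number of channels")
    exposures, _ = scipy.optimize.nnls(p.T, c)
    return exposures
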