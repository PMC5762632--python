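"""Feature-screening statistics over labeled cohorts.

Rank-sum screening of each feature between the impact and nonimpact
distributions (features are not assumed normal), Bonferroni-corrected over
the full 411-feature family; PCA on the standardised feature matrix; and
the feature-feature Pearson correlation matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .registry import N_FEATURES

#: family-wise error rate; the per-test threshold is alpha / 411 ~ 1.22e-4
FAMILY_ALPHA = 0.05
#: exact null enumeration is used up to this smaller-sample size (no ties)
EXACT_MAX_N = 8


def _effectively_constant(X: np.ndarray) -> np.ndarray:
    """Columns whose spread is at floating-point noise level."""
    sd = X.std(axis=0)
    return sd <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))


def ranksum_test(a, b) -> float:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact null distribution when the smaller sample has <= 8 observations
    and the pooled data are tie-free; otherwise the normal approximation
    with tie and continuity corrections.  A comparison whose U statistic
    sits exactly at the null mean (e.g. identical samples) has p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test requires nonempty samples")
    pooled = np.concatenate([a, b])
    u_stat = sps.mannwhitneyu(a, b, alternative="two-sided",
                              method="asymptotic").statistic
    if u_stat == a.size * b.size / 2.0:
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                  method=method, use_continuity=True).pvalue)


def bonferroni_screen(pvals, family_alpha: float = FAMILY_ALPHA) -> pd.DataFrame:
    """Flag features significant at the Bonferroni-adjusted threshold.

    The family size is the registry size (411), not the count of
    non-degenerate features; significance is the strict inequality
    p < alpha / 411.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size != N_FEATURES:
        raise ValueError(
            f"Bonferroni family is the {N_FEATURES}-feature registry; "
            f"got {pvals.size} p-values")
    threshold = family_alpha / N_FEATURES
    return pd.DataFrame({"p": pvals, "significant": pvals < threshold})


def screen_features(impacts: pd.DataFrame, nonimpacts: pd.DataFrame,
                    family_alpha: float = FAMILY_ALPHA) -> pd.DataFrame:
    """Per-feature rank-sum screen between the two classes.

    Returns a DataFrame indexed by feature with the p-value, Bonferroni
    significance flag, and effect direction (sign of the impact-minus-
    nonimpact median difference).  Features constant across the pooled
    cohort are degenerate and scored p = 1.
    """
    pvals, directions = [], []
    for name in impacts.columns:
        a = impacts[name].to_numpy(dtype=float)
        b = nonimpacts[name].to_numpy(dtype=float)
        pooled = np.concatenate([a, b])[:, None]
        if _effectively_constant(pooled)[0]:
            pvals.append(1.0)
        else:
            pvals.append(ranksum_test(a, b))
        directions.append(int(np.sign(np.median(a) - np.median(b))))
    threshold = family_alpha / N_FEATURES   # registry-sized family, always
    return pd.DataFrame({
        "p": pvals,
        "significant": np.asarray(pvals) < threshold,
        "direction": directions,
    }, index=impacts.columns)


def pca_variance(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the standardised (zero-mean, unit-variance) feature matrix.

    Zero-variance columns are dropped with a warning before
    standardisation.  Returns (variance-explained fractions, loadings with
    orthonormal rows, indices of the retained columns).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    sd = X.std(axis=0)
    keep = np.nonzero(~_effectively_constant(X))[0]
    if keep.size < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - keep.size} zero-variance "
                      "columns before PCA", stacklevel=2)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=min(Z.shape)).fit(Z)
    fractions = pca.explained_variance_ratio_
    return fractions, pca.components_, keep


def top_contributors(loadings: np.ndarray, component: int, k: int = 30) -> np.ndarray:
    """Indices of the k features with largest |loading| on one component."""
    row = np.abs(loadings[component])
    return np.argsort(-row, kind="stable")[:k]


def pearson_matrix(X) -> np.ndarray:
    """Feature-feature Pearson correlations; zero-variance columns read 0."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("Pearson correlation needs at least 3 rows")
    valid = ~_effectively_constant(X)
    corr = np.eye(X.shape[1])
    if valid.sum() >= 1:
        sub = np.corrcoef(X[:, valid], rowvar=False)
        sub = np.atleast_2d(sub)
        ii = np.nonzero(valid)[0]
        corr[np.ix_(ii, ii)] = sub
    if not valid.all():
        warnings.warn("zero-variance columns: correlations reported as 0",
                      stacklevel=2)
    return corr
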