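"""Two-group differential expression, FDR adjustment, selection and
supervised hierarchical clustering of log2 expression matrices.

Fold changes are differences of group means on the log2 scale
(non-reference minus reference).  The default test is the ordinary
pooled-variance two-sample t; Welch's unequal-variance variant is
available.  Adjusted p-values use Benjamini-Hochberg step-up by default
(Holm and Benjamini-Yekutieli exposed as alternatives).  Missing values
are excluded pairwise; a feature is tested only if at least two
non-missing samples remain in each group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .io_core import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "log2_fold_changes",
    "two_group_test",
    "bh_adjust",
    "select_de",
    "differential_expression",
    "hierarchical_cluster",
    "ClusteringResult",
]

_ADJUST_METHODS = {"bh": "fdr_bh", "holm": "holm", "by": "fdr_by"}


def _two_group_arrays(matrix: ExpressionMatrix, reference_group: str
                      ) -> tuple[np.ndarray, np.ndarray, str]:
    labels = matrix.group_labels
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not among {labels}")
    other = labels[0] if labels[1] == reference_group else labels[1]
    a = matrix.values[matrix.samples_in_group(other)].to_numpy()
    b = matrix.values[matrix.samples_in_group(reference_group)].to_numpy()
    return a, b, other


def log2_fold_changes(matrix: ExpressionMatrix, reference_group: str) -> pd.Series:
    """Per-feature mean(non-reference) - mean(reference) on the log2 scale.

    Missing values are excluded per group; a feature missing in an entire
    group is flagged NaN, never zero.
    """
    a, b, _ = _two_group_arrays(matrix, reference_group)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # a feature absent from a whole group is deliberately NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    return pd.Series(fc, index=matrix.feature_ids, name="log2fc")


def two_group_test(matrix: ExpressionMatrix, reference_group: str,
                   method: str = "student") -> pd.DataFrame:
    """Two-sided two-sample t-test per feature.

    ``method`` is 'student' (pooled variance) or 'welch'
    (Welch-Satterthwaite df).  The sign of t follows
    mean(non-reference) - mean(reference).  Degenerate features: zero
    variance in both groups with equal means gives p = 1 by convention;
    unequal means with zero variance gives p = 0 and is flagged in the
    'degenerate' column.  Features with fewer than two non-missing
    samples in either group are NaN.
    """
    if method not in ("student", "welch"):
        raise ValueError("method must be 'student' or 'welch'")
    a, b, _ = _two_group_arrays(matrix, reference_group)
    t = np.full(a.shape[0], np.nan)
    p = np.full(a.shape[0], np.nan)
    degenerate = np.zeros(a.shape[0], dtype=bool)
    for i in range(a.shape[0]):
        xa = a[i][~np.isnan(a[i])]
        xb = b[i][~np.isnan(b[i])]
        if xa.size < 2 or xb.size < 2:
            continue
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        if va == 0 and vb == 0:
            if xa.mean() == xb.mean():
                t[i], p[i] = 0.0, 1.0
            else:
                t[i] = np.inf if xa.mean() > xb.mean() else -np.inf
                p[i] = 0.0
                degenerate[i] = True
            continue
        res = stats.ttest_ind(xa, xb, equal_var=(method == "student"))
        t[i], p[i] = res.statistic, res.pvalue
    return pd.DataFrame({"t": t, "p": p, "degenerate": degenerate},
                        index=matrix.feature_ids)


def bh_adjust(p_values, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up by default).

    Input order is preserved; adjusted values are capped at 1 and are
    always >= the raw values.  NaNs pass through as NaN and do not enter
    the adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method=_ADJUST_METHODS[method])[1]
    return out


def differential_expression(matrix: ExpressionMatrix, reference_group: str,
                            method: str = "student",
                            adjust: str = "bh") -> pd.DataFrame:
    """Full DE table: feature, log2fc, t, p, p_adj, direction.

    ``direction`` is 'up_in_A'/'up_in_B' where A is the non-reference
    group and B the reference, consistent with the sign of log2fc.
    Sorted by adjusted then raw p, ties broken by feature id.
    """
    fc = log2_fold_changes(matrix, reference_group)
    tt = two_group_test(matrix, reference_group, method=method)
    table = pd.DataFrame({
        "log2fc": fc,
        "t": tt["t"],
        "p": tt["p"],
        "p_adj": bh_adjust(tt["p"].to_numpy(), method=adjust),
    })
    table["direction"] = np.where(table["log2fc"] >= 0, "up_in_A", "up_in_B")
    # stable rank order: adjusted p, then raw p, then feature id (NaNs last)
    table = table.loc[sorted(table.index)]
    table = table.sort_values(["p_adj", "p"], kind="stable", na_position="last")
    table.index.name = "feature"
    return table


def select_de(table: pd.DataFrame, logfc_min: float = 0.0,
              p_adj_max: float = 0.01) -> tuple[list[str], list[str]]:
    """Features passing strict thresholds, split by direction.

    Selection uses |log2fc| strictly greater than ``logfc_min`` and
    adjusted p strictly below ``p_adj_max``; returns (up_in_A, up_in_B)
    with a feature in at most one set.
    """
    if logfc_min < 0 or p_adj_max < 0:
        raise ValueError("thresholds must be non-negative")
    ok = (table["p_adj"] < p_adj_max) & (table["log2fc"].abs() > logfc_min)
    up_a = list(table.index[ok & (table["log2fc"] > 0)])
    up_b = list(table.index[ok & (table["log2fc"] < 0)])
    return up_a, up_b


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    """Sample/feature leaf orders, the sample merge tree and group purity.

    ``purity`` cuts the sample tree into as many clusters as there are
    group labels and reports the fraction of samples falling in a
    cluster dominated by their own group.
    """

    sample_order: list[str]
    feature_order: list[str]
    sample_linkage: np.ndarray
    feature_linkage: np.ndarray | None
    purity: float
    newick: str


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def build(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = build(node.get_left())
        right = build(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return build(tree) + ";"


def hierarchical_cluster(matrix: ExpressionMatrix, feature_subset: list[str],
                         linkage: str = "average",
                         distance: str = "euclidean") -> ClusteringResult:
    """Cluster samples (and features) on a selected feature subset.

    Deterministic given its inputs.  All-constant features produce zero
    distances, which the linkage handles without error.  Purity is
    computed against the known group labels by cutting the sample tree
    into n-groups clusters.
    """
    if not feature_subset:
        raise ValueError("feature subset is empty")
    sub = matrix.subset_features(feature_subset)
    data = sub.values.to_numpy()
    samples = sub.sample_ids
    if len(samples) < 2:
        raise ValueError("at least two samples required")

    def _dist(x: np.ndarray) -> np.ndarray:
        if distance == "euclidean":
            return pdist(x, metric="euclidean")
        if distance == "correlation":
            d = pdist(x, metric="correlation")
            return np.nan_to_num(d, nan=0.0)
        raise ValueError(f"unknown distance {distance!r}")

    zs = hierarchy.linkage(_dist(data.T), method=linkage)
    sample_order = [samples[i] for i in hierarchy.leaves_list(zs)]

    zf = None
    feature_order = list(sub.feature_ids)
    if len(feature_order) >= 2:
        zf = hierarchy.linkage(_dist(data), method=linkage)
        feature_order = [feature_order[i] for i in hierarchy.leaves_list(zf)]

    groups = [sub.groups[s] for s in samples]
    n_groups = len(set(groups))
    if n_groups < 2 or len(samples) == n_groups:
        purity = 1.0
    else:
        assign = hierarchy.fcluster(zs, t=n_groups, criterion="maxclust")
        purity = 0.0
        for c in np.unique(assign):
            members = [groups[i] for i in np.flatnonzero(assign == c)]
            purity += max(members.count(g) for g in set(members))
        purity /= len(samples)

    return ClusteringResult(sample_order, feature_order, zs, zf, purity,
                            _linkage_to_newick(zs, samples))


def write_de_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="feature",
                 columns=["log2fc", "t", "p", "p_adj", "direction"])
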