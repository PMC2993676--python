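"""Transcription-factor screening and TF-versus-microRNA-cluster regression.

The screen intersects the up-regulated selections of two independent DE
tables (e.g. two cohorts profiled on different platforms), restricted to
a supplied TF universe.  Candidate TFs are then related to the per-sample
median expression of a microRNA cluster by ordinary least squares, with a
two-sided t-test on the slope (n - 2 df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import select_de
from .io_core import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["RegressionFit", "screen_tfs", "mir_cluster_summary", "regress_tf_on_mir"]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int


def _rank_map(table: pd.DataFrame) -> dict[str, int]:
    """1-based rank of each feature by adjusted then raw p, ties by id."""
    order = sorted(table.index, key=lambda f: (
        np.inf if pd.isna(table.at[f, "p_adj"]) else table.at[f, "p_adj"],
        np.inf if pd.isna(table.at[f, "p"]) else table.at[f, "p"], f))
    return {f: i + 1 for i, f in enumerate(order)}


def screen_tfs(de_a: pd.DataFrame, de_b: pd.DataFrame, tf_universe: set[str],
               logfc_min: float = 1.0, p_adj_max: float = 0.01) -> list[str]:
    """TFs up-regulated (in the A direction) in both DE tables.

    Both tables must share the direction convention (positive log2fc =
    up in the group of interest).  The result is restricted to
    ``tf_universe`` and ordered by rank in the first dataset.
    """
    if not tf_universe:
        logger.warning("empty TF universe; screen returns no candidates")
        return []
    up_a, _ = select_de(de_a, logfc_min, p_adj_max)
    up_b, _ = select_de(de_b, logfc_min, p_adj_max)
    shared = set(up_a) & set(up_b) & set(tf_universe)
    ranks = _rank_map(de_a)
    return sorted(shared, key=lambda f: ranks[f])


def mir_cluster_summary(mir_matrix: ExpressionMatrix, members: list[str]) -> pd.Series:
    """Per-sample median expression over the cluster members.

    Missing member values are excluded per sample; a sample with no
    member measured is an error.
    """
    present = [m for m in members if m in mir_matrix.values.index]
    if not present:
        raise ValueError("no cluster member present in the matrix")
    sub = mir_matrix.values.loc[present]
    med = sub.median(axis=0, skipna=True)
    if med.isna().any():
        s = med.index[med.isna()][0]
        raise ValueError(f"no cluster member measured in sample {s!r}")
    med.name = "mir_cluster_median"
    return med


def regress_tf_on_mir(tf_values: Mapping[str, float],
                      mir_median: Mapping[str, float]) -> RegressionFit:
    """OLS of TF expression on the miR-cluster median over shared samples.

    Samples present in only one input are dropped (with a logged count);
    at least three shared samples are required.  The slope p-value is
    the two-sided t-test with n - 2 degrees of freedom.
    """
    shared = sorted(set(tf_values) & set(mir_median))
    dropped = (len(tf_values) - len(shared)) + (len(mir_median) - len(shared))
    if dropped:
        logger.info("dropped %d unpaired samples from regression", dropped)
    if len(shared) < 3:
        raise ValueError("at least three shared samples required")
    x = np.array([mir_median[s] for s in shared], dtype=float)
    y = np.array([tf_values[s] for s in shared], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: miR median has zero variance")
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2), float(res.pvalue), len(shared))


def tf_regression_table(candidates: Iterable[str], de_a: pd.DataFrame,
                        de_b: pd.DataFrame, mrna_matrix: ExpressionMatrix,
                        mir_median: pd.Series) -> pd.DataFrame:
    """Summary table: gene, rank/log2fc in each dataset, slope, r2, p_slope."""
    ra, rb = _rank_map(de_a), _rank_map(de_b)
    rows = []
    for g in candidates:
        fit = regress_tf_on_mir(mrna_matrix.values.loc[g].to_dict(),
                                mir_median.to_dict())
        rows.append((g, ra.get(g), de_a.at[g, "log2fc"], rb.get(g),
                     de_b.at[g, "log2fc"] if g in de_b.index else np.nan,
                     fit.slope, fit.r_squared, fit.p_slope))
    return pd.DataFrame(rows, columns=["gene", "rank_a", "logfc_a", "rank_b",
                                       "logfc_b", "slope", "r2", "p_slope"]
                        ).set_index("gene")
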