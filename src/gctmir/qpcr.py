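"""Relative quantification of qRT-PCR data by the ddCt method.

dCT = CT(gene) - CT(housekeeper) per sample; ddCT = dCT - dCT(reference);
relative expression = 2**(-ddCT).  Two referencing conventions are
supported: a named reference sample (e.g. a universal reference RNA run
as a sample), or per-gene referencing to the sample with the lowest
normalized expression (i.e. the maximal dCT).  The housekeeper can be
chosen automatically as the candidate with the smallest CT standard
deviation across samples.  Group comparisons use a two-sided Welch
(unequal-variance) t-test on the log/dCT scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CtTable

logger = logging.getLogger(__name__)

__all__ = [
    "RelativeExpressionTable",
    "select_housekeeper",
    "delta_delta_ct",
    "group_compare_welch",
    "compare_groups",
]


@dataclass
class RelativeExpressionTable:
    """Per gene x sample dCT / ddCT (cycles) and fold-unit relative expression."""

    housekeeper: str
    reference: str  # sample id, or 'lowest_expression_sample'
    delta_ct: pd.DataFrame
    delta_delta_ct: pd.DataFrame
    relative_expression: pd.DataFrame


def select_housekeeper(ct: CtTable, candidates: list[str]) -> str:
    """Candidate housekeeper with the smallest CT standard deviation.

    Ties are broken by candidate order; a candidate absent from the
    table is an error naming it.
    """
    if len(candidates) < 2:
        raise ValueError("at least two housekeeper candidates required")
    best, best_sd = None, np.inf
    for cand in candidates:
        if cand not in ct.ct.index:
            raise ValueError(f"housekeeper candidate {cand!r} not in CT table")
        sd = float(ct.ct.loc[cand].std(ddof=1))
        if sd < best_sd:
            best, best_sd = cand, sd
    return best


def delta_delta_ct(ct: CtTable, housekeeper: str,
                   reference: str = "lowest_expression_sample",
                   reference_id: str | None = None) -> RelativeExpressionTable:
    """ddCt relative quantification normalized to a housekeeper gene.

    ``reference`` is either 'lowest_expression_sample' (per gene, the
    sample with maximal dCT becomes the unit reference) or
    'named_sample' with ``reference_id`` giving the sample.  For a named
    reference every gene has relative expression exactly 1 in that
    sample.
    """
    if housekeeper not in ct.ct.index:
        raise ValueError(f"housekeeper {housekeeper!r} not in CT table")
    hk = ct.ct.loc[housekeeper]
    if hk.isna().any():
        missing = hk.index[hk.isna()][0]
        raise ValueError(f"housekeeper not measured in sample {missing!r}")
    genes = [g for g in ct.gene_ids if g != housekeeper]
    dct = ct.ct.loc[genes].sub(hk, axis=1)

    if reference == "lowest_expression_sample":
        ref_dct = dct.max(axis=1)
    elif reference == "named_sample":
        if reference_id is None:
            raise ValueError("reference_id required for a named reference sample")
        if reference_id not in dct.columns:
            raise ValueError(f"reference sample {reference_id!r} not in CT table")
        ref_dct = dct[reference_id]
        if ref_dct.isna().any():
            gene = ref_dct.index[ref_dct.isna()][0]
            raise ValueError(f"reference sample missing gene {gene!r}")
    else:
        raise ValueError("reference must be 'lowest_expression_sample' or 'named_sample'")

    ddct = dct.sub(ref_dct, axis=0)
    rel = np.power(2.0, -ddct)
    ref_label = reference_id if reference == "named_sample" else reference
    return RelativeExpressionTable(housekeeper, ref_label, dct, ddct, rel)


def group_compare_welch(values, groups) -> float:
    """Two-sided Welch t-test p-value for a two-group comparison.

    ``values`` and ``groups`` are aligned sequences (or a mapping from
    sample to value plus sample to group).  At least two observations
    per group are required.  Zero variance in both groups with equal
    means gives p = 1 by convention.
    """
    if isinstance(values, dict):
        samples = list(values)
        v = np.array([values[s] for s in samples], dtype=float)
        g = [groups[s] for s in samples]
    else:
        v = np.asarray(values, dtype=float)
        g = list(groups)
    labels = sorted(set(g))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    xa = v[[i for i, x in enumerate(g) if x == labels[0]]]
    xb = v[[i for i, x in enumerate(g) if x == labels[1]]]
    if xa.size < 2 or xb.size < 2:
        raise ValueError("at least two observations per group required")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        return 1.0 if xa.mean() == xb.mean() else 0.0
    return float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)


def compare_groups(rel: RelativeExpressionTable, groups: dict[str, str]) -> pd.DataFrame:
    """Per-gene Welch comparison of ddCT values between two groups.

    Tests operate on the ddCT (log) scale for approximate normality.
    Returns mean ddCT per group, the implied log2 fold difference and
    the two-sided Welch p-value.
    """
    samples = [s for s in rel.delta_delta_ct.columns if s in groups]
    labels = sorted(set(groups[s] for s in samples))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for gene in rel.delta_delta_ct.index:
        vals = rel.delta_delta_ct.loc[gene, samples]
        ok = vals.notna()
        p = group_compare_welch(vals[ok].to_numpy(),
                                [groups[s] for s in vals.index[ok]])
        ma = vals[[s for s in samples if groups[s] == labels[0]]].mean()
        mb = vals[[s for s in samples if groups[s] == labels[1]]].mean()
        # lower ddCT = higher expression, so log2 fold (A vs B) = -(ma - mb)
        rows.append((gene, ma, mb, -(ma - mb), p))
    return pd.DataFrame(rows, columns=["gene", f"mean_ddct_{labels[0]}",
                                       f"mean_ddct_{labels[1]}", "log2_fold_a_vs_b",
                                       "p_welch"]).set_index("gene")


def write_relative_expression_tsv(rel: RelativeExpressionTable, path) -> None:
    long = pd.concat({
        "delta_ct": rel.delta_ct.stack(),
        "delta_delta_ct": rel.delta_delta_ct.stack(),
        "relative_expression": rel.relative_expression.stack(),
    }, axis=1)
    long.index.names = ["gene", "sample"]
    long.to_csv(path, sep="\t")
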