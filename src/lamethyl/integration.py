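"""Methylation-expression integration and qPCR fold-change helper.

Differentially methylated genes are overlapped with external
differential-expression lists (blood and brain-tissue profiles), and each
overlapping gene is screened for the canonical regulatory pattern:
promoter hypermethylation with down-regulated expression, or promoter
hypomethylation with up-regulation.  Expression quantitation from qPCR
cycle thresholds uses the 2^-ddCT method against a housekeeping gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PROMOTER_FEATURES

METH_REGIONS = ("promoter", "body", "other")


def region_class(gene_feature: str) -> str:
    """Collapse a gene feature to promoter / body / other."""
    if gene_feature in PROMOTER_FEATURES:
        return "promoter"
    if gene_feature == "Body":
        return "body"
    return "other"


def anticorrelation_flag(meth_direction: str, meth_region: str, expr_direction: str) -> bool:
    """True for the expression-silencing/activation pattern at promoters.

    Promoter hypermethylation with down-regulation, or promoter
    hypomethylation with up-regulation; every non-promoter region is
    False regardless of directions.
    """
    if meth_direction not in ("hyper", "hypo"):
        raise ValueError(f"bad methylation direction {meth_direction!r}")
    if meth_region not in METH_REGIONS:
        raise ValueError(f"bad methylation region {meth_region!r}")
    if expr_direction not in ("up", "down"):
        raise ValueError(f"bad expression direction {expr_direction!r}")
    return meth_region == "promoter" and (
        (meth_direction == "hyper" and expr_direction == "down")
        or (meth_direction == "hypo" and expr_direction == "up")
    )


def overlap_expression(
    meth_genes,
    blood: pd.DataFrame,
    tissue: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Overlap methylation genes with two expression lists.

    ``meth_genes`` is either a set of symbols or a DataFrame with
    ``gene_symbol`` plus optional ``direction``/``region`` columns (when
    present, anticorrelation is evaluated per record).  Returns one row
    per overlapping gene per source and counts per source plus the
    combined (de-duplicated) overlap.
    """
    if isinstance(meth_genes, pd.DataFrame):
        meth = meth_genes.drop_duplicates("gene_symbol").set_index("gene_symbol")
    else:
        meth = pd.DataFrame(index=pd.Index(sorted(set(meth_genes)), name="gene_symbol"))

    rows = []
    for expr in (blood, tissue):
        for rec in expr.itertuples(index=False):
            if rec.gene_symbol not in meth.index:
                continue
            meth_dir = meth.loc[rec.gene_symbol].get("direction", np.nan) if len(meth.columns) else np.nan
            meth_reg = meth.loc[rec.gene_symbol].get("region", np.nan) if len(meth.columns) else np.nan
            flag = (
                anticorrelation_flag(meth_dir, meth_reg, rec.direction)
                if meth_dir in ("hyper", "hypo") and isinstance(meth_reg, str)
                else False
            )
            rows.append((rec.gene_symbol, meth_dir, meth_reg, rec.direction, rec.source, flag))

    table = pd.DataFrame(
        rows,
        columns=["gene_symbol", "meth_direction", "meth_region", "expr_direction", "source", "anticorrelated"],
    )
    counts = {
        "blood": int((table["source"] == "blood").sum()) if len(table) else 0,
        "tissue": int((table["source"] == "tissue").sum()) if len(table) else 0,
        "combined": int(table["gene_symbol"].nunique()) if len(table) else 0,
    }
    return table, counts


def ddct_fold_change(
    ct_target_case: float,
    ct_housekeeping_case: float,
    ct_target_control: float,
    ct_housekeeping_control: float,
) -> float:
    """Relative expression by 2^-ddCT.

    ddCT = (CT_target,case - CT_housekeeping,case)
         - (CT_target,control - CT_housekeeping,control);
    one extra cycle of the case target halves the reported fold change.
    """
    cts = np.array([ct_target_case, ct_housekeeping_case, ct_target_control, ct_housekeeping_control], dtype=float)
    if not np.isfinite(cts).all() or (cts <= 0).any():
        raise ValueError("CT values must be finite and positive")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))
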