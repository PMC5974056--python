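"""Staged comparisons, gene mapping, and shared-gene inversion logic.

Three contrasts span the staged design Normal -> LA Type I -> LA Type II:

* occurrence:   TypeI vs Normal
* progression:  TypeII vs TypeI
* overall:      TypeII vs Normal

Significant sites are mapped to genes; genes called in both occurrence
and progression are classified by whether their methylation direction
inverts between the two processes, and the overall contrast is used to
derive occurrence- and progression-specific gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import diffmeth
from .containers import BetaMatrix, Comparison

log = logging.getLogger(__name__)

COMPARISONS = {
    "TypeI_vs_Normal": ("TypeI", "Normal"),
    "TypeII_vs_TypeI": ("TypeII", "TypeI"),
    "TypeII_vs_Normal": ("TypeII", "Normal"),
}

#: occurrence/progression aliases for the three contrasts
OCCURRENCE, PROGRESSION, OVERALL = ("TypeI_vs_Normal", "TypeII_vs_TypeI", "TypeII_vs_Normal")


def run_comparison(
    betas: BetaMatrix | pd.DataFrame,
    design: dict[str, str],
    name: str,
    delta_min: float = diffmeth.DELTA_MIN,
    score_min: float = diffmeth.SCORE_MIN,
) -> pd.DataFrame:
    """Call sites for one named contrast (first-named group is condition)."""
    if name not in COMPARISONS:
        raise ValueError(f"unknown comparison {name!r}; expected one of {sorted(COMPARISONS)}")
    cond, ref = COMPARISONS[name]
    comparison = Comparison.from_design(name, cond, ref, design)
    return diffmeth.call_sites(betas, comparison, delta_min=delta_min, score_min=score_min)


def map_to_genes(site_results: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Collapse significant sites to one row per (gene, comparison).

    Intergenic sites are dropped.  A gene's direction is hyper/hypo when
    all supporting probes agree and 'mixed' otherwise.
    """
    sig = site_results.loc[site_results["significant"]] if "significant" in site_results.columns else site_results
    cols = ["gene_symbol", "comparison", "direction", "n_probes", "supporting_probes"]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    man = manifest.set_index("probe_id")
    joined = sig.merge(
        man[["gene_symbol"]], left_on="probe_id", right_index=True, how="left"
    )
    joined = joined[joined["gene_symbol"].fillna("") != ""]
    if joined.empty:
        return pd.DataFrame(columns=cols)

    def collapse(grp: pd.DataFrame) -> pd.Series:
        dirs = set(grp["direction"])
        return pd.Series({
            "direction": dirs.pop() if len(dirs) == 1 else "mixed",
            "n_probes": len(grp),
            "supporting_probes": ";".join(sorted(grp["probe_id"])),
        })

    out = (
        joined.groupby(["gene_symbol", "comparison"], sort=True)
        .apply(collapse, include_groups=False)
        .reset_index()
    )
    return out[cols]


_CATEGORY = {
    ("hyper", "hypo"): "hyper_to_hypo",
    ("hypo", "hyper"): "hypo_to_hyper",
    ("hyper", "hyper"): "same_hyper",
    ("hypo", "hypo"): "same_hypo",
}

INVERSE_CATEGORIES = ("hyper_to_hypo", "hypo_to_hyper")


@dataclass
class SharedGeneClassification:
    """Genes significant in both occurrence and progression, by inversion."""

    records: pd.DataFrame  # gene_symbol, occ_direction, prog_direction, category
    n_mixed_excluded: int

    @property
    def n_shared(self) -> int:
        return len(self.records)

    @property
    def n_inverse(self) -> int:
        return int(self.records["category"].isin(INVERSE_CATEGORIES).sum())

    @property
    def n_same(self) -> int:
        return self.n_shared - self.n_inverse

    @property
    def percent_inverse(self) -> float:
        return 100.0 * self.n_inverse / self.n_shared if self.n_shared else 0.0

    def summary(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "n_inverse": self.n_inverse,
            "n_same": self.n_same,
            "percent_inverse": self.percent_inverse,
            "n_mixed_excluded": self.n_mixed_excluded,
        }


def classify_shared(occ_genes: pd.DataFrame, prog_genes: pd.DataFrame) -> SharedGeneClassification:
    """Classify genes shared between occurrence and progression calls.

    Inputs are gene tables with ``gene_symbol`` and ``direction`` columns
    (as from :func:`map_to_genes`).  Mixed-direction genes are excluded
    with a logged count; the intersection is categorised as inverting
    (hyper→hypo / hypo→hyper) or keeping direction.
    """
    n_mixed = int((occ_genes.get("direction") == "mixed").sum() + (prog_genes.get("direction") == "mixed").sum())
    if n_mixed:
        log.info("classify_shared: excluding %d mixed-direction gene records", n_mixed)
    occ = occ_genes.loc[occ_genes["direction"] != "mixed", ["gene_symbol", "direction"]]
    prog = prog_genes.loc[prog_genes["direction"] != "mixed", ["gene_symbol", "direction"]]
    merged = occ.merge(prog, on="gene_symbol", suffixes=("_occ", "_prog"))
    merged = merged.rename(columns={"direction_occ": "occ_direction", "direction_prog": "prog_direction"})
    merged["category"] = [
        _CATEGORY[(o, p)] for o, p in zip(merged["occ_direction"], merged["prog_direction"])
    ]
    merged = merged.sort_values("gene_symbol").reset_index(drop=True)
    return SharedGeneClassification(records=merged, n_mixed_excluded=n_mixed)


def derive_specific(
    occ_genes,
    prog_genes,
    overall_genes,
    exclude_other: bool = True,
) -> tuple[set[str], set[str]]:
    """Occurrence- and progression-specific gene sets via the overall contrast.

    With ``exclude_other`` (default) a gene is occurrence-specific when it
    appears in both the overall and occurrence contrasts but not the
    progression contrast, and symmetrically for progression-specific.
    ``exclude_other=False`` keeps the plain pairwise intersections.
    """
    occ = _symbols(occ_genes)
    prog = _symbols(prog_genes)
    overall = _symbols(overall_genes)
    occ_specific = overall & occ
    prog_specific = overall & prog
    if exclude_other:
        occ_specific -= prog
        prog_specific -= occ
    return occ_specific, prog_specific


def _symbols(genes) -> set[str]:
    if isinstance(genes, pd.DataFrame):
        return set(genes["gene_symbol"])
    return set(genes)
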