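"""CpG-island context annotation and category summaries.

A probe is classified relative to the nearest CpG island using the
standard BeadChip distance convention: inside an island -> Island;
within 2 kb of an island edge -> shore; 2-4 kb -> shelf; beyond 4 kb ->
open sea.  The N (north) side is the lower-coordinate flank, S (south)
the higher-coordinate flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GENE_FEATURES, ISLAND_RELATIONS

SHORE_BP = 2000
SHELF_BP = 4000

ISLAND_COLUMNS = ("chromosome", "start", "end", "island_id")


def make_island_index(islands: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge overlapping intervals and index them per chromosome.

    Parameters
    ----------
    islands : DataFrame with columns chromosome, start, end (1-based inclusive).

    Returns
    -------
    dict mapping chromosome -> (starts, ends) as sorted arrays of
    non-overlapping intervals.
    """
    if (islands["start"] > islands["end"]).any():
        raise ValueError("island start must be <= end")
    index = {}
    for chrom, grp in islands.groupby("chromosome", sort=False):
        ivs = grp[["start", "end"]].sort_values("start").to_numpy()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.asarray(merged)
        index[chrom] = (arr[:, 0], arr[:, 1])
    return index


def island_relation_of(position: int, chromosome: str, islands) -> str:
    """Classify one genomic position relative to a CpG-island set.

    ``islands`` may be an island DataFrame or a prebuilt index from
    :func:`make_island_index`.  Unknown chromosomes classify as OpenSea
    with a warning.
    """
    index = islands if isinstance(islands, dict) else make_island_index(islands)
    return _relations(np.asarray([position]), chromosome, index)[0]


def island_relations(manifest: pd.DataFrame, islands) -> pd.Series:
    """Vectorized :func:`island_relation_of` over a manifest."""
    index = islands if isinstance(islands, dict) else make_island_index(islands)
    out = pd.Series("OpenSea", index=manifest.index, dtype=object)
    for chrom, grp in manifest.groupby("chromosome", sort=False):
        out.loc[grp.index] = _relations(grp["position"].to_numpy(), chrom, index)
    return out


def _relations(positions: np.ndarray, chromosome: str, index: dict) -> np.ndarray:
    if chromosome not in index:
        warnings.warn(f"chromosome {chromosome!r} has no islands; classifying as OpenSea", stacklevel=3)
        return np.full(positions.shape, "OpenSea", dtype=object)
    starts, ends = index[chromosome]
    i = np.searchsorted(starts, positions, side="right") - 1
    inside = (i >= 0) & (positions <= ends[np.clip(i, 0, None)])

    # distance to the end of the island at/below the position (S flank of it)
    d_prev = np.where(i >= 0, positions - ends[np.clip(i, 0, None)], np.iinfo(np.int64).max)
    # distance to the start of the next island up (N flank of it)
    j = i + 1
    d_next = np.where(j < len(starts), starts[np.clip(j, 0, len(starts) - 1)] - positions, np.iinfo(np.int64).max)

    south = d_prev < d_next  # ties break to the N side of the island above
    d = np.minimum(d_prev, d_next)

    rel = np.full(positions.shape, "OpenSea", dtype=object)
    shore = (d >= 1) & (d <= SHORE_BP)
    shelf = (d > SHORE_BP) & (d <= SHELF_BP)
    rel[shore & south] = "S_Shore"
    rel[shore & ~south] = "N_Shore"
    rel[shelf & south] = "S_Shelf"
    rel[shelf & ~south] = "N_Shelf"
    rel[inside] = "Island"
    return rel


@dataclass
class AnnotationSummary:
    """Category counts/proportions for a set of called sites.

    Two proportion denominators are reported, mirroring the two styles in
    which such results are usually summarised: over all sites, and over
    the annotated subset only (non-OpenSea for island context, non-
    Intergenic for gene features).
    """

    n_sites: int
    island_counts: pd.Series
    island_props_all: pd.Series
    island_props_annotated: pd.Series
    feature_counts: pd.Series
    feature_props_all: pd.Series
    feature_props_annotated: pd.Series
    chromosome_counts: pd.Series
    direction_counts: pd.Series

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in ISLAND_RELATIONS:
            rows.append(("island_relation", cat, int(self.island_counts.get(cat, 0)),
                         float(self.island_props_all.get(cat, 0.0)),
                         float(self.island_props_annotated.get(cat, 0.0))))
        for cat in GENE_FEATURES:
            rows.append(("gene_feature", cat, int(self.feature_counts.get(cat, 0)),
                         float(self.feature_props_all.get(cat, 0.0)),
                         float(self.feature_props_annotated.get(cat, 0.0))))
        for chrom, n in self.chromosome_counts.items():
            rows.append(("chromosome", chrom, int(n), float(n) / self.n_sites if self.n_sites else 0.0, np.nan))
        for d, n in self.direction_counts.items():
            rows.append(("direction", d, int(n), float(n) / self.n_sites if self.n_sites else 0.0, np.nan))
        return pd.DataFrame(rows, columns=["category", "level", "count", "prop_all", "prop_annotated"])


def summarize_annotations(site_results: pd.DataFrame, manifest: pd.DataFrame) -> AnnotationSummary:
    """Summarise island/feature/chromosome context of called sites.

    ``site_results`` needs a ``probe_id`` column (typically the significant
    rows of a call table) and, if present, a ``direction`` column feeds the
    hyper/hypo split.  Every probe must exist in the manifest; each probe
    counts once per category using its manifest record.
    """
    man = manifest.set_index("probe_id")
    unknown = set(site_results.get("probe_id", pd.Series(dtype=object))) - set(man.index)
    if unknown:
        raise ValueError(f"probes absent from manifest: {sorted(unknown)[:5]}...")
    n = len(site_results)
    if n == 0:
        zero = pd.Series(dtype=float)
        zc = pd.Series(dtype=int)
        return AnnotationSummary(0, zc, zero, zero, zc, zero, zero, zc, zc)

    ann = man.loc[site_results["probe_id"]]
    island_counts = ann["island_relation"].value_counts()
    feature_counts = ann["gene_feature"].value_counts()
    chrom_counts = ann["chromosome"].value_counts()

    island_ann = island_counts.drop("OpenSea", errors="ignore")
    feature_ann = feature_counts.drop("Intergenic", errors="ignore")

    direction_counts = (
        site_results["direction"].value_counts()
        if "direction" in site_results.columns
        else pd.Series(dtype=int)
    )
    return AnnotationSummary(
        n_sites=n,
        island_counts=island_counts,
        island_props_all=island_counts / n,
        island_props_annotated=island_ann / island_ann.sum() if island_ann.sum() else island_ann.astype(float),
        feature_counts=feature_counts,
        feature_props_all=feature_counts / n,
        feature_props_annotated=feature_ann / feature_ann.sum() if feature_ann.sum() else feature_ann.astype(float),
        chromosome_counts=chrom_counts,
        direction_counts=direction_counts,
    )
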