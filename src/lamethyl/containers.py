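"""Core in-memory containers shared across pipeline stages.

The pipeline operates on probes-by-samples matrices keyed by probe id
(rows) and sample id (columns), carried as pandas DataFrames so that
label alignment is explicit at every stage boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("Normal", "TypeI", "TypeII")

ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

GENE_FEATURES = ("TSS200", "TSS1500", "FiveUTR", "FirstExon", "Body", "ThreeUTR", "Intergenic")

#: gene features treated as promoter context for methylation-expression logic
PROMOTER_FEATURES = frozenset({"TSS200", "TSS1500", "FirstExon"})

MANIFEST_COLUMNS = (
    "probe_id",
    "chromosome",
    "position",
    "island_relation",
    "gene_symbol",
    "gene_feature",
    "strand",
)


@dataclass
class SignalSet:
    """Two-colour intensity data for one BeadChip-style experiment.

    Attributes
    ----------
    M, U : DataFrame, probes x samples
        Methylated / unmethylated fluorescence intensities (non-negative).
    bead_count : DataFrame, probes x samples
        Number of beads supporting each measurement.
    negctrl : DataFrame, control-index x samples
        Negative-control (background) intensities per sample.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    bead_count: pd.DataFrame
    negctrl: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("U", "bead_count"):
            other = getattr(self, name)
            if not (other.index.equals(self.M.index) and other.columns.equals(self.M.columns)):
                raise ValueError(f"{name} matrix is not aligned with M")
        if not self.negctrl.columns.equals(self.M.columns):
            raise ValueError("negctrl columns do not match sample order")
        if (self.M.to_numpy() < 0).any() or (self.U.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if (self.bead_count.to_numpy() < 0).any():
            raise ValueError("bead counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.M.columns)

    @property
    def probes(self) -> pd.Index:
        return self.M.index

    def subset(self, probes=None, samples=None) -> "SignalSet":
        probes = self.M.index if probes is None else probes
        samples = self.M.columns if samples is None else samples
        return SignalSet(
            M=self.M.loc[probes, samples],
            U=self.U.loc[probes, samples],
            bead_count=self.bead_count.loc[probes, samples],
            negctrl=self.negctrl.loc[:, samples],
        )


@dataclass
class BetaMatrix:
    """Methylation fractions with an explicit missingness mask.

    ``beta`` holds M/(M+U+alpha) values; cells flagged in ``mask`` (True =
    missing) are also NaN in ``beta`` so that downstream median/t-test code
    can rely on NaN-aware reductions alone.
    """

    beta: pd.DataFrame
    mask: pd.DataFrame
    alpha: float = 100.0

    def __post_init__(self) -> None:
        if not (self.mask.index.equals(self.beta.index) and self.mask.columns.equals(self.beta.columns)):
            raise ValueError("mask is not aligned with beta")
        vals = self.beta.to_numpy()
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals < 1.0))
        if not ok.all():
            raise ValueError("beta values must lie in [0, 1)")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    def values_masked(self) -> pd.DataFrame:
        """Beta matrix with masked cells forced to NaN."""
        return self.beta.mask(self.mask)


@dataclass
class QCReport:
    """Record of every probe/sample removal decision made by QC."""

    probes_removed_beads: list[str] = field(default_factory=list)
    samples_removed: dict[str, float] = field(default_factory=dict)  # id -> success rate
    sites_removed_missing: list[str] = field(default_factory=list)
    n_cells_masked: int = 0
    thresholds: dict[str, float] = field(default_factory=dict)
    detection_model: str = "one-sided z-test of M+U against per-sample negative-control mean/sd"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.probes_removed_beads:
            rows.append(("probe", p, "bead_count", ""))
        for s, rate in self.samples_removed.items():
            rows.append(("sample", s, "low_success_rate", f"{rate:.4f}"))
        for p in self.sites_removed_missing:
            rows.append(("probe", p, "missing_fraction", ""))
        return pd.DataFrame(rows, columns=["kind", "id", "reason", "detail"])

    def log_lines(self) -> list[str]:
        return [
            f"QC: removed {len(self.probes_removed_beads)} probes with bead count < {self.thresholds.get('bead_min')}",
            f"QC: removed {len(self.samples_removed)} samples with success rate < {self.thresholds.get('sample_success_min')}",
            f"QC: masked {self.n_cells_masked} beta cells with detection p > {self.thresholds.get('detection_max')}",
            f"QC: removed {len(self.sites_removed_missing)} sites with missing fraction > {self.thresholds.get('site_missing_max')}",
            f"QC: detection p model: {self.detection_model}",
        ]


@dataclass(frozen=True)
class Comparison:
    """One condition-vs-reference contrast over named sample groups."""

    name: str
    cond_group: str
    ref_group: str
    cond_samples: tuple[str, ...]
    ref_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.cond_samples) & set(self.ref_samples):
            raise ValueError("condition and reference samples overlap")
        if len(self.cond_samples) < 2 or len(self.ref_samples) < 2:
            raise ValueError("need at least 2 samples per side for a p-value")

    @classmethod
    def from_design(cls, name: str, cond_group: str, ref_group: str, design: dict[str, str]) -> "Comparison":
        cond = tuple(s for s, g in design.items() if g == cond_group)
        ref = tuple(s for s, g in design.items() if g == ref_group)
        if not cond or not ref:
            raise ValueError(f"design lacks samples for {cond_group!r} or {ref_group!r}")
        return cls(name, cond_group, ref_group, cond, ref)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants and return the frame unchanged."""
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in manifest")
    if (manifest["position"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    intergenic = manifest["gene_feature"] == "Intergenic"
    empty = manifest["gene_symbol"].fillna("") == ""
    if not (intergenic == empty).all():
        raise ValueError("gene_feature must be Intergenic exactly when gene_symbol is empty")
    return manifest
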