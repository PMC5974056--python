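"""Synthetic 450K-style experiment generator and bundled gene-list fixtures.

The generator emulates the study design the pipeline targets: 9 blood
samples in three stages (3 Normal, 3 LA Type I, 3 LA Type II) measured on
a two-colour methylation array.  It produces a probe manifest with CpG
island context, methylated/unmethylated intensity matrices with bead
counts and negative controls, and records the planted ground truth so
recovery can be scored.

Signal model
------------
The beta formula beta = M/(M+U+alpha) is inverted exactly: given a target
beta and a lognormal total intensity T, set K = max(T+alpha,
alpha/(1-beta)), M = beta*K and U = (1-beta)*K - alpha, so that
compute_beta recovers the target to machine precision whenever beta < 1.
A target of exactly 1 is represented with U = 0, whose computed beta
M/(M+alpha) stays below 1 — the offset makes fully-methylated signals
unreachable by construction.  Per-sample noise is Gaussian on the beta
scale, then clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import annotate
from .containers import GENE_FEATURES, GROUPS, ISLAND_RELATIONS, SignalSet, validate_manifest

DEFAULT_DESIGN = {
    "N1": "Normal", "N2": "Normal", "N3": "Normal",
    "T1_1": "TypeI", "T1_2": "TypeI", "T1_3": "TypeI",
    "T2_1": "TypeII", "T2_2": "TypeII", "T2_3": "TypeII",
}

_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)

# manifest category frequencies (roughly chip-like; islands and flanks
# over-represented relative to genome so every class is well populated)
_ISLAND_PROBS = {"Island": 0.30, "N_Shore": 0.14, "S_Shore": 0.14,
                 "N_Shelf": 0.06, "S_Shelf": 0.06, "OpenSea": 0.30}
_FEATURE_PROBS = {"Body": 0.40, "TSS200": 0.12, "TSS1500": 0.18,
                  "FiveUTR": 0.12, "FirstExon": 0.08, "ThreeUTR": 0.10}
_P_INTERGENIC = 0.25

_MIN_ISLAND_GAP = 20_000  # keeps offset-based placement unambiguous


def make_islands(n_islands: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Non-overlapping CpG-island intervals spread over the chromosomes.

    Islands on the same chromosome are separated by at least 20 kb so that
    shore/shelf flanks of neighbouring islands never interleave.
    """
    if n_islands < 1:
        raise ValueError("n_islands must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = rng.choice(len(_CHROMS), size=n_islands)
    rows = []
    cursor: dict[str, int] = {}
    for k, ci in enumerate(chroms):
        chrom = _CHROMS[ci]
        start = cursor.get(chrom, 10_000) + int(rng.exponential(30_000))
        length = int(rng.integers(200, 2_000))
        end = start + length
        cursor[chrom] = end + _MIN_ISLAND_GAP
        rows.append((chrom, start, end, f"CGI_{k:05d}"))
    return pd.DataFrame(rows, columns=list(annotate.ISLAND_COLUMNS))


def make_manifest(
    n_probes: int,
    n_islands: int,
    seed: int = 0,
    return_islands: bool = False,
):
    """Random probe manifest consistent with a generated island set.

    Each probe is placed at an offset from a sampled island chosen to
    realise a target island-relation category; the stored relation is then
    recomputed with :func:`annotate.island_relations`, so manifest and
    distance convention agree by construction.  With ``n_probes >= 50``
    the leading probes cycle through every island-relation and
    gene-feature category so none is empty.
    """
    if n_probes < 1 or n_islands < 1 or n_probes < n_islands:
        raise ValueError("need n_probes >= n_islands >= 1")
    rng = np.random.default_rng(seed)
    islands = make_islands(n_islands, rng)
    index = annotate.make_island_index(islands)

    rel_names = list(_ISLAND_PROBS)
    rel_choice = rng.choice(len(rel_names), size=n_probes, p=list(_ISLAND_PROBS.values()))
    island_rows = rng.integers(0, n_islands, size=n_probes)
    # deterministic leading block guarantees category coverage
    for i in range(min(n_probes, len(ISLAND_RELATIONS))):
        rel_choice[i] = rel_names.index(ISLAND_RELATIONS[i])

    positions = np.empty(n_probes, dtype=np.int64)
    chrom_arr = np.empty(n_probes, dtype=object)
    for i in range(n_probes):
        isl = islands.iloc[int(island_rows[i])]
        start, end = int(isl["start"]), int(isl["end"])
        rel = rel_names[int(rel_choice[i])]
        if rel == "Island":
            pos = int(rng.integers(start, end + 1))
        elif rel == "N_Shore":
            pos = start - int(rng.integers(1, annotate.SHORE_BP + 1))
        elif rel == "S_Shore":
            pos = end + int(rng.integers(1, annotate.SHORE_BP + 1))
        elif rel == "N_Shelf":
            pos = start - int(rng.integers(annotate.SHORE_BP + 1, annotate.SHELF_BP + 1))
        elif rel == "S_Shelf":
            pos = end + int(rng.integers(annotate.SHORE_BP + 1, annotate.SHELF_BP + 1))
        else:  # OpenSea
            pos = end + int(rng.integers(annotate.SHELF_BP + 1, annotate.SHELF_BP + 6_000))
        positions[i] = max(pos, 1)
        chrom_arr[i] = isl["chromosome"]

    manifest = pd.DataFrame({
        "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
        "chromosome": chrom_arr,
        "position": positions,
        "gene_symbol": "",
        "gene_feature": "Intergenic",
        "strand": rng.choice(["+", "-"], size=n_probes),
    })
    manifest["island_relation"] = annotate.island_relations(manifest, index)

    # gene annotation: genic probes draw a feature and a symbol from a pool
    n_genes = max(1, n_probes // 3)
    pool = [f"GENE{i:05d}" for i in range(n_genes)]
    genic = rng.random(n_probes) >= _P_INTERGENIC
    feats = list(_FEATURE_PROBS)
    feat_draw = rng.choice(len(feats), size=n_probes, p=list(_FEATURE_PROBS.values()))
    gene_draw = rng.integers(0, n_genes, size=n_probes)
    for i in range(min(n_probes, len(GENE_FEATURES))):
        f = GENE_FEATURES[i]
        genic[i] = f != "Intergenic"
        if f != "Intergenic":
            feat_draw[i] = feats.index(f)
    manifest.loc[genic, "gene_feature"] = [feats[j] for j in feat_draw[genic]]
    manifest.loc[genic, "gene_symbol"] = [pool[j] for j in gene_draw[genic]]

    manifest = manifest[["probe_id", "chromosome", "position", "island_relation",
                         "gene_symbol", "gene_feature", "strand"]]
    validate_manifest(manifest)
    if return_islands:
        return manifest, islands
    return manifest


def make_truth(
    manifest: pd.DataFrame,
    planted: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Full per-probe ground-truth table with clipped group targets.

    ``planted`` rows (probe_id, base_beta, effect_typeI, effect_typeII)
    override the defaults; all other probes draw a bimodal baseline beta
    and carry zero effects.  Group targets are ``clip(base + effect, 0, 1)``
    and the clipped values are what recovery is scored against.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(manifest)
    low = rng.beta(1.2, 8.0, size=n)
    high = rng.beta(8.0, 1.2, size=n)
    base = np.where(rng.random(n) < 0.5, low, high)
    truth = pd.DataFrame({
        "probe_id": manifest["probe_id"].to_numpy(),
        "base_beta": base,
        "effect_typeI": 0.0,
        "effect_typeII": 0.0,
    })
    if planted is not None and len(planted):
        unknown = set(planted["probe_id"]) - set(truth["probe_id"])
        if unknown:
            raise ValueError(f"planted probes absent from manifest: {sorted(unknown)[:5]}")
        truth = truth.set_index("probe_id")
        sub = planted.set_index("probe_id")
        truth.loc[sub.index, ["base_beta", "effect_typeI", "effect_typeII"]] = sub[
            ["base_beta", "effect_typeI", "effect_typeII"]
        ]
        truth = truth.reset_index()
    truth["target_Normal"] = truth["base_beta"].clip(0.0, 1.0)
    truth["target_TypeI"] = (truth["base_beta"] + truth["effect_typeI"]).clip(0.0, 1.0)
    truth["target_TypeII"] = (truth["base_beta"] + truth["effect_typeII"]).clip(0.0, 1.0)
    return truth


def simulate_intensities(
    manifest: pd.DataFrame,
    design: dict[str, str] | None = None,
    truth: pd.DataFrame | None = None,
    noise_sd: float = 0.02,
    mean_total_intensity: float = 10_000.0,
    seed: int = 0,
    alpha: float = 100.0,
    low_bead_fraction: float = 0.0,
    bead_lambda: float = 14.0,
    negctrl_mean: float = 200.0,
    n_negctrl: int = 200,
) -> tuple[SignalSet, pd.DataFrame]:
    """Simulate a two-signal experiment realising the truth table's betas.

    ``design`` maps sample id -> group and must cover Normal, TypeI and
    TypeII.  ``truth`` may be a planted-effect table (see
    :func:`make_truth`) or None for a pure-null experiment.  Returns the
    SignalSet and the full ground-truth table (clipped targets included).
    """
    if not 0 <= noise_sd <= 0.2:
        raise ValueError("noise_sd must lie in [0, 0.2]")
    if mean_total_intensity <= 0:
        raise ValueError("mean_total_intensity must be positive")
    design = dict(DEFAULT_DESIGN) if design is None else dict(design)
    bad = set(design.values()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if set(design.values()) != set(GROUPS):
        raise ValueError("design must cover Normal, TypeI and TypeII")

    rng = np.random.default_rng(seed)
    if truth is None or "target_Normal" not in getattr(truth, "columns", ()):
        truth = make_truth(manifest, planted=truth, seed=rng)

    samples = list(design)
    n_p, n_s = len(truth), len(samples)
    targets = np.column_stack([truth[f"target_{design[s]}"].to_numpy() for s in samples])
    beta = targets
    if noise_sd > 0:
        beta = np.clip(targets + rng.normal(0.0, noise_sd, size=(n_p, n_s)), 0.0, 1.0)

    T = rng.lognormal(mean=np.log(mean_total_intensity), sigma=0.25, size=(n_p, n_s))
    full = beta >= 1.0
    safe = np.minimum(beta, np.nextafter(1.0, 0.0))
    K = np.maximum(T + alpha, alpha / (1.0 - safe))
    M = safe * K
    U = np.maximum((1.0 - safe) * K - alpha, 0.0)
    M[full] = T[full]
    U[full] = 0.0

    beads = np.maximum(rng.poisson(bead_lambda, size=(n_p, n_s)), 1)
    n_low = int(round(low_bead_fraction * n_p))
    if n_low:
        rows = rng.choice(n_p, size=n_low, replace=False)
        cols = rng.integers(0, n_s, size=n_low)
        beads[rows, cols] = rng.integers(1, 3, size=n_low)

    negctrl = rng.lognormal(np.log(negctrl_mean), 0.25, size=(n_negctrl, n_s))

    idx = pd.Index(truth["probe_id"], name="probe_id")
    signals = SignalSet(
        M=pd.DataFrame(M, index=idx, columns=samples),
        U=pd.DataFrame(U, index=idx, columns=samples),
        bead_count=pd.DataFrame(beads, index=idx, columns=samples),
        negctrl=pd.DataFrame(negctrl, columns=samples),
    )
    return signals, truth


def simulate_expression_lists(
    meth_genes,
    overlap_blood: int,
    overlap_tissue: int,
    seed: int = 0,
    n_blood: int = 179,
    n_tissue: int = 360,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two stand-in differential-expression lists with planted overlaps.

    The blood and tissue lists overlap the methylation gene set in exactly
    ``overlap_blood`` and ``overlap_tissue`` genes, chosen disjointly so
    the combined overlap is their sum; remaining entries are filler
    symbols outside the methylation set.  Directions are random up/down.
    """
    genes = sorted(set(meth_genes))
    if overlap_blood < 0 or overlap_tissue < 0:
        raise ValueError("overlaps must be non-negative")
    if overlap_blood + overlap_tissue > len(genes):
        raise ValueError("requested overlaps exceed the methylation gene set")
    if overlap_blood > n_blood or overlap_tissue > n_tissue:
        raise ValueError("overlap larger than the requested list size")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(genes), size=overlap_blood + overlap_tissue, replace=False)
    blood_genes = [genes[i] for i in picked[:overlap_blood]]
    tissue_genes = [genes[i] for i in picked[overlap_blood:]]
    blood_genes += [f"EXPRB{i:05d}" for i in range(n_blood - overlap_blood)]
    tissue_genes += [f"EXPRT{i:05d}" for i in range(n_tissue - overlap_tissue)]

    def frame(symbols, source):
        return pd.DataFrame({
            "gene_symbol": symbols,
            "direction": rng.choice(["up", "down"], size=len(symbols)),
            "source": source,
        })

    return frame(blood_genes, "blood"), frame(tissue_genes, "tissue")


def plant_stage_effects(
    manifest: pd.DataFrame,
    seed: int = 0,
    n_occurrence: int = 8,
    n_progression: int = 8,
    n_inverse: int = 8,
    n_same: int = 4,
    effect: float = 0.30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant stage-patterned effects on whole genes for end-to-end tests.

    Four gene roles mirror the staged analysis: occurrence-specific genes
    shift at Type I and hold (significant in occurrence and overall,
    not progression); progression-specific genes shift only at Type II;
    shared-inverse genes shift at Type I and revert; shared-same genes
    shift at Type I and shift again at Type II.  Every probe of a planted
    gene carries the effect with a baseline leaving headroom, so clipping
    never attenuates the planted contrast.

    Returns (planted probe-truth table, gene-role table).
    """
    rng = np.random.default_rng(seed)
    genic = manifest[manifest["gene_symbol"] != ""]
    genes = genic["gene_symbol"].unique()
    need = n_occurrence + n_progression + n_inverse + n_same
    if need > len(genes):
        raise ValueError(f"manifest has only {len(genes)} genes; {need} requested")
    chosen = rng.choice(genes, size=need, replace=False)
    roles = (
        ["occurrence_specific"] * n_occurrence
        + ["progression_specific"] * n_progression
        + ["shared_inverse"] * n_inverse
        + ["shared_same"] * n_same
    )
    probe_rows, gene_rows = [], []
    for gene, role in zip(chosen, roles):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        e = sign * effect
        if role == "occurrence_specific":
            e1, e2 = e, e
        elif role == "progression_specific":
            e1, e2 = 0.0, e
        elif role == "shared_inverse":
            e1, e2 = e, 0.0
        else:  # shared_same: second step continues in the same direction
            e1, e2 = e, 2 * e
        lo, hi = (0.12, 0.35) if sign > 0 else (0.65, 0.88)
        for pid in genic.loc[genic["gene_symbol"] == gene, "probe_id"]:
            probe_rows.append((pid, float(rng.uniform(lo, hi)), e1, e2))
        gene_rows.append((gene, role, "hyper" if sign > 0 else "hypo"))
    planted = pd.DataFrame(probe_rows, columns=["probe_id", "base_beta", "effect_typeI", "effect_typeII"])
    gene_truth = pd.DataFrame(gene_rows, columns=["gene_symbol", "role", "direction"])
    return planted, gene_truth


@dataclass
class SharedGeneFixture:
    """Published per-gene methylation directions for the staged contrasts.

    ``records`` lists the 32 genes called in both the occurrence
    (Type I vs Normal) and progression (Type II vs Type I) contrasts with
    their direction on each side; ``occurrence_specific`` and
    ``progression_specific`` are the 11- and 20-gene stage-specific lists.
    """

    records: pd.DataFrame
    occurrence_specific: list[str]
    progression_specific: list[str]

    def to_gene_results(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Split into occurrence- and progression-side direction tables."""
        occ = self.records[["gene_symbol", "occ_direction"]].rename(columns={"occ_direction": "direction"})
        prog = self.records[["gene_symbol", "prog_direction"]].rename(columns={"prog_direction": "direction"})
        return occ.assign(comparison="TypeI_vs_Normal"), prog.assign(comparison="TypeII_vs_TypeI")


def load_shared_gene_fixture() -> SharedGeneFixture:
    """Load the bundled shared/stage-specific gene tables."""
    pkg = resources.files("lamethyl.data")
    with resources.as_file(pkg / "shared_genes.tsv") as path:
        records = pd.read_csv(path, sep="\t")
    with resources.as_file(pkg / "stage_specific_genes.tsv") as path:
        specific = pd.read_csv(path, sep="\t")
    occ = specific.loc[specific["stage"] == "occurrence", "gene_symbol"].tolist()
    prog = specific.loc[specific["stage"] == "progression", "gene_symbol"].tolist()
    return SharedGeneFixture(records=records, occurrence_specific=occ, progression_specific=prog)
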