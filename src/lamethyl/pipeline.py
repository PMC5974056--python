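"""End-to-end pipeline: simulate -> QC -> call -> annotate -> stage -> integrate.

Every stage writes plain TSV tables into the output directory and a
``run_manifest.json`` records the configuration, seeds, package version
and a sha256 checksum of every file, so reruns are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotate, diffmeth, integration, io, preprocess, staging, synthetic

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the staged analysis; defaults are the study's values
    (alpha 100, |delta beta| >= 0.17, |DiffScore| > 13, detection p 0.01,
    bead count 3, sample success 95%, site missingness 1%)."""

    alpha: float = 100.0
    delta_min: float = 0.17
    score_min: float = 13.0
    detection_max: float = 0.01
    bead_min: int = 3
    sample_success_min: float = 0.95
    site_missing_max: float = 0.01

    seed: int = 0
    n_probes: int = 10_000
    n_islands: int = 300
    noise_sd: float = 0.02
    mean_total_intensity: float = 10_000.0
    low_bead_fraction: float = 0.005
    overlap_blood: int = 1
    overlap_tissue: int = 6

    bh_adjust: bool = False
    normalize: bool = False
    specific_exclude_other: bool = True
    run_trend: bool = True
    input_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _call(betas, design, name, config: PipelineConfig) -> pd.DataFrame:
    sites = staging.run_comparison(betas, design, name,
                                   delta_min=config.delta_min, score_min=config.score_min)
    if config.bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ok = sites["p_value"].notna()
        q = pd.Series(float("nan"), index=sites.index)
        if ok.any():
            q.loc[ok] = multipletests(sites.loc[ok, "p_value"], method="fdr_bh")[1]
        sites["q_value"] = q
        sites["significant"] = sites["significant"] & (sites["q_value"] <= 0.05)
    return sites


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full staged analysis and write the result bundle.

    Returns a dict with the in-memory tables; every table is also written
    under ``outdir``.  Deterministic for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs: load or simulate -----------------------------------------
    if config.input_dir:
        indir = Path(config.input_dir)
        manifest = io.read_manifest(indir / "manifest.tsv")
        design = io.read_sample_sheet(indir / "sample_sheet.tsv")
        signals = io.read_signals(indir / "signals")
        truth = gene_truth = None
    else:
        manifest = synthetic.make_manifest(config.n_probes, config.n_islands, seed=config.seed)
        design = dict(synthetic.DEFAULT_DESIGN)
        planted, gene_truth = synthetic.plant_stage_effects(manifest, seed=config.seed + 1)
        signals, truth = synthetic.simulate_intensities(
            manifest, design, truth=planted,
            noise_sd=config.noise_sd,
            mean_total_intensity=config.mean_total_intensity,
            seed=config.seed + 2,
            alpha=config.alpha,
            low_bead_fraction=config.low_bead_fraction,
        )
        io.write_manifest(manifest, outdir / "manifest.tsv")
        io.write_sample_sheet(design, outdir / "sample_sheet.tsv")
        io.write_signals(signals, outdir / "signals")
        truth.to_csv(outdir / "planted_truth.tsv", sep="\t", index=False)
        gene_truth.to_csv(outdir / "planted_genes.tsv", sep="\t", index=False)

    # --- preprocess --------------------------------------------------------
    betas = preprocess.compute_beta_matrix(signals, alpha=config.alpha)
    betas, qc = preprocess.qc_filter(
        signals, betas,
        bead_min=config.bead_min,
        detection_max=config.detection_max,
        sample_success_min=config.sample_success_min,
        site_missing_max=config.site_missing_max,
    )
    if config.normalize:
        betas = preprocess.median_scale(betas)
    for line in qc.log_lines():
        log.info(line)
    qc.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    (outdir / "qc_log.txt").write_text("\n".join(qc.log_lines()) + "\n")
    io.write_betas(betas, outdir / "betas")
    design = {s: g for s, g in design.items() if s in betas.samples}

    # --- differential calls, annotation ------------------------------------
    sites, gene_tables, summaries = {}, {}, {}
    for name in staging.COMPARISONS:
        tab = _call(betas, design, name, config)
        sites[name] = tab
        tab.to_csv(outdir / f"sites_{name}.tsv", sep="\t", index=False)
        diffmeth.volcano_table(tab).to_csv(outdir / f"volcano_{name}.tsv", sep="\t", index=False)
        io.write_sites_bed(tab, manifest, outdir / f"significant_{name}.bed")
        summary = annotate.summarize_annotations(tab.loc[tab["significant"]], manifest)
        summaries[name] = summary
        summary.to_frame().to_csv(outdir / f"annotation_summary_{name}.tsv", sep="\t", index=False)
        genes = staging.map_to_genes(tab, manifest)
        gene_tables[name] = genes
        genes.to_csv(outdir / f"genes_{name}.tsv", sep="\t", index=False)

    if config.run_trend:
        trend = diffmeth.site_trend_regression(betas, design)
        trend.to_csv(outdir / "trend_regression.tsv", sep="\t", index=False)
    else:
        trend = None

    # --- staging: shared and specific gene sets -----------------------------
    shared = staging.classify_shared(gene_tables[staging.OCCURRENCE], gene_tables[staging.PROGRESSION])
    shared.records.to_csv(outdir / "shared_genes.tsv", sep="\t", index=False)
    pd.DataFrame([shared.summary()]).to_csv(outdir / "shared_summary.tsv", sep="\t", index=False)
    occ_specific, prog_specific = staging.derive_specific(
        gene_tables[staging.OCCURRENCE],
        gene_tables[staging.PROGRESSION],
        gene_tables[staging.OVERALL],
        exclude_other=config.specific_exclude_other,
    )
    specific = pd.DataFrame(
        [(g, "occurrence") for g in sorted(occ_specific)]
        + [(g, "progression") for g in sorted(prog_specific)],
        columns=["gene_symbol", "stage"],
    )
    specific.to_csv(outdir / "specific_genes.tsv", sep="\t", index=False)
    venn = pd.DataFrame([{
        "n_occurrence_genes": len(gene_tables[staging.OCCURRENCE]),
        "n_progression_genes": len(gene_tables[staging.PROGRESSION]),
        "n_overall_genes": len(gene_tables[staging.OVERALL]),
        "n_shared": shared.n_shared,
        "n_occurrence_specific": len(occ_specific),
        "n_progression_specific": len(prog_specific),
    }])
    venn.to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)

    # --- integration with expression stand-ins ------------------------------
    meth_union = pd.concat(gene_tables.values(), ignore_index=True)
    meth_genes = _gene_meth_table(meth_union, manifest)
    blood, tissue = synthetic.simulate_expression_lists(
        set(meth_genes["gene_symbol"]) or {"NONE"},
        overlap_blood=min(config.overlap_blood, len(meth_genes)),
        overlap_tissue=min(config.overlap_tissue, max(len(meth_genes) - config.overlap_blood, 0)),
        seed=config.seed + 3,
    )
    blood.to_csv(outdir / "expression_blood.tsv", sep="\t", index=False)
    tissue.to_csv(outdir / "expression_tissue.tsv", sep="\t", index=False)
    integ_table, integ_counts = integration.overlap_expression(meth_genes, blood, tissue)
    integ_table.to_csv(outdir / "integration.tsv", sep="\t", index=False)
    pd.DataFrame([integ_counts]).to_csv(outdir / "integration_counts.tsv", sep="\t", index=False)

    _write_run_manifest(config, outdir)
    return {
        "manifest": manifest,
        "design": design,
        "qc": qc,
        "betas": betas,
        "sites": sites,
        "summaries": summaries,
        "gene_tables": gene_tables,
        "shared": shared,
        "occ_specific": occ_specific,
        "prog_specific": prog_specific,
        "trend": trend,
        "integration": integ_table,
        "integration_counts": integ_counts,
        "truth": truth,
        "gene_truth": gene_truth,
    }


def _gene_meth_table(gene_union: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """One row per methylation gene with direction and promoter/body region."""
    if gene_union.empty:
        return pd.DataFrame(columns=["gene_symbol", "direction", "region"])
    first = gene_union.drop_duplicates("gene_symbol").copy()
    feat = (
        manifest.loc[manifest["gene_symbol"] != ""]
        .drop_duplicates("gene_symbol")
        .set_index("gene_symbol")["gene_feature"]
    )
    first["region"] = [integration.region_class(feat.get(g, "Intergenic")) for g in first["gene_symbol"]]
    return first[["gene_symbol", "direction", "region"]]


def _write_run_manifest(config: PipelineConfig, outdir: Path) -> None:
    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "run_manifest.json":
            checksums[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "package": "lamethyl",
        "version": __version__,
        "config": config.to_dict(),
        "checksums": checksums,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
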