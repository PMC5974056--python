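"""Plain-TSV readers/writers for every pipeline artifact.

File conventions: manifests use columns (probe_id, chr, pos,
island_relation, gene_symbol, gene_feature, strand) with 1-based
positions; signal sets are three probes-x-samples matrices (M, U,
bead_count) plus a controls-x-samples negctrl table; sample sheets map
sample_id -> group.  BED export converts to 0-based half-open intervals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import BetaMatrix, SignalSet, validate_manifest

_MANIFEST_FILE_COLS = {"chromosome": "chr", "position": "pos"}


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.rename(columns=_MANIFEST_FILE_COLS)
    out.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", dtype={"chr": str})
    man = man.rename(columns={v: k for k, v in _MANIFEST_FILE_COLS.items()})
    man["gene_symbol"] = man["gene_symbol"].fillna("")
    return validate_manifest(man)


def write_signals(signals: SignalSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signals.M.to_csv(directory / "M.tsv", sep="\t")
    signals.U.to_csv(directory / "U.tsv", sep="\t")
    signals.bead_count.to_csv(directory / "bead_count.tsv", sep="\t")
    signals.negctrl.to_csv(directory / "negctrl.tsv", sep="\t", index=False)


def read_signals(directory) -> SignalSet:
    directory = Path(directory)
    read = lambda name: pd.read_csv(directory / name, sep="\t", index_col=0)
    return SignalSet(
        M=read("M.tsv"),
        U=read("U.tsv"),
        bead_count=read("bead_count.tsv"),
        negctrl=pd.read_csv(directory / "negctrl.tsv", sep="\t"),
    )


def write_sample_sheet(design: dict[str, str], path) -> None:
    pd.DataFrame({"sample_id": list(design), "group": list(design.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_sample_sheet(path) -> dict[str, str]:
    sheet = pd.read_csv(path, sep="\t")
    return dict(zip(sheet["sample_id"].astype(str), sheet["group"]))


def write_betas(betas: BetaMatrix, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    betas.beta.to_csv(directory / "beta.tsv", sep="\t")
    betas.mask.to_csv(directory / "missing_mask.tsv", sep="\t")


def read_betas(directory, alpha: float = 100.0) -> BetaMatrix:
    directory = Path(directory)
    beta = pd.read_csv(directory / "beta.tsv", sep="\t", index_col=0)
    mask = pd.read_csv(directory / "missing_mask.tsv", sep="\t", index_col=0).astype(bool)
    return BetaMatrix(beta=beta, mask=mask, alpha=alpha)


def write_sites_bed(site_results: pd.DataFrame, manifest: pd.DataFrame, path) -> None:
    """Significant sites as BED (0-based half-open) for browser tracks."""
    sig = site_results.loc[site_results["significant"]]
    man = manifest.set_index("probe_id")
    ann = man.loc[sig["probe_id"]]
    bed = pd.DataFrame({
        "chrom": ann["chromosome"].to_numpy(),
        "start": ann["position"].to_numpy() - 1,
        "end": ann["position"].to_numpy(),
        "name": sig["probe_id"].to_numpy(),
        "score": sig["diff_score"].abs().round(3).to_numpy(),
        "strand": ann["strand"].to_numpy(),
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_expression_list(path, source: str | None = None) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t")
    if source is not None:
        expr["source"] = source
    return expr
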