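"""Beta-value computation, detection p-values, and probe/sample QC.

The methylation fraction at a CpG is beta = M / (M + U + alpha), where M
and U are the methylated and unmethylated fluorescence intensities and
alpha (default 100) is an offset stabilising the ratio at low intensity.
Beta therefore lies in [0, 1) for finite signals.

Detection confidence follows the documented BeadChip convention: the
total signal M + U is compared against the per-sample negative-control
background with a one-sided upper-tail z-test; a large p means the probe
is indistinguishable from background.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, QCReport, SignalSet

DEFAULT_ALPHA = 100.0


def compute_beta(M, U, alpha: float = DEFAULT_ALPHA):
    """beta = M / (M + U + alpha), vectorized over arrays/DataFrames.

    Raises on negative intensities or non-positive alpha.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    M_arr = np.asarray(M, dtype=float) if not isinstance(M, pd.DataFrame) else M
    U_arr = np.asarray(U, dtype=float) if not isinstance(U, pd.DataFrame) else U
    if np.any(np.asarray(M_arr) < 0) or np.any(np.asarray(U_arr) < 0):
        raise ValueError("intensities must be non-negative")
    return M_arr / (M_arr + U_arr + alpha)


def compute_beta_matrix(signals: SignalSet, alpha: float = DEFAULT_ALPHA) -> BetaMatrix:
    """Beta matrix for a whole SignalSet, with an all-False missing mask."""
    beta = compute_beta(signals.M, signals.U, alpha)
    mask = pd.DataFrame(False, index=beta.index, columns=beta.columns)
    return BetaMatrix(beta=beta, mask=mask, alpha=alpha)


def detection_p(M, U, negctrl_mean, negctrl_sd):
    """One-sided upper-tail probability that M+U arises from background.

    Background is modelled N(negctrl_mean, negctrl_sd); the returned value
    is P(background >= M+U), small when the probe signal is well above
    background.
    """
    if np.any(np.asarray(negctrl_sd) <= 0):
        raise ValueError("negative-control sd must be positive")
    total = np.asarray(M, dtype=float) + np.asarray(U, dtype=float)
    z = (total - np.asarray(negctrl_mean, dtype=float)) / np.asarray(negctrl_sd, dtype=float)
    return stats.norm.sf(z)


def detection_p_matrix(signals: SignalSet) -> pd.DataFrame:
    """Per-cell detection p using each sample's own negative controls."""
    mu = signals.negctrl.mean(axis=0).to_numpy()
    sd = signals.negctrl.std(axis=0, ddof=1).to_numpy()
    p = detection_p(signals.M.to_numpy(), signals.U.to_numpy(), mu[None, :], sd[None, :])
    return pd.DataFrame(p, index=signals.M.index, columns=signals.M.columns)


def median_scale(betas: BetaMatrix) -> BetaMatrix:
    """Optional per-sample median scaling of beta values (off by default
    in the pipeline: raw signals are used without normalization).

    Each sample's betas are rescaled so that all samples share the grand
    median, then clipped back below 1.
    """
    vals = betas.values_masked()
    med = vals.median(axis=0)
    grand = float(np.nanmedian(vals.to_numpy()))
    scaled = vals * (grand / med)
    scaled = scaled.clip(lower=0.0, upper=np.nextafter(1.0, 0.0))
    return BetaMatrix(beta=scaled, mask=betas.mask.copy(), alpha=betas.alpha)


def qc_filter(
    signals: SignalSet,
    betas: BetaMatrix | None = None,
    bead_min: int = 3,
    detection_max: float = 0.01,
    sample_success_min: float = 0.95,
    site_missing_max: float = 0.01,
    bead_rule: str = "any",
) -> tuple[BetaMatrix, QCReport]:
    """Apply probe/sample quality control in a fixed order.

    1. drop probes whose bead count is below ``bead_min`` in any sample
       (``bead_rule="all"`` requires every sample to fail);
    2. drop samples whose fraction of remaining probes detected at
       p <= ``detection_max`` falls below ``sample_success_min``;
    3. mask beta cells with detection p > ``detection_max`` as missing;
    4. drop sites whose missing fraction exceeds ``site_missing_max``.

    Returns the filtered BetaMatrix and a QCReport recording every
    removal decision.  Raises if nothing survives.
    """
    if not (0 < detection_max < 1 and 0 < sample_success_min <= 1 and 0 <= site_missing_max < 1):
        raise ValueError("QC thresholds out of range")
    if bead_rule not in ("any", "all"):
        raise ValueError("bead_rule must be 'any' or 'all'")
    if betas is None:
        betas = compute_beta_matrix(signals)

    report = QCReport(thresholds={
        "bead_min": bead_min,
        "detection_max": detection_max,
        "sample_success_min": sample_success_min,
        "site_missing_max": site_missing_max,
    })

    low = signals.bead_count < bead_min
    bad_beads = low.any(axis=1) if bead_rule == "any" else low.all(axis=1)
    report.probes_removed_beads = list(signals.probes[bad_beads])
    keep_probes = signals.probes[~bad_beads]
    if len(keep_probes) == 0:
        raise ValueError("QC removed every probe at the bead-count step")

    sub = signals.subset(probes=keep_probes)
    det_p = detection_p_matrix(sub)
    success = (det_p <= detection_max).mean(axis=0)
    bad_samples = success[success < sample_success_min]
    report.samples_removed = {s: float(r) for s, r in bad_samples.items()}
    keep_samples = [s for s in sub.samples if s not in bad_samples.index]
    if not keep_samples:
        raise ValueError("QC removed every sample")

    det_p = det_p.loc[:, keep_samples]
    beta = betas.beta.loc[keep_probes, keep_samples]
    mask = betas.mask.loc[keep_probes, keep_samples] | (det_p > detection_max)
    report.n_cells_masked = int((mask & ~betas.mask.loc[keep_probes, keep_samples]).to_numpy().sum())

    missing_frac = mask.mean(axis=1)
    bad_sites = missing_frac > site_missing_max
    report.sites_removed_missing = list(beta.index[bad_sites])
    beta = beta.loc[~bad_sites]
    mask = mask.loc[~bad_sites]
    if beta.empty:
        raise ValueError("QC removed every site at the missingness step")

    beta = beta.mask(mask)
    return BetaMatrix(beta=beta, mask=mask, alpha=betas.alpha), report
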