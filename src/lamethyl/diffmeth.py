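"""Locus-by-locus differential methylation calling.

For each CpG site and a condition/reference pair of sample groups the
module computes:

* ``delta_beta`` — difference of robust (median) group beta values;
* a two-sided Welch t-test p-value on the per-sample betas;
* ``DiffScore`` — the signed significance score ``sgn(delta_beta) *
  |10 * log10(p)|``; |DiffScore| = 13 corresponds to p = 0.05.

A site is called significant when |delta_beta| >= 0.17 (inclusive) and
|DiffScore| > 13 (strict), the conjunction used throughout the staged
leukoaraiosis contrasts.  A positive DiffScore marks hypermethylation of
the condition group, a negative one hypomethylation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BetaMatrix, Comparison

DELTA_MIN = 0.17
SCORE_MIN = 13.0

_P_FLOOR = 1e-300  # keeps log10(p) finite for zero-variance separations


def delta_beta(betas_cond, betas_ref) -> float:
    """Median(condition) - median(reference), ignoring missing values."""
    c = np.asarray(betas_cond, dtype=float)
    r = np.asarray(betas_ref, dtype=float)
    if np.isnan(c).all() or np.isnan(r).all():
        raise ValueError("a group has no non-missing beta values")
    return float(np.nanmedian(c) - np.nanmedian(r))


def site_p_value(betas_cond, betas_ref) -> float:
    """Two-sided Welch t-test p-value on per-sample betas.

    Zero-variance degenerate cases are resolved explicitly: identical
    constant groups carry no evidence (p = 1); disjoint constant groups
    are floored at a tiny positive p so downstream logs stay finite.
    """
    c = np.asarray(betas_cond, dtype=float)[None, :]
    r = np.asarray(betas_ref, dtype=float)[None, :]
    if np.sum(~np.isnan(c)) < 2 or np.sum(~np.isnan(r)) < 2:
        raise ValueError("need at least 2 non-missing values per side")
    return float(_welch_p(c, r)[0])


def _welch_p(cond: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values with NaN-aware degenerate handling."""
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical groups trip scipy's catastrophic-cancellation
        # warning; those cases are resolved explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(cond, ref, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)

    n_c = np.sum(~np.isnan(cond), axis=1)
    n_r = np.sum(~np.isnan(ref), axis=1)
    enough = (n_c >= 2) & (n_r >= 2)
    with np.errstate(invalid="ignore"):
        sd_c = np.nanstd(cond, axis=1)
        sd_r = np.nanstd(ref, axis=1)
        mu_c = np.nanmean(cond, axis=1)
        mu_r = np.nanmean(ref, axis=1)
    const = (sd_c == 0) & (sd_r == 0) & enough
    p = np.where(const & (mu_c == mu_r), 1.0, p)
    p = np.where(const & (mu_c != mu_r), _P_FLOOR, p)
    p = np.where(enough, p, np.nan)
    return np.clip(p, _P_FLOOR, 1.0)


def diff_score(p: float, delta: float) -> float:
    """Signed DiffScore: magnitude |10 * log10(p)|, sign of delta_beta.

    ``delta == 0`` yields 0 by convention (the sign is undefined there).
    """
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    return float(np.sign(delta)) * abs(10.0 * np.log10(p))


def call_sites(
    betas: BetaMatrix | pd.DataFrame,
    comparison: Comparison,
    delta_min: float = DELTA_MIN,
    score_min: float = SCORE_MIN,
) -> pd.DataFrame:
    """Call differential methylation for every retained probe.

    Returns one row per probe with columns probe_id, median_beta_cond,
    median_beta_ref, delta_beta, p_value, diff_score, direction,
    significant — sorted by |diff_score| descending, ties broken by
    probe_id.  The significance rule is |delta_beta| >= delta_min AND
    |diff_score| > score_min.
    """
    values = betas.values_masked() if isinstance(betas, BetaMatrix) else betas
    missing = [s for s in comparison.cond_samples + comparison.ref_samples if s not in values.columns]
    if missing:
        raise ValueError(f"comparison samples absent from beta matrix: {missing}")

    cond = values.loc[:, list(comparison.cond_samples)].to_numpy(dtype=float)
    ref = values.loc[:, list(comparison.ref_samples)].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        med_c = np.nanmedian(cond, axis=1)
        med_r = np.nanmedian(ref, axis=1)
    delta = med_c - med_r
    p = _welch_p(cond, ref)

    with np.errstate(invalid="ignore"):
        score = np.sign(delta) * np.abs(10.0 * np.log10(p))
    ok = ~np.isnan(p)
    significant = ok & (np.abs(delta) >= delta_min) & (np.abs(score) > score_min)

    out = pd.DataFrame({
        "probe_id": values.index,
        "median_beta_cond": med_c,
        "median_beta_ref": med_r,
        "delta_beta": delta,
        "p_value": p,
        "diff_score": score,
        "direction": np.where(delta > 0, "hyper", "hypo"),
        "significant": significant,
        "comparison": comparison.name,
    })
    out["_abs"] = out["diff_score"].abs()
    out = (
        out.sort_values(["_abs", "probe_id"], ascending=[False, True], na_position="last")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return out


def site_trend_regression(betas: BetaMatrix | pd.DataFrame, design: dict[str, str]) -> pd.DataFrame:
    """Robust linear trend of beta on the ordinal disease stage.

    Stages are coded Normal=0, TypeI=1, TypeII=2 and each probe's betas
    are regressed on the code with iteratively reweighted least squares
    (Huber weights, tuning constant 1.345).  Returns probe_id, slope,
    p_value and -log10(p) for genome-plot tables.
    """
    import statsmodels.api as sm

    values = betas.values_masked() if isinstance(betas, BetaMatrix) else betas
    coding = {"Normal": 0.0, "TypeI": 1.0, "TypeII": 2.0}
    samples = [s for s in values.columns if s in design]
    x_all = np.array([coding[design[s]] for s in samples])
    if len(np.unique(x_all)) < 3:
        raise ValueError("trend regression needs all three stage levels")

    sub = values.loc[:, samples].to_numpy(dtype=float)
    rows = []
    huber = sm.robust.norms.HuberT(t=1.345)
    for pid, y in zip(values.index, sub):
        keep = ~np.isnan(y)
        yv, xv = y[keep], x_all[keep]
        if len(yv) < 3 or len(np.unique(xv)) < 2:
            rows.append((pid, np.nan, np.nan))
            continue
        if np.ptp(yv) < 1e-12:
            rows.append((pid, 0.0, 1.0))
            continue
        X = sm.add_constant(xv)
        try:
            res = sm.RLM(yv, X, M=huber).fit()
            slope, pv = float(res.params[1]), float(res.pvalues[1])
        except Exception:
            slope, pv = np.nan, np.nan
        if np.isnan(pv):
            # zero robust scale (perfect fit): fall back on OLS inference
            ols = sm.OLS(yv, X).fit()
            slope, pv = float(ols.params[1]), float(ols.pvalues[1])
        if np.isnan(pv):
            pv = 1.0 if abs(slope) < 1e-12 else _P_FLOOR
        rows.append((pid, slope, min(max(pv, _P_FLOOR), 1.0)))

    out = pd.DataFrame(rows, columns=["probe_id", "slope", "p_value"])
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out


def volcano_table(site_results: pd.DataFrame) -> pd.DataFrame:
    """Export table for a volcano view: X = delta_beta, Y = |DiffScore|."""
    cols = ["probe_id", "delta_beta", "abs_diff_score", "significant"]
    if site_results.empty:
        return pd.DataFrame(columns=cols)
    out = site_results.loc[:, ["probe_id", "delta_beta", "diff_score", "significant"]].copy()
    out["abs_diff_score"] = out.pop("diff_score").abs()
    return out.loc[:, cols]
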