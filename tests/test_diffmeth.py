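"""Delta-beta, DiffScore, site calling, and the robust trend regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lamethyl import diffmeth
from lamethyl.containers import Comparison


def _comparison(n_cond=3, n_ref=3, name="TypeI_vs_Normal"):
    return Comparison(
        name, "TypeI", "Normal",
        tuple(f"c{i}" for i in range(n_cond)),
        tuple(f"r{i}" for i in range(n_ref)),
    )


def _beta_frame(cond_rows, ref_rows):
    cond = np.atleast_2d(cond_rows)
    ref = np.atleast_2d(ref_rows)
    data = np.hstack([cond, ref])
    cols = [f"c{i}" for i in range(cond.shape[1])] + [f"r{i}" for i in range(ref.shape[1])]
    idx = pd.Index([f"cg{i:04d}" for i in range(data.shape[0])], name="probe_id")
    return pd.DataFrame(data, index=idx, columns=cols)


class TestDeltaBeta:
    def test_identical_groups_give_zero(self):
        assert diffmeth.delta_beta([0.4, 0.5, 0.6], [0.4, 0.5, 0.6]) == 0.0

    def test_hand_median_arithmetic(self):
        assert diffmeth.delta_beta([0.8, 0.8, 0.8], [0.6, 0.6, 0.6]) == pytest.approx(0.20)

    def test_all_missing_group_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.delta_beta([np.nan, np.nan], [0.5, 0.5])


class TestSitePValue:
    def test_identical_constant_groups_give_one(self):
        assert diffmeth.site_p_value([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]) == 1.0

    def test_separated_groups_are_significant(self):
        p = diffmeth.site_p_value([0.9, 0.91, 0.89], [0.1, 0.11, 0.09])
        assert p < 1e-4

    def test_symmetry_under_group_swap(self):
        a, b = [0.2, 0.3, 0.25], [0.6, 0.7, 0.65]
        assert diffmeth.site_p_value(a, b) == pytest.approx(diffmeth.site_p_value(b, a))

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError):
            diffmeth.site_p_value([0.5], [0.4, 0.5])


class TestDiffScore:
    def test_p005_rounds_to_13(self):
        score = diffmeth.diff_score(0.05, +0.2)
        assert score == pytest.approx(13.0103, abs=1e-3)
        assert round(score) == 13

    def test_p_one_gives_zero(self):
        assert diffmeth.diff_score(1.0, 0.5) == 0.0

    def test_hypo_direction_is_negative(self):
        assert diffmeth.diff_score(0.01, -0.3) == pytest.approx(-20.0)

    def test_zero_delta_gives_zero_score(self):
        assert diffmeth.diff_score(0.001, 0.0) == 0.0

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError):
            diffmeth.diff_score(p, 0.1)


class TestCallSites:
    def test_conjunctive_threshold_rule(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.004, size=(3, 6))
        rows = np.array([
            [0.70] * 3 + [0.50] * 3,  # delta 0.20, well separated -> significant
            [0.60] * 3 + [0.50] * 3,  # delta 0.10 -> fails the delta criterion
            [0.70] * 3 + [0.50] * 3,  # delta 0.20, see below: noisy -> weak p
        ])
        rows = rows + noise
        rows[2, :3] = [0.45, 0.70, 0.95]  # huge spread kills the t-test
        betas = _beta_frame(rows[:, :3], rows[:, 3:])
        out = diffmeth.call_sites(betas, _comparison()).set_index("probe_id")
        assert bool(out.loc["cg0000", "significant"]) is True
        assert out.loc["cg0000", "direction"] == "hyper"
        assert bool(out.loc["cg0001", "significant"]) is False  # |delta| < 0.17
        assert bool(out.loc["cg0002", "significant"]) is False  # |score| <= 13

    def test_delta_threshold_is_inclusive(self):
        # constant groups exactly 0.17 apart: the delta criterion passes at equality
        betas = _beta_frame([[0.67, 0.67, 0.67]], [[0.50, 0.50, 0.50]])
        out = diffmeth.call_sites(betas, _comparison())
        assert out["delta_beta"].iloc[0] == pytest.approx(0.17)
        assert bool(out["significant"].iloc[0]) is True

    def test_sorted_by_abs_score_then_probe_id(self):
        rng = np.random.default_rng(1)
        betas = _beta_frame(
            rng.uniform(0.4, 0.9, size=(20, 3)), rng.uniform(0.1, 0.6, size=(20, 3))
        )
        out = diffmeth.call_sites(betas, _comparison())
        absdesc = out["diff_score"].abs().to_numpy()
        assert (np.diff(absdesc) <= 1e-12).all()

    def test_sign_coherence(self):
        rng = np.random.default_rng(2)
        betas = _beta_frame(
            rng.uniform(0, 0.99, size=(200, 3)), rng.uniform(0, 0.99, size=(200, 3))
        )
        out = diffmeth.call_sites(betas, _comparison())
        sig = out[out["significant"]]
        hyper = sig[sig["direction"] == "hyper"]
        hypo = sig[sig["direction"] == "hypo"]
        assert (hyper["delta_beta"] > 0).all() and (hyper["diff_score"] > 0).all()
        assert (hypo["delta_beta"] < 0).all() and (hypo["diff_score"] < 0).all()

    @given(
        delta_min=st.floats(0.17, 0.6),
        score_min=st.floats(13.0, 60.0),
    )
    def test_threshold_monotonicity(self, delta_min, score_min):
        rng = np.random.default_rng(3)
        betas = _beta_frame(
            rng.uniform(0, 0.99, size=(60, 3)), rng.uniform(0, 0.99, size=(60, 3))
        )
        base = diffmeth.call_sites(betas, _comparison())["significant"].sum()
        tightened = diffmeth.call_sites(
            betas, _comparison(), delta_min=delta_min, score_min=score_min
        )["significant"].sum()
        assert tightened <= base

    def test_missing_samples_rejected(self):
        betas = _beta_frame([[0.5, 0.5, 0.5]], [[0.5, 0.5, 0.5]])
        bad = Comparison("x", "TypeI", "Normal", ("c0", "nope", "c2"), ("r0", "r1", "r2"))
        with pytest.raises(ValueError, match="absent"):
            diffmeth.call_sites(betas, bad)


class TestTrendRegression:
    DESIGN = {
        "n0": "Normal", "n1": "Normal", "n2": "Normal",
        "t0": "TypeI", "t1": "TypeI", "t2": "TypeI",
        "u0": "TypeII", "u1": "TypeII", "u2": "TypeII",
    }

    def _frame(self, rows):
        return pd.DataFrame(
            np.atleast_2d(rows), columns=list(self.DESIGN),
            index=pd.Index([f"cg{i}" for i in range(np.atleast_2d(rows).shape[0])]),
        )

    def test_constant_beta_gives_p_one(self):
        out = diffmeth.site_trend_regression(self._frame([[0.5] * 9]), self.DESIGN)
        assert out["p_value"].iloc[0] == 1.0

    def test_monotone_trend_is_significant(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0.1, 0.5, 0.9], 3) + rng.normal(0, 0.01, 9)
        out = diffmeth.site_trend_regression(self._frame([y]), self.DESIGN)
        assert out["p_value"].iloc[0] < 1e-3
        assert out["neg_log10_p"].iloc[0] > 3

    def test_matches_ols_without_outliers(self):
        import statsmodels.api as sm

        # alternating +-e residuals keep every Huber weight at 1
        x = np.repeat([0.0, 1.0, 2.0], 3)
        y = 0.2 + 0.1 * x + 1e-3 * np.tile([1.0, -1.0, 0.0], 3)
        out = diffmeth.site_trend_regression(self._frame([y]), self.DESIGN)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert out["slope"].iloc[0] == pytest.approx(ols.params[1], abs=1e-6)

    def test_requires_three_stages(self):
        design = {k: v for k, v in self.DESIGN.items() if v != "TypeII"}
        frame = self._frame([[0.5] * 9]).loc[:, list(design)]
        with pytest.raises(ValueError, match="three stage"):
            diffmeth.site_trend_regression(frame, design)


class TestVolcanoTable:
    def test_empty_input_keeps_header(self):
        out = diffmeth.volcano_table(pd.DataFrame())
        assert list(out.columns) == ["probe_id", "delta_beta", "abs_diff_score", "significant"]
        assert out.empty

    def test_rows_conserved_and_flagged(self):
        rng = np.random.default_rng(4)
        betas = _beta_frame(
            rng.uniform(0.5, 0.99, size=(10, 3)), rng.uniform(0.0, 0.4, size=(10, 3))
        )
        sites = diffmeth.call_sites(betas, _comparison())
        out = diffmeth.volcano_table(sites)
        assert len(out) == len(sites)
        assert (out["abs_diff_score"] >= 0).all()
        assert out["significant"].sum() == sites["significant"].sum()
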