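"""Normalized-predictor OLS, purposeful selection, and model diagnostics."""

import numpy as np
import pandas as pd
import pytest

from speechrestore import RestorationModel, purposeful_selection


def planted_confounder_data(n=50):
    """Exposure/confounder/outcome with exactly known coefficients.

    Basis vectors are orthogonalized against each other and the constant,
    then scaled to unit sample SD, so OLS recovers the planted betas with
    no sampling error: x carries 0.4, the confounder c carries 0.35, and
    removing c shifts the x coefficient to 0.4 + 0.35*0.8 = 0.68 (+70%).
    """
    rng = np.random.default_rng(7)
    A = np.c_[np.ones(n), rng.standard_normal((n, 3))]
    Q = np.linalg.qr(A)[0][:, 1:] * np.sqrt(n - 1)  # unit sample SD, mean 0
    c, u, v = Q.T
    x = 0.8 * c + 0.6 * u  # corr(x, c) = 0.8, unit variance
    y = 0.4 * x + 0.35 * c + 1.2 * v
    return pd.DataFrame({"x": x, "c": c, "y": y})


def make_data(rng, n=200, betas=(3.0, -1.5), noise=2.0, extra=0):
    k = len(betas)
    X = rng.standard_normal((n, k + extra))
    y = 50.0 + X[:, :k] @ np.array(betas) + rng.normal(0, noise, n)
    cols = [f"x{i}" for i in range(k + extra)]
    df = pd.DataFrame(X, columns=cols)
    df["y"] = y
    return df, cols


class TestRestorationModel:
    def test_intercept_is_outcome_mean_with_centered_predictor(self, rng):
        df, cols = make_data(rng)
        fit = RestorationModel.from_dataframe(df, "y", cols).fit()
        assert fit.params["const"] == pytest.approx(df["y"].mean())

    def test_single_zscored_predictor_beta_is_r_times_sd(self, rng):
        df, _ = make_data(rng, betas=(2.0,))
        fit = RestorationModel.from_dataframe(df, "y", ["x0"]).fit()
        r = np.corrcoef(df["x0"], df["y"])[0, 1]
        assert fit.params["x0"] == pytest.approx(r * df["y"].std(ddof=1))

    def test_beta_invariant_to_affine_rescaling_of_raw_predictor(self, rng):
        df, cols = make_data(rng)
        fit1 = RestorationModel.from_dataframe(df, "y", cols).fit()
        df2 = df.copy()
        df2["x0"] = 1000.0 + 37.5 * df2["x0"]
        fit2 = RestorationModel.from_dataframe(df2, "y", cols).fit()
        assert fit2.params["x0"] == pytest.approx(fit1.params["x0"])
        assert fit2.rsquared == pytest.approx(fit1.rsquared)

    def test_duplicated_predictor_is_rank_deficiency_error(self, rng):
        df, _ = make_data(rng)
        df["x0_copy"] = df["x0"]
        with pytest.raises(ValueError):
            RestorationModel.from_dataframe(df, "y", ["x0", "x0_copy"])

    def test_ci_contains_beta_and_adj_r2_below_r2(self, rng):
        df, cols = make_data(rng)
        fit = RestorationModel.from_dataframe(df, "y", cols).fit()
        ci = fit.conf_int()
        for name in fit.params.index:
            assert ci.loc[name, "lower"] <= fit.params[name] <= ci.loc[name, "upper"]
        assert fit.rsquared_adj <= fit.rsquared
        assert "R^2" in fit.summary()

    def test_table_report_shape(self, rng):
        df, cols = make_data(rng)
        frame = RestorationModel.from_dataframe(df, "y", cols).fit().to_frame()
        assert list(frame.columns) == ["beta", "ci_lower", "ci_upper", "t", "p"]
        assert set(frame.index) == {"const", "x0", "x1"}


class TestDiagnostics:
    def test_orthogonal_predictors_unit_vif(self, rng):
        n = 64
        # orthogonalize against the constant too, so columns stay exactly
        # orthogonal after mean-centering/z-scoring
        A = np.c_[np.ones(n), rng.standard_normal((n, 3))]
        X = np.linalg.qr(A)[0][:, 1:]
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = X @ [1.0, 2.0, 3.0] + rng.normal(0, 0.5, n)
        diag = RestorationModel.from_dataframe(df, "y", ["a", "b", "c"]).fit().diagnostics()
        assert np.allclose(diag.vif, 1.0, atol=1e-8)

    def test_collinear_predictors_inflate_vif(self, rng):
        df, cols = make_data(rng)
        df["x2"] = df["x0"] + rng.normal(0, 0.05, len(df))
        diag = RestorationModel.from_dataframe(df, "y", cols + ["x2"]).fit().diagnostics()
        assert diag.vif[["x0", "x2"]].min() > 10.0

    def test_bp_and_shapiro_type_i_rates(self, rng):
        """Homoscedastic Gaussian models reject at about the nominal 5%."""
        bp_hits = sw_hits = 0
        reps = 400
        for _ in range(reps):
            df, cols = make_data(rng, n=60, noise=1.0)
            diag = RestorationModel.from_dataframe(df, "y", cols).fit().diagnostics()
            bp_hits += diag.bp_p < 0.05
            sw_hits += diag.shapiro_p < 0.05
        assert bp_hits / reps == pytest.approx(0.05, abs=0.035)
        assert sw_hits / reps == pytest.approx(0.05, abs=0.035)


class TestPurposefulSelection:
    def test_null_predictor_removed(self):
        """A true-zero predictor is dropped at the theoretical rate.

        Under the null its p-value is uniform, so the p > p_stay rule fires
        with probability 1 - p_stay: ~75% at the default 0.25 and ~95% at a
        stricter 0.05 stay threshold.
        """
        removed_default = removed_strict = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            df, cols = make_data(r, n=500, betas=(3.0, -1.5), extra=1)  # x2 is noise
            sel = purposeful_selection(df, "y", cols, hypothesis_set=["x0", "x1"])
            removed_default += "x2" not in sel.predictors
            sel2 = purposeful_selection(df, "y", cols, hypothesis_set=["x0", "x1"],
                                        p_stay=0.05)
            removed_strict += "x2" not in sel2.predictors
        assert removed_default / n_seeds > 0.55
        assert removed_strict / n_seeds > 0.85

    def test_hypothesis_members_never_removed(self, rng):
        df, cols = make_data(rng, n=300, betas=(0.0, 0.0), extra=0)  # both null
        sel = purposeful_selection(df, "y", cols, hypothesis_set=cols)
        assert set(sel.predictors) == set(cols)

    def test_planted_confounder_reinstated(self):
        """A confounder whose removal shifts a retained beta > 20% is locked in.

        The fixture is built on an exactly orthonormal basis so the fitted
        coefficients equal the planted ones: the confounder's own partial
        effect is weak (a removal candidate), but dropping it inflates the
        exposure's coefficient by 70%, which must trigger reinstatement.
        """
        df = planted_confounder_data()
        sel = purposeful_selection(df, "y", ["x", "c"], hypothesis_set=["x"],
                                   p_stay=0.01)
        assert "c" in sel.predictors
        steps = [a["step"] for a in sel.audit]
        assert "reinstate" in steps

    def test_literal_direction_flag_inverts_rule(self, rng):
        df, cols = make_data(rng, n=500, betas=(3.0, -1.5), extra=1)
        sel = purposeful_selection(df, "y", cols, hypothesis_set=["x0", "x1"],
                                   literal_direction=True)
        # under the literal reading, the strongly significant x2?  x2 is null:
        # its p is large, so it is NOT removed under the inverted rule
        assert "x2" in sel.predictors

    def test_audit_trail_records_every_step(self, rng):
        df, cols = make_data(rng, n=300, extra=2)
        sel = purposeful_selection(df, "y", cols, hypothesis_set=["x0", "x1"])
        frame = sel.audit_frame()
        assert {"step", "predictor", "p"} <= set(frame.columns)

    def test_empty_saturated_set_rejected(self, rng):
        df, _ = make_data(rng)
        with pytest.raises(ValueError):
            purposeful_selection(df, "y", [], hypothesis_set=[])

    def test_interactions_screened_one_by_one(self, rng):
        n = 500
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        y = 2.0 * a + 1.0 * b + 3.0 * a * b + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"a": a, "b": b, "y": y})
        sel = purposeful_selection(df, "y", ["a", "b"], hypothesis_set=["a", "b"])
        assert "a:b" in sel.interactions
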