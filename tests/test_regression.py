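import numpy as np
import pandas as pd
import pytest

from chromcascade import regression as regr


class TestRnaFoldChange:
    def _tables(self):
        intronic = pd.DataFrame({"r1": [10, 0, 0], "r2": [10, 0, 0],
                                 "s1": [40, 0, 0], "s2": [40, 0, 0]},
                                index=["g_intron", "g_orf", "g_zero"])
        orf = pd.DataFrame({"r1": [80, 100, 0], "r2": [80, 100, 0],
                            "s1": [300, 300, 0], "s2": [300, 300, 0]},
                           index=["g_intron", "g_orf", "g_zero"])
        return intronic, orf

    def test_intronic_ratio_with_pseudocount(self):
        intronic, orf = self._tables()
        out = regr.rna_fold_change(intronic, orf, ["r1", "r2"], ["s1", "s2"])
        assert out.loc["g_intron", "fold_change"] == pytest.approx(40.5 / 10.5)
        assert out.loc["g_intron", "source"] == "intronic"

    def test_orf_fallback_for_intronless(self):
        intronic, orf = self._tables()
        out = regr.rna_fold_change(intronic, orf, ["r1", "r2"], ["s1", "s2"])
        assert out.loc["g_orf", "fold_change"] == pytest.approx(300.5 / 100.5)
        assert out.loc["g_orf", "source"] == "orf"

    def test_all_zero_gene_gives_unit_fold(self):
        intronic, orf = self._tables()
        out = regr.rna_fold_change(intronic, orf, ["r1", "r2"], ["s1", "s2"])
        assert out.loc["g_zero", "fold_change"] == pytest.approx(1.0)


class TestSkewness:
    def test_symmetric_sample_zero(self):
        x = np.concatenate([np.linspace(-2, 2, 101)])
        assert regr.skewness(x) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_population_value(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(1.0, 100_000)
        assert regr.skewness(x) == pytest.approx(2.0, abs=0.05)

    def test_log_transform_removes_lognormal_skew(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 0.5, 100_000)
        assert regr.skewness(x) > 1.0
        assert abs(regr.skewness(np.log(x))) < 0.05

    def test_type_conventions(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(1.0, 50)
        n = len(x)
        g1 = regr.skewness(x, kind=1)
        assert regr.skewness(x, kind=3) == pytest.approx(g1 * ((n - 1) / n) ** 1.5)
        assert regr.skewness(x, kind=2) == pytest.approx(
            g1 * np.sqrt(n * (n - 1)) / (n - 2))

    def test_zero_variance_flagged(self):
        assert np.isnan(regr.skewness(np.ones(10)))


class TestLogLogFit:
    def test_exact_power_law(self):
        x = pd.DataFrame({"x": np.linspace(1, 10, 50)})
        y = pd.Series(x["x"] ** 2)
        model = regr.loglog_fit(y, x)
        assert model.coefficients["x"] == pytest.approx(2.0)
        assert model.r_squared == pytest.approx(1.0)

    def test_null_predictor_slope_within_2se(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"x": rng.lognormal(0, 0.5, 500)})
        y = pd.Series(rng.lognormal(0, 0.5, 500))
        model = regr.loglog_fit(y, x)
        assert abs(model.coefficients["x"]) <= 2 * model.bse["x"]

    def test_scale_invariance_of_slope(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame({"x": rng.lognormal(0, 0.4, 200)})
        y = pd.Series((x["x"] ** 1.5) * rng.lognormal(0, 0.1, 200))
        m1 = regr.loglog_fit(y, x)
        m2 = regr.loglog_fit(y, x * 37.0)
        assert m1.coefficients["x"] == pytest.approx(m2.coefficients["x"])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            regr.loglog_fit(pd.Series([1.0, -2.0]), pd.DataFrame({"x": [1.0, 2.0]}))


class TestStepwiseAIC:
    def _data(self, seed=7, n=300):
        rng = np.random.default_rng(seed)
        x_true = rng.normal(0, 1, n)
        x_noise = rng.normal(0, 1, n)
        y = 1.5 * x_true + rng.normal(0, 0.5, n)
        X = pd.DataFrame({"true": x_true, "noise": x_noise})
        return pd.Series(y), X

    def test_true_predictor_kept_noise_excluded(self):
        hits = 0
        for seed in range(20):
            y, X = self._data(seed)
            model = regr.stepwise_aic(y, X, already_log=True)
            if model.terms == ["true"]:
                hits += 1
        assert hits >= 19

    def test_all_noise_gives_intercept_only_at_theoretical_rate(self):
        """With a pure-noise candidate, AIC admits it with probability
        P(chi2_1 > 2) ~ 0.157; the intercept-only model must therefore be
        returned at about the 84% theoretical rate."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            y = pd.Series(rng.normal(0, 1, 300))
            X = pd.DataFrame({"a": rng.normal(0, 1, 300)})
            model = regr.stepwise_aic(y, X, already_log=True)
            if model.terms == []:
                hits += 1
        assert hits >= 28  # 84% of 40 minus ~2.5 binomial sigma

    def test_duplicated_column_never_selected(self):
        y, X = self._data()
        X["dup"] = X["true"]
        model = regr.stepwise_aic(y, X, already_log=True)
        assert not ("true" in model.terms and "dup" in model.terms)

    def test_aic_never_worse_than_start(self):
        y, X = self._data()
        full = regr.loglog_fit(y, X, already_log=True)
        step = regr.stepwise_aic(y, X, already_log=True)
        assert step.aic <= full.aic + 1e-9


class TestDiagnostics:
    def test_balanced_design_equal_leverages(self):
        """A design with duplicated balanced rows has equal hat diagonals
        summing to the parameter count."""
        X = pd.DataFrame({"x": np.tile([1.0, 2.0, 3.0, 4.0], 5)})
        rng = np.random.default_rng(8)
        y = pd.Series(2 * X["x"] + rng.normal(0, 0.1, len(X)))
        model = regr.loglog_fit(y, X, already_log=True)
        diag = regr.model_diagnostics(model)
        h = diag["leverage"].to_numpy()
        assert h.sum() == pytest.approx(2.0)
        assert np.allclose(sorted(set(np.round(h, 12))),
                           sorted(set(np.round(h[:4], 12))))

    def test_gross_outlier_has_max_cooks_distance(self):
        rng = np.random.default_rng(9)
        x = np.linspace(1, 10, 30)
        y = 2 * x + rng.normal(0, 0.2, 30)
        y[7] += 25.0
        model = regr.loglog_fit(pd.Series(y), pd.DataFrame({"x": x}),
                                already_log=True)
        diag = regr.model_diagnostics(model)
        assert diag["cooks_distance"].idxmax() == 7

    def test_cooks_distance_matches_loo_oracle(self):
        """Cook's distance equals the leave-one-out coefficient-shift form
        (beta - beta_(i))' X'X (beta - beta_(i)) / (p s^2) to 1e-10."""
        rng = np.random.default_rng(10)
        n = 20
        X = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(0, 1, n)})
        y = pd.Series(1.0 + 0.5 * X["a"] - 0.8 * X["b"] + rng.normal(0, 0.3, n))
        model = regr.loglog_fit(y, X, already_log=True)
        diag = regr.model_diagnostics(model)

        import statsmodels.api as sm
        Xd = sm.add_constant(X).to_numpy()
        yv = y.to_numpy()
        beta = np.linalg.lstsq(Xd, yv, rcond=None)[0]
        p = Xd.shape[1]
        resid = yv - Xd @ beta
        s2 = resid @ resid / (n - p)
        xtx = Xd.T @ Xd
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.lstsq(Xd[keep], yv[keep], rcond=None)[0]
            delta = beta - beta_i
            d_oracle = delta @ xtx @ delta / (p * s2)
            assert diag["cooks_distance"].iloc[i] == pytest.approx(d_oracle, abs=1e-10)

    def test_underdetermined_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        y = pd.Series([1.0, 2.0])
        model = regr.loglog_fit(y, X, already_log=True)
        with pytest.raises(ValueError):
            regr.model_diagnostics(model)
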