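import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromcascade import dependence as dep


def _series(values, prefix="r"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


def _points(x, y):
    idx = [f"r{i}" for i in range(len(x))]
    return dep.DependencePoints(pd.Series(x, index=idx), pd.Series(y, index=idx))


class TestMakePoints:
    def test_equal_backgrounds_give_zero_y(self):
        fc = _series([1.5, 2.0, 0.8])
        pts = dep.make_dependence_points(fc, fc.copy())
        assert (pts.y == 0).all()

    def test_abolished_induction_gives_y_equal_x(self):
        fc1 = _series([2.0, 4.0, 1.5])
        fc2 = _series([1.0, 1.0, 1.0])
        pts = dep.make_dependence_points(fc1, fc2)
        pd.testing.assert_series_equal(pts.y, pts.x)

    def test_swapping_backgrounds_negates_y(self):
        rng = np.random.default_rng(0)
        fc1 = _series(rng.uniform(0.5, 3, 50))
        fc2 = _series(rng.uniform(0.5, 3, 50))
        p12 = dep.make_dependence_points(fc1, fc2)
        p21 = dep.make_dependence_points(fc2, fc1)
        np.testing.assert_allclose(p12.y, -p21.y)

    def test_mismatched_regions_rejected(self):
        with pytest.raises(ValueError):
            dep.make_dependence_points(_series([1.0, 2.0]), _series([1.0, 2.0], "q"))

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            dep.make_dependence_points(_series([1.0, 0.0]), _series([1.0, 1.0]))

    def test_independent_noise_symmetric(self):
        rng = np.random.default_rng(1)
        fc1 = _series(np.exp(rng.normal(0.3, 0.2, 2000)))
        fc2 = _series(np.exp(rng.normal(0.3, 0.2, 2000)))
        pts = dep.make_dependence_points(fc1, fc2)
        k = int((pts.y > 0).sum())
        assert stats.binomtest(k, 2000, 0.5).pvalue > 0.01


class TestAsymmetryRegression:
    def test_exact_half_slope(self):
        x = np.linspace(0.1, 2, 50)
        pts = _points(x, 0.5 * x)
        reg = dep.fit_asymmetry_regression(pts)
        assert reg["above"]["slope"] == pytest.approx(0.5)
        assert reg["above"]["se"] == pytest.approx(0.0, abs=1e-12)

    def test_fully_dependent_slope_one(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(2, 0.4, 2000) + 0.1
        y = x + rng.normal(0, 0.05, 2000)
        reg = dep.fit_asymmetry_regression(_points(x, y))
        assert reg["above"]["slope"] == pytest.approx(1.0, abs=0.05)

    def test_null_slopes_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2, 0.4, 2000)
        y = rng.normal(0, 0.2, 2000)
        reg = dep.fit_asymmetry_regression(_points(x, y))
        for side in ("above", "below"):
            assert abs(reg[side]["slope"]) <= 2 * reg[side]["se"] + 0.05

    def test_one_sided_empty_flagged(self):
        x = np.linspace(0.1, 1, 20)
        reg = dep.fit_asymmetry_regression(_points(x, x))  # all above
        assert np.isnan(reg["below"]["slope"])


class TestDependentSetEstimation:
    def test_all_dependent_zero_noise_counts_everything(self):
        x = np.linspace(0.2, 2, 100)
        est = dep.estimate_dependent_set(_points(x, x))
        assert est.n_dependent == 100
        assert est.flags.all()

    def test_symmetric_null_flags_few(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2, 0.4, 2000)
        y = rng.normal(0, 0.2, 2000)
        est = dep.estimate_dependent_set(_points(x, y))
        assert est.n_dependent <= 0.02 * 2000 + 3 * np.sqrt(2000)

    def test_planted_fraction_recovered(self):
        """80% of n=2000 regions planted dependent (induction abolished in
        the second background): recovered fraction within ±0.05."""
        rng = np.random.default_rng(5)
        n, frac = 2000, 0.80
        g = rng.gamma(2, 0.35, n) + 0.15
        dep_mask = rng.random(n) < frac
        noise = 0.14
        x = g + rng.normal(0, noise, n)
        y = np.where(dep_mask, g, 0.0) + rng.normal(0, noise, n)
        est = dep.estimate_dependent_set(_points(x, y))
        assert est.n_dependent / n == pytest.approx(frac, abs=0.05)

    def test_consistency_with_n(self):
        """Recovery error shrinks as the region universe grows."""
        errs = []
        for n in (500, 2000, 8000):
            rng = np.random.default_rng(6)
            g = rng.gamma(2, 0.35, n) + 0.15
            dep_mask = rng.random(n) < 0.8
            x = g + rng.normal(0, 0.14, n)
            y = np.where(dep_mask, g, 0.0) + rng.normal(0, 0.14, n)
            est = dep.estimate_dependent_set(_points(x, y))
            errs.append(abs(est.n_dependent / n - 0.8))
        assert errs[2] <= errs[0] + 0.02

    def test_null_flagged_fraction_across_seeds(self):
        """Under the symmetric null the flagged fraction stays <= 5%."""
        fractions = []
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            x = rng.gamma(2, 0.4, 2000)
            y = rng.normal(0, 0.2, 2000)
            est = dep.estimate_dependent_set(_points(x, y))
            fractions.append(est.n_dependent / 2000)
        assert np.mean(fractions) <= 0.05
        assert max(fractions) <= 0.05


class TestRestorationClassification:
    def _flags(self, tko, elk1, nona, dfw, index):
        return {
            "TKO": pd.Series(tko, index=index),
            "TKO+Elk1": pd.Series(elk1, index=index),
            "TKO+Elk1nonA": pd.Series(nona, index=index),
            "TKO+Elk1dFW": pd.Series(dfw, index=index),
        }

    def test_definitions(self):
        idx = ["full_restore", "needs_phospho", "never_restored", "independent"]
        flags = self._flags(
            tko=[True, True, True, False],
            elk1=[False, False, True, False],
            nona=[False, True, True, False],
            dfw=[False, True, True, False],
            index=idx,
        )
        cls = dep.classify_restoration(flags)
        assert cls["full_restore"] == "restored-any-Elk1"
        assert cls["needs_phospho"] == "restored-requires-phospho+FW"
        assert cls["never_restored"] == "dependent-not-restored"
        assert cls["independent"] == "not-dependent"

    def test_missing_background_rejected(self):
        flags = self._flags([True], [False], [False], [False], ["r"])
        del flags["TKO+Elk1"]
        with pytest.raises(ValueError):
            dep.classify_restoration(flags)

    def test_planted_class_fractions_recovered(self):
        """Synthetic fold changes with planted class fractions (0.8
        dependent, 0.6 restored, 0.9 requiring phospho+FW): each recovered
        within ±0.05 via the pairwise estimator runs."""
        rng = np.random.default_rng(7)
        n = 2000
        g = rng.gamma(2, 0.35, n) + 0.2
        u = rng.random(n)
        # class assignment: 20% independent; of the 80% dependent, 40%
        # never restored; of the 60% restored, 90% need phospho+FW
        independent = u < 0.2
        restored = (~independent) & (rng.random(n) < 0.6)
        needs = restored & (rng.random(n) < 0.9)
        active = {
            "WT": np.ones(n, bool),
            "TKO": independent,
            "TKO+Elk1": independent | restored,
            "TKO+Elk1nonA": independent | (restored & ~needs),
            "TKO+Elk1dFW": independent | (restored & ~needs),
        }
        noise = 0.14
        idx = [f"r{i}" for i in range(n)]
        fc = {
            bg: pd.DataFrame(
                {"m": np.exp2(np.where(act, g, 0.0) + rng.normal(0, noise, n))},
                index=idx)
            for bg, act in active.items()
        }
        flags = dep.tss_dependence_flags(fc, "WT")
        variants = dep.combined_pair_flags(fc, ("TKO+Elk1nonA", "TKO+Elk1dFW"), "WT")
        cls = dep.classify_restoration(flags, variants_combined=variants)
        dep_mask = cls != "not-dependent"
        res_mask = cls.isin(["restored-any-Elk1", "restored-requires-phospho+FW"])
        assert dep_mask.mean() == pytest.approx(0.8, abs=0.05)
        assert res_mask[dep_mask].mean() == pytest.approx(0.6, abs=0.05)
        assert (cls[res_mask] == "restored-requires-phospho+FW").mean() == \
            pytest.approx(0.9, abs=0.05)
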