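"""Proportional and linear fits, R^2, and proportionality-constant comparison."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcountqc import (
    FitError,
    bootstrap_statistic,
    compare_proportionality_constants,
    compute_r2,
    fit_linear,
    fit_proportional,
)
from cellcountqc.resampling import BootstrapResult
from cellcountqc.synthetic_data import SyntheticConfig, simulate_dilution_series

from conftest import DESIGN_DFS, make_dataset


class TestFitProportional:
    def test_noiseless_proportional_is_exact(self, exact_proportional):
        fit = fit_proportional(exact_proportional)
        assert fit.beta1 == pytest.approx(1_000_000.0, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0)
        np.testing.assert_allclose(fit.fitted, fit.beta1 * exact_proportional.df_values)

    def test_constant_response_matches_weighted_normal_equation(self):
        # oracle: beta1 = sum(w*DF*c) / sum(w*DF^2); with w = 1/DF this is
        # n*c / sum(DF), hand-computable for the 5-point design
        c = 100.0
        ds = make_dataset({df: [[c]] for df in DESIGN_DFS})
        fit = fit_proportional(ds, variance_model="proportional_to_mean")
        expected = len(DESIGN_DFS) * c / sum(DESIGN_DFS)
        assert fit.beta1 == pytest.approx(expected, rel=1e-12)
        # and under constant variance: sum(DF*c)/sum(DF^2)
        fit_c = fit_proportional(ds, variance_model="constant")
        dfs = np.array(DESIGN_DFS)
        assert fit_c.beta1 == pytest.approx(c * dfs.sum() / (dfs**2).sum(), rel=1e-12)

    def test_matches_statsmodels_wls_through_origin(self, noisy_dataset):
        # independent route: WLS without intercept on the same weights
        fit = fit_proportional(noisy_dataset)
        res = sm.WLS(
            noisy_dataset.response,
            noisy_dataset.df_values[:, None],
            weights=1.0 / noisy_dataset.df_values,
        ).fit()
        assert fit.beta1 == pytest.approx(float(res.params[0]), rel=1e-10)

    def test_recovers_stock_within_3_percent(self):
        sim = simulate_dilution_series(SyntheticConfig(seed=11))
        fit = fit_proportional(sim.dataset)
        assert 5e5 <= sim.truth.stock_conc <= 1e6
        assert fit.beta1 == pytest.approx(sim.truth.stock_conc, rel=0.03)

    def test_single_dilution_not_identifiable(self):
        ds = make_dataset({0.5: [[100.0, 110.0]]})
        with pytest.raises(FitError, match="not identifiable"):
            fit_proportional(ds)

    def test_all_zero_responses_warns_beta1_zero(self):
        ds = make_dataset({1.0: [[0.0, 0.0]], 0.5: [[0.0, 0.0]]}, viability=0.0)
        ds.frame["pct_viability"] = 0.0
        with pytest.warns(UserWarning, match="zero"):
            fit = fit_proportional(ds)
        assert fit.beta1 == 0.0

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.01, 1e4), seed=st.integers(0, 10_000))
    def test_scale_equivariance(self, scale, seed):
        ds = simulate_dilution_series(SyntheticConfig(seed=seed, stock_conc=7e5)).dataset
        base = fit_proportional(ds)
        scaled = ds
        scaled.frame = ds.frame.assign(
            viable_conc=ds.frame["viable_conc"] * scale,
            total_conc=ds.frame["total_conc"] * scale,
        )
        fit2 = fit_proportional(scaled)
        assert fit2.beta1 == pytest.approx(base.beta1 * scale, rel=1e-9)
        assert fit2.r2 == pytest.approx(base.r2, rel=1e-9)

    def test_duplicated_observations_equal_integer_weights(self):
        # constant-variance fit on duplicated data == fit on deduplicated data,
        # because duplication is equivalent to integer weights
        ds = make_dataset({1.0: [[100.0, 120.0]], 0.5: [[60.0, 55.0]]})
        dup = make_dataset({1.0: [[100.0, 120.0, 100.0, 120.0]], 0.5: [[60.0, 55.0, 60.0, 55.0]]})
        f1 = fit_proportional(ds, variance_model="constant")
        f2 = fit_proportional(dup, variance_model="constant")
        assert f2.beta1 == pytest.approx(f1.beta1, rel=1e-12)

    def test_parameter_recovery_and_noise_monotonicity(self):
        # mean of beta1 over 200 simulated designs within 1% of truth, and the
        # spread of the estimator shrinks with the observation CV
        stock = 8e5
        sds = {}
        for cv in (0.02, 0.05, 0.10):
            est = [
                fit_proportional(
                    simulate_dilution_series(SyntheticConfig(seed=s, stock_conc=stock, obs_cv=cv)).dataset
                ).beta1
                for s in range(200)
            ]
            est = np.array(est)
            if cv == 0.05:
                assert est.mean() == pytest.approx(stock, rel=0.01)
            sds[cv] = est.std(ddof=1)
        assert sds[0.02] < sds[0.05] < sds[0.10]


class TestFitLinear:
    def test_noiseless_line_recovered_exactly(self):
        ds = make_dataset({df: [[1e5 + 1e6 * df] * 2] for df in DESIGN_DFS})
        fit = fit_linear(ds)
        assert fit.intercept == pytest.approx(1e5, rel=1e-9)
        assert fit.slope == pytest.approx(1e6, rel=1e-9)

    def test_proportional_data_gives_zero_intercept(self, exact_proportional):
        fit = fit_linear(exact_proportional)
        prop = fit_proportional(exact_proportional)
        assert abs(fit.intercept) <= 1e-6 * prop.beta1

    def test_background_bias_recovery(self):
        b = 1.6e5  # 0.2 x stock
        est = [
            fit_linear(
                simulate_dilution_series(
                    SyntheticConfig(seed=s, stock_conc=8e5, bias_mode="background", bias_magnitude=b)
                ).dataset
            ).intercept
            for s in range(100)
        ]
        assert np.mean(est) == pytest.approx(b, rel=0.05)


class TestComputeR2:
    def test_r2_one_iff_zero_residuals(self, exact_proportional):
        fit = fit_proportional(exact_proportional)
        assert compute_r2(fit, exact_proportional) == pytest.approx(1.0, abs=1e-12)

    def test_identical_responses_flagged_undefined(self):
        ds = make_dataset({1.0: [[100.0, 100.0]], 0.5: [[100.0, 100.0]]})
        fit = fit_proportional(ds)
        assert math.isnan(compute_r2(fit, ds))
        assert not fit.r2_defined

    def test_noisy_synthetic_r2_above_0_9(self, noisy_dataset):
        fit = fit_proportional(noisy_dataset)
        assert fit.r2 > 0.9


class TestCompareProportionalityConstants:
    @staticmethod
    def _boot(lo, hi, level=0.95, reps=None, label=""):
        return BootstrapResult(
            point=(lo + hi) / 2, ci_lo=lo, ci_hi=hi, level=level, n_boot=10, seed=0,
            replicates=None if reps is None else np.asarray(reps), label=label,
        )

    def test_disjoint_intervals_significant(self):
        cmp_ = compare_proportionality_constants(self._boot(9.0e5, 9.5e5, label="m1"), self._boot(9.6e5, 10.1e5, label="m3"))
        assert cmp_.significantly_different
        assert "non-overlap" in cmp_.rule

    def test_identical_intervals_not_significant(self):
        cmp_ = compare_proportionality_constants(self._boot(9.0e5, 9.5e5), self._boot(9.0e5, 9.5e5))
        assert not cmp_.significantly_different

    def test_mismatched_levels_error(self):
        with pytest.raises(FitError, match="levels differ"):
            compare_proportionality_constants(self._boot(1, 2), self._boot(1, 2, level=0.9))

    def test_difference_rule_reproducible_from_replicates(self, rng):
        reps_a = rng.normal(10, 1, 400)
        reps_b = rng.normal(15, 1, 400)
        a = self._boot(8, 12, reps=reps_a)
        b = self._boot(13, 17, reps=reps_b)
        cmp_ = compare_proportionality_constants(a, b, rule="difference_ci")
        lo, hi = np.quantile(reps_a - reps_b, [0.025, 0.975])
        assert cmp_.difference_ci == pytest.approx((lo, hi))
        assert cmp_.significantly_different == (not (lo <= 0 <= hi))

    def test_rules_agree_for_clearly_separated_methods(self):
        # two methods on a shared truth, one with a strong density-dependent
        # miscount; both decision rules should call the bias for most seeds
        hits = {"ci_overlap": 0, "difference_ci": 0}
        n_seeds = 25
        for s in range(n_seeds):
            boots = {}
            for name, infl in (("a", 0.0), ("b", 0.15)):
                ds = simulate_dilution_series(
                    SyntheticConfig(seed=s * 2 + (name == "b"), stock_conc=8e5, bead_count_inflation=infl)
                ).dataset
                boots[name] = bootstrap_statistic(
                    ds, lambda d: fit_proportional(d).beta1, n_boot=200, seed=s, name="beta1", label=name
                )
            for rule in hits:
                if compare_proportionality_constants(boots["a"], boots["b"], rule=rule).significantly_different:
                    hits[rule] += 1
        assert hits["ci_overlap"] >= 0.8 * n_seeds
        assert hits["difference_ci"] >= hits["ci_overlap"]  # difference rule is at least as powerful
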