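"""Proportional and linear model fits for dilution-series data.

The proportional (zero-intercept) model says the measured concentration is
``lambda_ij = beta1 * DF_i``: the response at dilution fraction DF is the
stock concentration scaled by DF, so ``beta1`` estimates the stock
concentration.  Fits are weighted least squares; under the standard
assumption that measurement variance is proportional to the mean, the mean
at DF is proportional to DF and the weights are ``w = 1/DF``.

The linear model additionally allows a non-zero y-intercept, which captures
additive background (debris, mis-segmentation) that does not dilute with the
cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .exceptions import FitError
from .study_data import DilutionSeriesDataset

VARIANCE_MODELS = ("proportional_to_mean", "constant")


def _weights(df_values: np.ndarray, variance_model: str) -> np.ndarray:
    if variance_model == "proportional_to_mean":
        if np.any(df_values <= 0):
            raise FitError("weights undefined: dilution fraction must be positive")
        return 1.0 / df_values
    if variance_model == "constant":
        return np.ones_like(df_values)
    raise FitError(f"unknown variance model {variance_model!r}; choose from {VARIANCE_MODELS}")


def _check_fittable(ds: DilutionSeriesDataset) -> None:
    ds.single_group()
    if len(ds.distinct_dfs()) < 2:
        raise FitError("proportionality not identifiable: need >= 2 distinct dilution fractions")


def weighted_r2(y: np.ndarray, fitted: np.ndarray, w: np.ndarray) -> float:
    """Centered weighted R^2 = 1 - SSE/SST, SST about the weighted grand mean.

    Returns NaN when SST is zero (all responses identical): R^2 is undefined
    there and the NaN acts as the flagged sentinel.
    """
    resid = y - fitted
    sse = float(np.sum(w * resid**2))
    ybar = float(np.sum(w * y) / np.sum(w))
    sst = float(np.sum(w * (y - ybar) ** 2))
    if sst == 0.0:
        return math.nan
    return 1.0 - sse / sst


@dataclass
class ProportionalFit:
    """Zero-intercept weighted least-squares fit ``y ~ beta1 * DF``."""

    beta1: float
    weights: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    variance_model: str
    n_obs: int

    @property
    def r2_defined(self) -> bool:
        return not math.isnan(self.r2)

    def predict(self, df_values: np.ndarray | float) -> np.ndarray | float:
        return self.beta1 * np.asarray(df_values, dtype=float)

    def summary_row(self) -> dict:
        return {"beta1": self.beta1, "r2": self.r2, "n_obs": self.n_obs, "variance_model": self.variance_model}


@dataclass
class LinearFit:
    """Weighted least-squares line with intercept, same weighting convention."""

    intercept: float
    slope: float
    weights: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    variance_model: str
    n_obs: int

    def predict(self, df_values: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(df_values, dtype=float)


def fit_proportional(
    ds: DilutionSeriesDataset,
    variance_model: str = "proportional_to_mean",
) -> ProportionalFit:
    """Fit the proportional model by weighted least squares through the origin.

    beta1 minimises ``sum_k w_k (y_k - beta1 * DF_k)^2``, i.e.
    ``beta1 = sum(w*DF*y) / sum(w*DF^2)``.  With ``w = 1/DF`` this reduces to
    ``sum(y) / sum(DF)``, the ratio estimator.  R^2 uses the centered
    (weighted grand mean) definition.
    """
    _check_fittable(ds)
    x = ds.df_values
    y = ds.response
    w = _weights(x, variance_model)
    denom = float(np.sum(w * x * x))
    beta1 = float(np.sum(w * x * y) / denom)
    if np.all(y == 0):
        warnings.warn("all responses are zero; beta1 = 0", stacklevel=2)
        beta1 = 0.0
    fitted = beta1 * x
    resid = y - fitted
    r2 = weighted_r2(y, fitted, w)
    return ProportionalFit(
        beta1=beta1, weights=w, fitted=fitted, residuals=resid, r2=r2,
        variance_model=variance_model, n_obs=len(y),
    )


def fit_linear(
    ds: DilutionSeriesDataset,
    variance_model: str = "proportional_to_mean",
) -> LinearFit:
    """Fit ``y ~ intercept + slope * DF`` by weighted least squares."""
    _check_fittable(ds)
    x = ds.df_values
    y = ds.response
    w = _weights(x, variance_model)
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = (float(v) for v in res.params)
    fitted = intercept + slope * x
    resid = y - fitted
    r2 = weighted_r2(y, fitted, w)
    return LinearFit(
        intercept=intercept, slope=slope, weights=w, fitted=fitted, residuals=resid,
        r2=r2, variance_model=variance_model, n_obs=len(y),
    )


def compute_r2(fit: ProportionalFit | LinearFit, ds: DilutionSeriesDataset) -> float:
    """Recompute the centered weighted R^2 of ``fit`` on ``ds``.

    NaN flags the undefined case (zero total sum of squares); no division by
    zero is performed.
    """
    y = ds.response
    fitted = np.asarray(fit.predict(ds.df_values), dtype=float)
    return weighted_r2(y, fitted, fit.weights)


@dataclass
class BiasComparison:
    """Decision on whether two methods' proportionality constants differ."""

    method_a: str
    method_b: str
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    significantly_different: bool
    rule: str
    difference_ci: tuple[float, float] | None = None


def compare_proportionality_constants(
    boot_a,
    boot_b,
    rule: str = "ci_overlap",
) -> BiasComparison:
    """Compare two bootstrap results for beta1 between counting methods.

    Default rule declares a significant bias when the two confidence
    intervals do not overlap.  The more powerful alternative
    ``rule="difference_ci"`` forms the bootstrap distribution of the paired
    difference of replicates and declares significance when its percentile
    interval excludes zero (requires stored replicates of equal length).
    """
    if boot_a.level != boot_b.level:
        raise FitError(f"confidence levels differ: {boot_a.level} vs {boot_b.level}")
    ci_a = (boot_a.ci_lo, boot_a.ci_hi)
    ci_b = (boot_b.ci_lo, boot_b.ci_hi)
    diff_ci = None
    if rule == "ci_overlap":
        sig = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
        rule_desc = f"non-overlap of the two {boot_a.level:.0%} percentile bootstrap CIs"
    elif rule == "difference_ci":
        if boot_a.replicates is None or boot_b.replicates is None:
            raise FitError("difference_ci rule requires stored bootstrap replicates")
        ra, rb = np.asarray(boot_a.replicates), np.asarray(boot_b.replicates)
        if len(ra) != len(rb):
            raise FitError("difference_ci rule requires equal replicate counts")
        alpha = 1.0 - boot_a.level
        lo, hi = np.quantile(ra - rb, [alpha / 2, 1 - alpha / 2])
        diff_ci = (float(lo), float(hi))
        sig = not (diff_ci[0] <= 0.0 <= diff_ci[1])
        rule_desc = f"{boot_a.level:.0%} percentile bootstrap CI of the difference excludes 0"
    else:
        raise FitError(f"unknown comparison rule {rule!r}")
    return BiasComparison(
        method_a=getattr(boot_a, "label", "") or "a",
        method_b=getattr(boot_b, "label", "") or "b",
        ci_a=(float(ci_a[0]), float(ci_a[1])),
        ci_b=(float(ci_b[0]), float(ci_b[1])),
        significantly_different=bool(sig),
        rule=rule_desc,
        difference_ci=diff_ci,
    )
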