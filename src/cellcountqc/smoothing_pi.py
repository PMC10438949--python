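"""Flexible polynomial smoothing and the proportionality index (PI).

The proportionality index quantifies systematic deviation from proportional
dilution response after random variability has been reduced by smoothing.
A flexible polynomial in the dilution fraction (default order 4),

    y = b0 + b1*DF + b2*DF^2 + b3*DF^3 + b4*DF^4,

is fit to the series; the PI is the smoothed scaled sum of squared errors

    PI = sum_ij ( e_ij^s / lambda_hat_ij )^2,

where ``lambda_hat_ij = beta1 * DF_i`` is the proportional-model prediction
and ``e_ij^s = y_smooth(DF_i) - lambda_hat_ij`` is the smoothed residual
from proportionality.  Lower PI means more proportional counting.

Conventions (the PI's residual is not uniquely defined by its double-sum
form; these choices are echoed into reports):

* replicate observations are averaged to the tube level before smoothing
  and PI (``level="observation"`` analyses raw observations instead);
* the smoothed value at DF_i is shared by all tubes j at that dilution, so a
  dilution with more tubes contributes more terms to the sum;
* the scaling denominator is the proportional-model prediction, the only
  model-based estimate of the true concentration available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .exceptions import FitError
from .proportionality import ProportionalFit, _weights
from .study_data import DilutionSeriesDataset

DEFAULT_SMOOTHING_DEGREE = 4


def _analysis_xy(ds: DilutionSeriesDataset, level: str) -> tuple[np.ndarray, np.ndarray]:
    if level == "tube":
        tm = ds.tube_means()
        return tm["target_df"].to_numpy(dtype=float), tm["response"].to_numpy(dtype=float)
    if level == "observation":
        return ds.df_values, ds.response
    raise FitError(f"level must be 'tube' or 'observation', got {level!r}")


@dataclass
class SmoothingFit:
    """Least-squares polynomial in DF (the flexible model)."""

    degree: int
    coefficients: np.ndarray  # power-basis, ascending: b0, b1, ...
    fitted_at_df: dict[float, float]
    level: str
    weighted: bool
    capped: bool  # True when the default degree was reduced to fit the data
    _poly: Polynomial

    def predict(self, df_values: np.ndarray | float) -> np.ndarray | float:
        return self._poly(np.asarray(df_values, dtype=float))


def fit_smoothing_polynomial(
    ds: DilutionSeriesDataset,
    degree: int | None = None,
    level: str = "tube",
    weighted: bool = False,
    variance_model: str = "proportional_to_mean",
) -> SmoothingFit:
    """Fit the flexible polynomial model by least squares.

    ``degree=None`` requests the default order (4), automatically capped at
    ``(number of distinct DFs) - 1`` with a warning; an explicit degree above
    the cap is an error.  The fit is unweighted by default; ``weighted=True``
    applies the same ``1/DF`` weights as the proportional fit.
    """
    x, y = _analysis_xy(ds, level)
    k = len(np.unique(x))
    cap = k - 1
    capped = False
    if degree is None:
        degree = DEFAULT_SMOOTHING_DEGREE
        if degree > cap:
            warnings.warn(
                f"smoothing degree {degree} capped at {cap} ({k} distinct dilution fractions)",
                stacklevel=2,
            )
            degree = cap
            capped = True
    if degree < 1:
        raise FitError(f"smoothing degree must be >= 1, got {degree}")
    if degree > cap:
        raise FitError(
            f"smoothing degree {degree} too high: at most {cap} for {k} distinct dilution fractions"
        )
    w = np.sqrt(_weights(x, variance_model)) if weighted else None
    poly = Polynomial.fit(x, y, deg=degree, w=w)
    coeffs = poly.convert().coef
    fitted_at_df = {float(d): float(poly(d)) for d in np.unique(x)}
    return SmoothingFit(
        degree=degree,
        coefficients=np.asarray(coeffs, dtype=float),
        fitted_at_df=fitted_at_df,
        level=level,
        weighted=weighted,
        capped=capped,
        _poly=poly,
    )


@dataclass
class PIValue:
    """Proportionality index with its per-sample components."""

    value: float
    components: np.ndarray  # one scaled squared error per (dilution, tube)
    level: str

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def compute_pi(
    ds: DilutionSeriesDataset,
    prop_fit: ProportionalFit,
    smooth_fit: SmoothingFit,
) -> PIValue:
    """Compute the smoothed scaled sum of squared errors.

    One component per sample (tube) at ``level="tube"``, or per observation
    at ``level="observation"`` (taken from ``smooth_fit.level``):
    ``((y_smooth(DF) - beta1*DF) / (beta1*DF))^2``.
    """
    x, _ = _analysis_xy(ds, smooth_fit.level)
    lam = prop_fit.beta1 * x
    if np.any(lam == 0):
        raise FitError("PI scaling undefined: proportional prediction is zero at some dilution")
    e = np.asarray(smooth_fit.predict(x), dtype=float) - lam
    components = (e / lam) ** 2
    return PIValue(value=float(components.sum()), components=components, level=smooth_fit.level)


def pi_statistic(
    ds: DilutionSeriesDataset,
    degree: int | None = None,
    level: str = "tube",
    variance_model: str = "proportional_to_mean",
) -> float:
    """Convenience scalar statistic: refit both models on ``ds`` and return PI.

    Suitable for bootstrapping (the fits are recomputed on every replicate).
    """
    from .proportionality import fit_proportional

    prop = fit_proportional(ds, variance_model=variance_model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        smooth = fit_smoothing_polynomial(ds, degree=degree, level=level)
    return compute_pi(ds, prop, smooth).value
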