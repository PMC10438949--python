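"""Consolidated evaluation reports: fits, PI, precision and comparisons.

One :class:`EvaluationReport` collects, per (preparation x method): the
proportional fit (beta1 with bootstrap CI, R^2), the linear fit (intercept),
the proportionality index with bootstrap CI, the replicate %CV summary and
the viability summary; plus, per preparation with >= 2 methods, pairwise
proportionality-constant bias comparisons and ANOVA/pairwise tables for
viable concentration and % viability.  Every number in the report is
recomputable from the input data and the recorded settings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .exceptions import DesignError
from .precision_viability import compare_methods, compute_replicate_cv, summarize_viability
from .proportionality import (
    compare_proportionality_constants,
    fit_linear,
    fit_proportional,
)
from .resampling import bootstrap_statistic
from .smoothing_pi import compute_pi, fit_smoothing_polynomial, pi_statistic
from .study_data import CountsTable, DilutionSeriesDataset


class AnalysisSettings(BaseModel):
    """Analysis conventions and tuning knobs; defaults follow the standard
    evaluation settings (1,000 bootstrap iterations, 95% confidence,
    degree-4 smoothing, alpha 0.05, variance proportional to mean)."""

    response: str = "viable_conc"
    variance_model: str = "proportional_to_mean"
    smoothing_degree: int | None = None  # None = default 4, capped by data
    pi_level: str = "tube"
    n_boot: int = Field(default=1000, ge=2)
    confidence_level: float = Field(default=0.95, gt=0, lt=1)
    resample_unit: str = "tube"
    stratified: bool = False
    alpha: float = Field(default=0.05, gt=0, lt=1)
    pairwise: str = "tukey"
    comparison_rule: str = "ci_overlap"
    viability_bin_width: float = Field(default=1.0, gt=0)
    seed: int = 0


def _conventions(settings: AnalysisSettings) -> dict:
    return {
        "pi_residual": "smoothed prediction at DF_i shared across tubes j; "
        "e_ij = y_smooth(DF_i) - beta1*DF_i; scaled by beta1*DF_i",
        "pi_analysis_level": settings.pi_level,
        "r2": "centered weighted R^2 (SST about the weighted grand mean), also for the zero-intercept model",
        "weights": "w = 1/DF under variance proportional to mean",
        "bootstrap": f"percentile interval, {settings.resample_unit}-level resampling, "
        f"{'stratified by dilution' if settings.stratified else 'unstratified'}",
        "pairwise": settings.pairwise,
        "bias_rule": settings.comparison_rule,
    }


@dataclass
class MethodEvaluation:
    """All single-series results for one (preparation, method)."""

    preparation: str
    method: str
    beta1: float
    beta1_ci: tuple[float, float]
    r2: float
    intercept: float
    slope: float
    pi: float
    pi_ci: tuple[float, float]
    smoothing_degree: int
    max_cv_pct: float
    mean_cv_pct: float
    viability: dict
    n_obs: int
    warnings: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "preparation": self.preparation,
            "method": self.method,
            "beta1": self.beta1,
            "beta1_ci_lo": self.beta1_ci[0],
            "beta1_ci_hi": self.beta1_ci[1],
            "r2": self.r2,
            "intercept": self.intercept,
            "slope": self.slope,
            "pi": self.pi,
            "pi_ci_lo": self.pi_ci[0],
            "pi_ci_hi": self.pi_ci[1],
            "smoothing_degree": self.smoothing_degree,
            "max_cv_pct": self.max_cv_pct,
            "mean_cv_pct": self.mean_cv_pct,
            "n_obs": self.n_obs,
        }


@dataclass
class EvaluationReport:
    evaluations: list[MethodEvaluation]
    bias_comparisons: list[dict]
    method_comparisons: list[dict]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "evaluations": [
                {**asdict(e)} for e in self.evaluations
            ],
            "bias_comparisons": self.bias_comparisons,
            "method_comparisons": self.method_comparisons,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=_jsonable)

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_row() for e in self.evaluations])

    def write(self, output_dir: str | Path) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tmp = out / "report.json.tmp"
        tmp.write_text(self.to_json())
        tmp.replace(out / "report.json")
        self.fits_frame().to_csv(out / "fits.csv", index=False)
        if self.method_comparisons:
            pd.DataFrame(self.method_comparisons).to_csv(out / "comparisons.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def evaluate_datasets(
    datasets: Mapping[tuple[str, str], DilutionSeriesDataset],
    settings: AnalysisSettings | None = None,
) -> EvaluationReport:
    """Run the full evaluation over (preparation, method)-keyed datasets."""
    settings = settings or AnalysisSettings()
    evaluations: list[MethodEvaluation] = []
    beta1_boots: dict[tuple[str, str], object] = {}

    for (prep, method), ds in datasets.items():
        ds = DilutionSeriesDataset(ds.design, ds.frame, response_choice=settings.response)
        notes: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            prop = fit_proportional(ds, variance_model=settings.variance_model)
            lin = fit_linear(ds, variance_model=settings.variance_model)
            smooth = fit_smoothing_polynomial(ds, degree=settings.smoothing_degree, level=settings.pi_level)
            pi = compute_pi(ds, prop, smooth)

            def beta1_stat(d, vm=settings.variance_model):
                return fit_proportional(d, variance_model=vm).beta1

            boot_beta1 = bootstrap_statistic(
                ds, beta1_stat, n_boot=settings.n_boot, level=settings.confidence_level,
                seed=settings.seed, resample_unit=settings.resample_unit,
                stratified=settings.stratified, name="beta1", label=method,
            )

            # degree=None lets each replicate's smoother auto-cap: an
            # unstratified resample can miss a dilution, leaving too few
            # distinct DFs for the full-degree polynomial
            def pi_stat(d, lvl=settings.pi_level, vm=settings.variance_model):
                return pi_statistic(d, degree=None, level=lvl, variance_model=vm)

            boot_pi = bootstrap_statistic(
                ds, pi_stat, n_boot=settings.n_boot, level=settings.confidence_level,
                seed=settings.seed, resample_unit=settings.resample_unit,
                stratified=settings.stratified, name="pi", label=method,
            )
            cv = compute_replicate_cv(ds)
            viab = summarize_viability(ds, bin_width=settings.viability_bin_width)
        notes.extend(str(w.message) for w in caught)
        beta1_boots[(prep, method)] = boot_beta1
        summary = cv.summary.iloc[0]
        evaluations.append(
            MethodEvaluation(
                preparation=prep,
                method=method,
                beta1=prop.beta1,
                beta1_ci=(boot_beta1.ci_lo, boot_beta1.ci_hi),
                r2=prop.r2,
                intercept=lin.intercept,
                slope=lin.slope,
                pi=pi.value,
                pi_ci=(boot_pi.ci_lo, boot_pi.ci_hi),
                smoothing_degree=smooth.degree,
                max_cv_pct=float(summary["max_cv_pct"]),
                mean_cv_pct=float(summary["mean_cv_pct"]),
                viability=viab.to_dict(),
                n_obs=ds.n_obs,
                warnings=notes,
            )
        )

    # cross-method sections, per preparation
    bias_rows: list[dict] = []
    comparison_rows: list[dict] = []
    preps = sorted({prep for prep, _ in datasets})
    for prep in preps:
        methods = sorted(m for p, m in datasets if p == prep)
        if len(methods) < 2:
            continue
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                cmp_ = compare_proportionality_constants(
                    beta1_boots[(prep, methods[i])],
                    beta1_boots[(prep, methods[j])],
                    rule=settings.comparison_rule,
                )
                bias_rows.append({"preparation": prep, **asdict(cmp_)})
        panel = {m: datasets[(prep, m)] for m in methods}
        for response in ("viable_conc", "pct_viability"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mc = compare_methods(panel, response=response, alpha=settings.alpha, pairwise=settings.pairwise)
            for row in mc.to_rows():
                comparison_rows.append({"preparation": prep, **row})

    provenance = {
        "package": "cellcountqc",
        "version": __version__,
        "settings": settings.model_dump(),
        "conventions": _conventions(settings),
    }
    return EvaluationReport(
        evaluations=evaluations,
        bias_comparisons=bias_rows,
        method_comparisons=comparison_rows,
        provenance=provenance,
    )


def evaluate_table(table: CountsTable, settings: AnalysisSettings | None = None) -> EvaluationReport:
    if not table.datasets:
        raise DesignError("no datasets to evaluate")
    return evaluate_datasets(table.datasets, settings)


# -- optional figures -------------------------------------------------------

def plot_report_figures(
    datasets: Mapping[tuple[str, str], DilutionSeriesDataset],
    output_dir: str | Path,
    bin_width: float = 1.0,
) -> list[Path]:
    """Write %CV-vs-dilution and viability-histogram figures per dataset."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (prep, method), ds in datasets.items():
        stem = f"{prep}_{method}".replace(" ", "_")
        cv = compute_replicate_cv(ds)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.scatter(cv.per_tube["target_df"], cv.per_tube["cv_pct"])
        ax.set_xlabel("target dilution fraction")
        ax.set_ylabel("%CV across replicate observations")
        ax.set_title(f"{prep} / {method}")
        fig.tight_layout()
        p = out / f"cv_{stem}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)

        viab = summarize_viability(ds, bin_width=bin_width)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        centers = (viab.bin_edges[:-1] + viab.bin_edges[1:]) / 2
        ax.bar(centers, viab.frequencies / viab.frequencies.sum(), width=viab.bin_width)
        ax.set_xlim(max(0, viab.range[0] - 5), min(100, viab.range[1] + 5))
        ax.set_xlabel("% viability")
        ax.set_ylabel("proportion of results")
        ax.set_title(f"{prep} / {method}")
        fig.tight_layout()
        p = out / f"viability_{stem}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
    return written
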