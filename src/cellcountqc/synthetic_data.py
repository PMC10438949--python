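"""Synthetic dilution-series generator.

Generates count data with the statistical structure the evaluation analysis
assumes: a proportional truth (tube mean = stock x DF), multiplicative gamma
measurement noise whose variance can be made proportional to the mean, small
gamma-distributed tube-to-tube pipetting effects, and a normal % viability
that is independent of dilution.  Non-proportional artifacts can be
injected:

* ``background`` bias adds a constant concentration ``b`` at every dilution
  (debris or mis-segmentation that does not dilute with the cells);
* ``saturation`` bias compresses the response above a DF knee (instrument
  operating-range effects);
* bead interference models residual selection beads with two separable
  effects: *count inflation*, a density-dependent miscount that multiplies
  the reported concentration by ``(1 + f * DF)`` (full fractional miscount f
  at the undiluted stock, shrinking with dilution, as crowding/coincidence
  interference does), and *viability depression*, which shifts the reported
  % viability down by a fixed number of percentage points (beads counted as
  dead cells).

``stock_conc`` is the viable-cell stock concentration; the generated total
concentration is derived from the viable concentration and the drawn
viability, so every synthetic observation is internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import DesignError
from .study_data import (
    DilutionSeriesDataset,
    StudyDesign,
    assign_blinded_ids,
)

STOCK_RANGE = (5e5, 1e6)  # cells/mL, instrument operating range


class SyntheticConfig(BaseModel):
    """Generative truth for one (preparation x method) dilution series."""

    model_config = ConfigDict(arbitrary_types_allowed=True, validate_assignment=True)

    design: StudyDesign = Field(default_factory=StudyDesign)
    preparation: str = "pbmc"
    method: str = "method_1"
    stock_conc: float | None = Field(default=None, gt=0, description="viable cells/mL; drawn in STOCK_RANGE when None")
    obs_cv: float = Field(default=0.05, ge=0, description="observation CV at the undiluted stock")
    tube_cv: float = Field(default=0.02, ge=0, description="tube-to-tube pipetting CV")
    variance_mode: Literal["proportional_to_mean", "constant_cv"] = "proportional_to_mean"
    bias_mode: Literal["none", "background", "saturation"] = "none"
    bias_magnitude: float = Field(default=0.0, ge=0, description="background concentration, cells/mL")
    saturation_knee: float = Field(default=0.5, gt=0, le=1)
    saturation_compression: float = Field(default=0.5, ge=0, le=1)
    viability_mean: float = Field(default=90.0, ge=0, le=100)
    viability_sd: float = Field(default=2.0, ge=0)
    bead_count_inflation: float = Field(default=0.0, ge=0, description="fractional miscount at the undiluted stock")
    bead_viability_depression: float = Field(default=0.0, ge=0, description="percentage points")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if self.bias_mode == "background" and self.bias_magnitude == 0:
            # allowed, just degenerate; no error
            pass
        return self

    def to_jsonable(self) -> dict:
        d = self.model_dump()
        d["design"] = {
            "target_dilution_fractions": [str(f) for f in self.design.target_dilution_fractions],
            "tubes_per_dilution": self.design.tubes_per_dilution,
            "observations_per_tube": self.design.observations_per_tube,
        }
        return d


@dataclass
class TruthRecord:
    """Every generative parameter and realisation behind a simulated dataset."""

    config: dict
    stock_conc: float
    tube_effects: dict[str, float]
    tube_means: dict[str, float]
    viability_clip_count: int
    expected_beta1: float  # weighted-fit expectation of beta1 under this truth

    def to_jsonable(self) -> dict:
        return {
            "config": self.config,
            "stock_conc": self.stock_conc,
            "tube_effects": self.tube_effects,
            "tube_means": self.tube_means,
            "viability_clip_count": self.viability_clip_count,
            "expected_beta1": self.expected_beta1,
        }


@dataclass
class SimulationResult:
    dataset: DilutionSeriesDataset
    truth: TruthRecord


def _gamma_multiplier(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Unit-mean gamma multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    shape = 1.0 / cv**2
    return rng.gamma(shape, 1.0 / shape, size=size)


def _effective_df(df: float, config: SyntheticConfig) -> float:
    if config.bias_mode == "saturation" and df > config.saturation_knee:
        return config.saturation_knee + (df - config.saturation_knee) * config.saturation_compression
    return df


def simulate_dilution_series(config: SyntheticConfig) -> SimulationResult:
    """Simulate one dilution series; deterministic for a given config.

    Per tube: ``mean = stock * DF_eff * tube_effect (+ background)``.
    Per observation, the viable concentration is gamma-distributed about the
    tube mean: under ``variance_mode="proportional_to_mean"`` with
    ``Var = theta * mean`` where ``theta = obs_cv^2 * stock`` (so the CV at
    the undiluted stock equals ``obs_cv``); under ``"constant_cv"`` the CV is
    ``obs_cv`` at every dilution.  % viability is normal, clipped to
    [0, 100] with clip events counted.
    """
    rng = np.random.default_rng(config.seed)
    stock = config.stock_conc if config.stock_conc is not None else float(rng.uniform(*STOCK_RANGE))
    design = config.design
    blind = assign_blinded_ids(design, seed=config.seed)

    rows = []
    tube_effects: dict[str, float] = {}
    tube_means: dict[str, float] = {}
    clip_count = 0
    theta = config.obs_cv**2 * stock  # variance/mean scale at proportional_to_mean
    for i, frac in enumerate(design.target_dilution_fractions, start=1):
        df = float(frac)
        df_eff = _effective_df(df, config)
        for j in range(1, design.tubes_per_dilution + 1):
            tube_id = f"d{i}t{j}"
            effect = float(_gamma_multiplier(rng, config.tube_cv))
            tube_mean = stock * df_eff * effect
            if config.bias_mode == "background":
                tube_mean += config.bias_magnitude
            tube_effects[tube_id] = effect
            tube_means[tube_id] = tube_mean
            for k in range(1, design.observations_per_tube + 1):
                if config.obs_cv == 0:
                    viable_true = tube_mean
                elif config.variance_mode == "proportional_to_mean":
                    shape = tube_mean / theta
                    viable_true = float(rng.gamma(shape, theta))
                else:
                    viable_true = tube_mean * float(_gamma_multiplier(rng, config.obs_cv))
                viable_rep = viable_true * (1.0 + config.bead_count_inflation * df)
                v = config.viability_mean - config.bead_viability_depression
                if config.viability_sd > 0:
                    v += float(rng.normal(0.0, config.viability_sd))
                if v < 0 or v > 100:
                    clip_count += 1
                    v = min(max(v, 0.0), 100.0)
                if v <= 0:
                    viable, total, v = 0.0, viable_rep, 0.0
                else:
                    viable = viable_rep
                    total = viable_rep * 100.0 / v
                rows.append(
                    {
                        "preparation": config.preparation,
                        "method": config.method,
                        "target_df": df,
                        "tube_id": tube_id,
                        "blinded_id": blind[(frac, j)],
                        "obs_index": k,
                        "total_conc": total,
                        "viable_conc": viable,
                        "pct_viability": v,
                    }
                )
    frame = pd.DataFrame(rows)
    ds = DilutionSeriesDataset(design=design, frame=frame)

    # expectation of the weighted (1/DF) zero-intercept fit under this truth:
    # beta1 = sum(E[y]) / sum(DF) with E[y] per observation at each DF
    dfs = np.array([float(f) for f in design.target_dilution_fractions])
    e_y = np.array([stock * _effective_df(d, config) for d in dfs])
    if config.bias_mode == "background":
        e_y = e_y + config.bias_magnitude
    e_y = e_y * (1.0 + config.bead_count_inflation * dfs)
    expected_beta1 = float(e_y.sum() / dfs.sum())

    truth = TruthRecord(
        config=config.to_jsonable(),
        stock_conc=stock,
        tube_effects=tube_effects,
        tube_means=tube_means,
        viability_clip_count=clip_count,
        expected_beta1=expected_beta1,
    )
    return SimulationResult(dataset=ds, truth=truth)


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % 2**31)


def simulate_method_panel(
    configs: Mapping[str, SyntheticConfig],
    shared_stock: bool = True,
) -> dict[str, SimulationResult]:
    """Simulate several counting methods on the same preparation.

    All configs must share one design.  With ``shared_stock=True`` one stock
    concentration is drawn (or taken from the first config that sets it) and
    forced on every method, so between-method differences reflect only the
    configured biases.  Each method's noise stream is derived from its config
    seed and its position in the panel, so identical configs still produce
    independent noise.
    """
    if not configs:
        raise DesignError("empty method panel")
    designs = {frozenset(c.design.target_dilution_fractions) for c in configs.values()}
    counts = {(c.design.tubes_per_dilution, c.design.observations_per_tube) for c in configs.values()}
    if len(designs) != 1 or len(counts) != 1:
        raise DesignError("panel configs must share one study design")

    stock = None
    if shared_stock:
        explicit = [c.stock_conc for c in configs.values() if c.stock_conc is not None]
        if explicit:
            stock = explicit[0]
        else:
            first = next(iter(configs.values()))
            stock = float(np.random.default_rng(_child_seed(first.seed, 0xC0FFEE % 2**16)).uniform(*STOCK_RANGE))

    out: dict[str, SimulationResult] = {}
    for idx, (name, cfg) in enumerate(configs.items()):
        update: dict = {"method": name, "seed": _child_seed(cfg.seed, idx)}
        if shared_stock:
            update["stock_conc"] = stock
        out[name] = simulate_dilution_series(cfg.model_copy(update=update))
    return out
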