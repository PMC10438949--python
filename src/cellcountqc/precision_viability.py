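"""Replicate precision (%CV), viability distributions, and method comparisons.

%CV across the replicate observations of a tube measures instrument
precision.  % viability should be invariant to dilution, so its distribution
across all samples of a series summarises the quality of the viability
measurement; methods are compared per dilution by one-way ANOVA on tube
means followed by pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError
from .study_data import DilutionSeriesDataset


@dataclass
class CVResult:
    """Per-tube replicate coefficients of variation plus group summaries."""

    per_tube: pd.DataFrame  # preparation, method, target_df, tube_id, n_obs, mean, sd, cv_pct, flag
    summary: pd.DataFrame  # preparation, method, max_cv_pct, mean_cv_pct, n_tubes


def compute_replicate_cv(ds: DilutionSeriesDataset) -> CVResult:
    """%CV = 100 * sd / mean across the replicate observations of each tube.

    Sample standard deviation (n-1 denominator).  Tubes with a single
    observation or zero mean are flagged and their cv left undefined (NaN).
    """
    f = ds.frame
    group_cols = [c for c in ("preparation", "method") if c in f.columns]
    rows = []
    for key, sub in f.groupby(group_cols + ["target_df", "tube_id"], sort=True):
        vals = sub[ds.response_choice].to_numpy(dtype=float)
        rec = dict(zip(group_cols + ["target_df", "tube_id"], key))
        rec["n_obs"] = len(vals)
        rec["mean"] = float(np.mean(vals))
        if len(vals) < 2:
            rec.update(sd=np.nan, cv_pct=np.nan, flag="single_observation")
        else:
            sd = float(np.std(vals, ddof=1))
            rec["sd"] = sd
            if rec["mean"] == 0:
                rec.update(cv_pct=np.nan, flag="zero_mean")
            else:
                rec.update(cv_pct=100.0 * sd / rec["mean"], flag="")
        rows.append(rec)
    per_tube = pd.DataFrame(rows)
    if group_cols:
        summary = (
            per_tube.groupby(group_cols, sort=True)["cv_pct"]
            .agg(max_cv_pct="max", mean_cv_pct="mean", n_tubes="count")
            .reset_index()
        )
    else:
        summary = pd.DataFrame(
            [{"max_cv_pct": per_tube["cv_pct"].max(), "mean_cv_pct": per_tube["cv_pct"].mean(), "n_tubes": per_tube["cv_pct"].count()}]
        )
    return CVResult(per_tube=per_tube, summary=summary)


@dataclass
class ViabilitySummary:
    """Histogram description of % viability across a dilution series."""

    values: np.ndarray
    bin_edges: np.ndarray
    frequencies: np.ndarray
    mode_bin: tuple[float, float]
    mode_tied: bool
    range: tuple[float, float]
    bin_width: float

    def to_dict(self) -> dict:
        return {
            "n": int(len(self.values)),
            "range": [float(self.range[0]), float(self.range[1])],
            "mode_bin": [float(self.mode_bin[0]), float(self.mode_bin[1])],
            "mode_tied": self.mode_tied,
            "bin_width": self.bin_width,
            "mean": float(np.mean(self.values)),
            "sd": float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0,
        }


def summarize_viability(ds: DilutionSeriesDataset, bin_width: float = 1.0) -> ViabilitySummary:
    """Histogram of % viability over [0, 100] with the given bin width.

    Ties for the peak bin break toward the lowest edge and are flagged.
    """
    vals = ds.frame["pct_viability"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise DesignError("no viability values present")
    n_bins = int(np.ceil(100.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    freq, edges = np.histogram(vals, bins=edges)
    peak = int(np.argmax(freq))  # argmax returns the first (lowest-edge) max
    tied = int(np.sum(freq == freq[peak])) > 1
    return ViabilitySummary(
        values=vals,
        bin_edges=edges,
        frequencies=freq,
        mode_bin=(float(edges[peak]), float(edges[peak + 1])),
        mode_tied=tied,
        range=(float(vals.min()), float(vals.max())),
        bin_width=bin_width,
    )


@dataclass
class PairwiseComparison:
    method_a: str
    method_b: str
    p: float
    significant: bool


@dataclass
class DilutionComparison:
    target_df: float
    anova_p: float
    pairwise: list[PairwiseComparison]
    n_per_method: dict[str, int]


@dataclass
class MethodComparison:
    """Per-dilution ANOVA + pairwise comparison of counting methods."""

    response: str
    alpha: float
    pairwise_procedure: str
    per_dilution: list[DilutionComparison]
    skipped_dilutions: list[float] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = []
        for d in self.per_dilution:
            for pw in d.pairwise:
                rows.append(
                    {
                        "response": self.response,
                        "target_df": d.target_df,
                        "anova_p": d.anova_p,
                        "method_a": pw.method_a,
                        "method_b": pw.method_b,
                        "p": pw.p,
                        "significant": pw.significant,
                        "procedure": self.pairwise_procedure,
                    }
                )
        return rows


def compare_methods(
    datasets: Mapping[str, DilutionSeriesDataset],
    response: str = "viable_conc",
    alpha: float = 0.05,
    pairwise: str = "tukey",
    level: str = "tube",
) -> MethodComparison:
    """One-way ANOVA per dilution across methods, with pairwise follow-up.

    The analysis unit is the tube mean (averaging within-tube replicates
    avoids pseudo-replication); ``level="observation"`` analyses raw
    observations instead and is anti-conservative.  Pairwise comparisons use
    Tukey's HSD by default; ``pairwise="ttest"`` gives unadjusted two-sample
    t-tests.  Dilutions with fewer than 2 tubes for any method are skipped
    with a warning.
    """
    if len(datasets) < 2:
        raise DesignError("need >= 2 methods to compare")
    if pairwise not in ("tukey", "ttest"):
        raise DesignError(f"pairwise must be 'tukey' or 'ttest', got {pairwise!r}")
    designs = [frozenset(ds.design.target_dilution_fractions) for ds in datasets.values()]
    if len(set(designs)) != 1:
        raise DesignError("methods must share one dilution design")

    methods = list(datasets)
    per_df_values: dict[float, dict[str, np.ndarray]] = {}
    for m, ds in datasets.items():
        f = ds.frame
        if level == "tube":
            grp = f.groupby(["target_df", "tube_id"], sort=True)[response].mean().reset_index()
            for df_val, sub in grp.groupby("target_df"):
                per_df_values.setdefault(float(df_val), {})[m] = sub[response].to_numpy(dtype=float)
        else:
            for df_val, sub in f.groupby("target_df"):
                per_df_values.setdefault(float(df_val), {})[m] = sub[response].to_numpy(dtype=float)

    per_dilution: list[DilutionComparison] = []
    skipped: list[float] = []
    for df_val in sorted(per_df_values, reverse=True):
        groups = per_df_values[df_val]
        if any(m not in groups or len(groups[m]) < 2 for m in methods):
            warnings.warn(f"dilution {df_val} skipped: < 2 tubes for some method", stacklevel=2)
            skipped.append(df_val)
            continue
        arrays = [groups[m] for m in methods]
        if all(np.allclose(a, arrays[0].mean()) for a in arrays) and all(np.ptp(a) == 0 for a in arrays):
            anova_p = np.nan  # constant input: F undefined
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, anova_p = stats.f_oneway(*arrays)
        pairs: list[PairwiseComparison] = []
        if pairwise == "tukey":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = stats.tukey_hsd(*arrays)
            for i in range(len(methods)):
                for j in range(i + 1, len(methods)):
                    p = float(res.pvalue[i, j])
                    pairs.append(PairwiseComparison(methods[i], methods[j], p, p < alpha))
        else:
            for i in range(len(methods)):
                for j in range(i + 1, len(methods)):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p = float(stats.ttest_ind(arrays[i], arrays[j]).pvalue)
                    pairs.append(PairwiseComparison(methods[i], methods[j], p, p < alpha))
        per_dilution.append(
            DilutionComparison(
                target_df=df_val,
                anova_p=float(anova_p),
                pairwise=pairs,
                n_per_method={m: int(len(groups[m])) for m in methods},
            )
        )
    procedure = "Tukey HSD after one-way ANOVA" if pairwise == "tukey" else "unadjusted pairwise t-tests"
    return MethodComparison(
        response=response,
        alpha=alpha,
        pairwise_procedure=procedure,
        per_dilution=per_dilution,
        skipped_dilutions=skipped,
    )
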