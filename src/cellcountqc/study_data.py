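"""Data model and tabular I/O for dilution-series cell-counting studies.

A counting-method evaluation study measures the same cell stock at several
target dilution fractions (DF), with replicate tubes per dilution and
replicate instrument observations per tube.  This module holds the study
design, the per-observation records, CSV/Excel readers and writers for the
documented long-format schema, dataset validation, and blinded tube-ID
assignment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DesignError, SchemaError

#: Documented CSV column names (external) -> internal frame column names.
CSV_COLUMNS: dict[str, str] = {
    "preparation": "preparation",
    "method": "method",
    "target_df": "target_df",
    "tube_id": "tube_id",
    "blinded_id": "blinded_id",
    "obs_index": "obs_index",
    "total_conc_cells_per_ml": "total_conc",
    "viable_conc_cells_per_ml": "viable_conc",
    "pct_viability": "pct_viability",
}

#: Columns that must be present in an input file (blinded_id is optional).
REQUIRED_CSV_COLUMNS = tuple(c for c in CSV_COLUMNS if c != "blinded_id")

_NUMERIC_FIELDS = ("total_conc", "viable_conc", "pct_viability")

#: Default tolerance (percentage points) for the viability consistency check.
DEFAULT_VIABILITY_TOLERANCE_PP = 0.5


def parse_dilution(value) -> Fraction:
    """Parse a dilution fraction given as a ratio string or a number.

    Accepts ``"1:3"`` (one part in three -> 1/3), ``"1/3"``, ``"0.25"`` or a
    plain number.  Numbers are snapped to the nearest small-denominator
    fraction so that ``0.3333333333`` round-trips to ``1/3``.
    """
    if isinstance(value, Fraction):
        frac = value
    elif isinstance(value, str):
        s = value.strip()
        if ":" in s:
            # "1:3" denotes a 1-to-3 dilution of stock, i.e. fraction 1/3
            a, b = s.split(":")
            frac = Fraction(int(a), int(b))
        elif "/" in s:
            frac = Fraction(s)
        else:
            frac = Fraction(float(s)).limit_denominator(1000)
    else:
        frac = Fraction(float(value)).limit_denominator(1000)
    if not 0 < frac <= 1:
        raise DesignError(f"dilution fraction must be in (0, 1], got {value!r}")
    return frac


@dataclass(frozen=True)
class StudyDesign:
    """The dilution-series layout of a counting-method evaluation.

    Defaults follow the recommended design: five target dilution fractions
    1, 1/2, 1/3, 1/4, 1/5, three tubes per dilution, three observations
    per tube (45 observations per method and preparation).
    """

    target_dilution_fractions: tuple[Fraction, ...] = (
        Fraction(1),
        Fraction(1, 2),
        Fraction(1, 3),
        Fraction(1, 4),
        Fraction(1, 5),
    )
    tubes_per_dilution: int = 3
    observations_per_tube: int = 3

    def __post_init__(self) -> None:
        fracs = tuple(parse_dilution(f) for f in self.target_dilution_fractions)
        object.__setattr__(self, "target_dilution_fractions", fracs)
        if len(fracs) < 1:
            raise DesignError("at least one dilution fraction is required")
        if len(set(fracs)) != len(fracs):
            raise DesignError("dilution fractions must be unique")
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise DesignError("dilution fractions must be strictly decreasing")
        if self.tubes_per_dilution < 1 or self.observations_per_tube < 1:
            raise DesignError("tube and observation counts must be >= 1")

    @property
    def fractions_float(self) -> tuple[float, ...]:
        return tuple(float(f) for f in self.target_dilution_fractions)

    @property
    def n_tubes_total(self) -> int:
        return len(self.target_dilution_fractions) * self.tubes_per_dilution

    @property
    def n_observations_total(self) -> int:
        return self.n_tubes_total * self.observations_per_tube


@dataclass(frozen=True)
class CountObservation:
    """One instrument reading on one tube."""

    preparation: str
    method: str
    target_df: float
    tube_id: str
    obs_index: int
    total_conc: float
    viable_conc: float
    pct_viability: float
    blinded_id: int | None = None


@dataclass
class Violation:
    """One validation finding, tied to a frame row where applicable."""

    row: int | None
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"row {self.row}" if self.row is not None else "dataset"
        return f"[{where}] {self.field}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, row: int | None, field_name: str, message: str) -> None:
        self.violations.append(Violation(row, field_name, message))

    def extend(self, other: "ValidationReport") -> None:
        self.violations.extend(other.violations)

    def __len__(self) -> int:
        return len(self.violations)


@dataclass
class DilutionSeriesDataset:
    """All observations for one (preparation x method) evaluation.

    ``frame`` holds one row per observation with internal column names
    (``target_df``, ``tube_id``, ``obs_index``, ``total_conc``,
    ``viable_conc``, ``pct_viability``, plus ``preparation``/``method`` and
    optional ``blinded_id``).  ``response_choice`` names the column analysed
    by the proportionality and precision operations; the default is the
    viable cell density.
    """

    design: StudyDesign
    frame: pd.DataFrame
    response_choice: str = "viable_conc"

    def __post_init__(self) -> None:
        missing = [c for c in ("target_df", "tube_id", "obs_index", *_NUMERIC_FIELDS) if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame missing columns: {missing}")
        if self.response_choice not in ("viable_conc", "total_conc"):
            raise SchemaError(f"response_choice must be viable_conc or total_conc, got {self.response_choice!r}")

    # -- accessors -------------------------------------------------------

    @property
    def response(self) -> np.ndarray:
        return self.frame[self.response_choice].to_numpy(dtype=float)

    @property
    def df_values(self) -> np.ndarray:
        return self.frame["target_df"].to_numpy(dtype=float)

    def distinct_dfs(self) -> np.ndarray:
        return np.unique(self.df_values)

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def tube_means(self) -> pd.DataFrame:
        """Average replicate observations to one value per tube.

        Returns a frame with columns target_df, tube_id, response (mean of
        ``response_choice``) and n_obs, one row per tube.
        """
        g = self.frame.groupby(["target_df", "tube_id"], sort=True)[self.response_choice]
        out = g.agg(["mean", "count"]).reset_index()
        return out.rename(columns={"mean": "response", "count": "n_obs"})

    @property
    def observations(self) -> list[CountObservation]:
        rows = []
        has_blind = "blinded_id" in self.frame.columns
        for _, r in self.frame.iterrows():
            blind = r["blinded_id"] if has_blind and pd.notna(r.get("blinded_id")) else None
            rows.append(
                CountObservation(
                    preparation=str(r.get("preparation", "")),
                    method=str(r.get("method", "")),
                    target_df=float(r["target_df"]),
                    tube_id=str(r["tube_id"]),
                    obs_index=int(r["obs_index"]),
                    total_conc=float(r["total_conc"]),
                    viable_conc=float(r["viable_conc"]),
                    pct_viability=float(r["pct_viability"]),
                    blinded_id=int(blind) if blind is not None else None,
                )
            )
        return rows

    @classmethod
    def from_observations(
        cls,
        design: StudyDesign,
        observations: Iterable[CountObservation],
        response_choice: str = "viable_conc",
    ) -> "DilutionSeriesDataset":
        frame = pd.DataFrame([dataclasses.asdict(o) for o in observations])
        return cls(design=design, frame=frame, response_choice=response_choice)

    def single_group(self) -> tuple[str, str]:
        """Return the unique (preparation, method), or raise if mixed."""
        preps = self.frame.get("preparation")
        methods = self.frame.get("method")
        prep = sorted(set(preps.astype(str))) if preps is not None else [""]
        meth = sorted(set(methods.astype(str))) if methods is not None else [""]
        if len(prep) > 1 or len(meth) > 1:
            raise DesignError(
                f"dataset mixes groups: preparations {prep}, methods {meth}; "
                "split with read_counts_csv before fitting"
            )
        return prep[0], meth[0]


def assign_blinded_ids(design: StudyDesign, seed: int) -> dict[tuple[Fraction, int], int]:
    """Assign each (dilution, tube index) a random blinded integer ID.

    Returns a bijection from (target_df, tube_index in 1..tubes_per_dilution)
    onto {1, ..., n_tubes_total}, deterministic for a given seed; e.g. the
    recommended 5 x 3 design blinds its tubes as a permutation of 1..15.
    """
    rng = np.random.default_rng(seed)
    n = design.n_tubes_total
    perm = rng.permutation(n) + 1
    keys = [
        (df, j)
        for df in design.target_dilution_fractions
        for j in range(1, design.tubes_per_dilution + 1)
    ]
    return {k: int(p) for k, p in zip(keys, perm)}


def design_from_frame(frame: pd.DataFrame) -> StudyDesign:
    """Infer the study design from observed data."""
    dfs = sorted({parse_dilution(v) for v in frame["target_df"].unique()}, reverse=True)
    tubes = int(frame.groupby("target_df")["tube_id"].nunique().max())
    obs = int(frame.groupby(["target_df", "tube_id"])["obs_index"].count().max())
    return StudyDesign(tuple(dfs), tubes, obs)


def validate_dataset(
    ds: DilutionSeriesDataset,
    tolerance_pp: float = DEFAULT_VIABILITY_TOLERANCE_PP,
) -> ValidationReport:
    """Check type invariants; violations are reported, never silently fixed.

    Checks per observation: non-negative concentrations, viable <= total,
    viability within [0, 100], and consistency of the reported % viability
    with viable/total within ``tolerance_pp`` percentage points (instruments
    round their displayed viability, hence the tolerance).  A zero total
    concentration with non-zero reported viability is flagged as
    inconsistent.  Also checks that every design dilution appears in the
    data.
    """
    rep = ValidationReport()
    f = ds.frame
    for idx, r in f.iterrows():
        total, viable, pct = float(r["total_conc"]), float(r["viable_conc"]), float(r["pct_viability"])
        if total < 0:
            rep.add(idx, "total_conc", f"negative concentration {total}")
        if viable < 0:
            rep.add(idx, "viable_conc", f"negative concentration {viable}")
        if viable > total:
            rep.add(idx, "viable_conc", f"viable {viable} exceeds total {total}")
        if not 0 <= pct <= 100:
            rep.add(idx, "pct_viability", f"viability {pct} outside [0, 100]")
        if total > 0:
            implied = 100.0 * viable / total
            if abs(pct - implied) > tolerance_pp:
                rep.add(
                    idx,
                    "pct_viability",
                    f"reported {pct:.3f}% inconsistent with viable/total = {implied:.3f}% "
                    f"(tolerance {tolerance_pp} pp)",
                )
        elif pct != 0:
            rep.add(idx, "pct_viability", f"viability {pct}% reported with zero total concentration")
    seen = {parse_dilution(v) for v in f["target_df"].unique()}
    for frac in ds.design.target_dilution_fractions:
        if frac not in seen:
            rep.add(None, "target_df", f"design dilution {frac} has no observations")
    return rep


@dataclass
class CountsTable:
    """Result of loading a counts file: datasets keyed by group, plus report."""

    datasets: dict[tuple[str, str], DilutionSeriesDataset]
    report: ValidationReport
    frame: pd.DataFrame

    def single(self) -> DilutionSeriesDataset:
        if len(self.datasets) != 1:
            raise DesignError(f"expected one (preparation, method) group, found {len(self.datasets)}")
        return next(iter(self.datasets.values()))


def _coerce_frame(
    raw: pd.DataFrame,
    report: ValidationReport,
    flag_policy: str,
) -> pd.DataFrame:
    """Map external column names, parse dilutions and numerics row by row."""
    missing = [c for c in REQUIRED_CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    frame = raw.rename(columns=CSV_COLUMNS).copy()

    bad_rows: list[int] = []
    dfs = []
    for idx, v in frame["target_df"].items():
        try:
            dfs.append(float(parse_dilution(v)))
        except (ValueError, ZeroDivisionError, DesignError) as exc:
            report.add(idx, "target_df", f"unparseable dilution {v!r}: {exc}")
            bad_rows.append(idx)
            dfs.append(np.nan)
    frame["target_df"] = dfs

    for col in _NUMERIC_FIELDS:
        # parse with float() for exact (shortest-repr) round trips; pandas'
        # to_numeric can be one ulp off
        vals = []
        for idx, v in frame[col].items():
            if v is None or (isinstance(v, float) and np.isnan(v)):
                vals.append(np.nan)
                continue
            try:
                vals.append(float(v))
            except (TypeError, ValueError):
                report.add(idx, col, f"non-numeric value {v!r} (line {idx + 2})")
                bad_rows.append(idx)
                vals.append(np.nan)
        frame[col] = vals

    frame["obs_index"] = pd.to_numeric(frame["obs_index"], errors="coerce").astype("Int64")
    if "blinded_id" in frame.columns:
        frame["blinded_id"] = pd.to_numeric(frame["blinded_id"], errors="coerce").astype("Int64")
    frame["tube_id"] = frame["tube_id"].astype(str)

    if bad_rows:
        if flag_policy == "raise":
            raise SchemaError(f"{len(set(bad_rows))} malformed row(s); first: {report.violations[0]}")
        frame = frame.drop(index=sorted(set(bad_rows)))
    return frame


def _build_table(
    frame: pd.DataFrame,
    response_choice: str,
    tolerance_pp: float,
    flag_policy: str,
    report: ValidationReport,
) -> CountsTable:
    if frame.empty:
        raise SchemaError("no observation rows found")
    datasets: dict[tuple[str, str], DilutionSeriesDataset] = {}
    for (prep, meth), sub in frame.groupby(["preparation", "method"], sort=True):
        ds = DilutionSeriesDataset(
            design=design_from_frame(sub),
            frame=sub.reset_index(drop=True),
            response_choice=response_choice,
        )
        sub_rep = validate_dataset(ds, tolerance_pp=tolerance_pp)
        if not sub_rep.ok and flag_policy == "raise":
            raise SchemaError(f"validation failed for ({prep}, {meth}): {sub_rep.violations[0]}")
        report.extend(sub_rep)
        datasets[(str(prep), str(meth))] = ds
    return CountsTable(datasets=datasets, report=report, frame=frame)


def read_counts_csv(
    path: str | Path,
    schema_options: Mapping[str, str] | None = None,
    response_choice: str = "viable_conc",
    tolerance_pp: float = DEFAULT_VIABILITY_TOLERANCE_PP,
    flag_policy: str = "warn",
) -> CountsTable:
    """Read long-format counts (one observation per row) from CSV.

    ``schema_options`` maps the file's column names onto the documented
    schema (``{"my_conc_col": "viable_conc_cells_per_ml", ...}``).  Malformed
    rows are collected into the validation report and dropped under
    ``flag_policy="warn"``, or raise a :class:`SchemaError` under
    ``"raise"``.  Row order is preserved within each group.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty file: {path}") from None
    if schema_options:
        raw = raw.rename(columns=dict(schema_options))
    report = ValidationReport()
    frame = _coerce_frame(raw, report, flag_policy)
    return _build_table(frame, response_choice, tolerance_pp, flag_policy, report)


def read_counts_excel(
    path: str | Path,
    response_choice: str = "viable_conc",
    tolerance_pp: float = DEFAULT_VIABILITY_TOLERANCE_PP,
    flag_policy: str = "warn",
) -> CountsTable:
    """Thin Excel adapter: one sheet per (preparation x method), same columns.

    All sheets are normalised into the one long-format representation used
    by :func:`read_counts_csv`.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    sheets = pd.read_excel(path, sheet_name=None, dtype=str)
    if not sheets:
        raise SchemaError(f"no sheets in workbook: {path}")
    report = ValidationReport()
    parts = []
    for name, raw in sheets.items():
        if raw.empty:
            continue
        parts.append(_coerce_frame(raw, report, flag_policy))
    if not parts:
        raise SchemaError(f"all sheets empty in workbook: {path}")
    frame = pd.concat(parts, ignore_index=True)
    return _build_table(frame, response_choice, tolerance_pp, flag_policy, report)


def write_counts_csv(
    data: CountsTable | DilutionSeriesDataset | Sequence[DilutionSeriesDataset],
    path: str | Path,
) -> None:
    """Write observations back to the documented CSV schema."""
    if isinstance(data, CountsTable):
        frames = [ds.frame for ds in data.datasets.values()]
    elif isinstance(data, DilutionSeriesDataset):
        frames = [data.frame]
    else:
        frames = [ds.frame for ds in data]
    out = pd.concat(frames, ignore_index=True)
    inverse = {v: k for k, v in CSV_COLUMNS.items()}
    out = out.rename(columns=inverse)
    cols = [c for c in CSV_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)
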