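"""Data model, CSV/Excel round trips, validation, blinded-ID assignment."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcountqc import (
    DesignError,
    SchemaError,
    StudyDesign,
    assign_blinded_ids,
    read_counts_csv,
    validate_dataset,
    write_counts_csv,
)
from cellcountqc.study_data import parse_dilution, read_counts_excel

from conftest import make_dataset


class TestStudyDesign:
    def test_default_matches_recommended_layout(self, design):
        assert design.fractions_float == (1.0, 0.5, 1 / 3, 0.25, 0.2)
        assert design.n_tubes_total == 15
        assert design.n_observations_total == 45

    @pytest.mark.parametrize(
        "fractions",
        [
            (Fraction(1, 2), Fraction(1)),  # not decreasing
            (Fraction(1), Fraction(1)),  # duplicate
            (Fraction(3, 2),),  # > 1
        ],
    )
    def test_invalid_fraction_sets_rejected(self, fractions):
        with pytest.raises(DesignError):
            StudyDesign(fractions)

    def test_counts_must_be_positive(self):
        with pytest.raises(DesignError):
            StudyDesign(tubes_per_dilution=0)

    @pytest.mark.parametrize(
        "raw,expected",
        [("1:3", Fraction(1, 3)), ("1/4", Fraction(1, 4)), ("0.5", Fraction(1, 2)), (0.3333333333333333, Fraction(1, 3))],
    )
    def test_parse_dilution_ratio_forms(self, raw, expected):
        assert parse_dilution(raw) == expected


class TestBlindedIds:
    def test_permutation_of_1_to_15_and_deterministic(self, design):
        ids = assign_blinded_ids(design, seed=7)
        assert sorted(ids.values()) == list(range(1, 16))
        assert ids == assign_blinded_ids(design, seed=7)

    def test_single_tube_design(self):
        d = StudyDesign((Fraction(1),), 1, 1)
        assert assign_blinded_ids(d, seed=0) == {(Fraction(1), 1): 1}

    def test_different_seeds_differ(self, design):
        a = assign_blinded_ids(design, seed=1)
        b = assign_blinded_ids(design, seed=2)
        assert sorted(a.values()) == sorted(b.values()) == list(range(1, 16))
        assert a != b

    @settings(derandomize=True, max_examples=40)
    @given(n_df=st.integers(1, 40), n_tube=st.integers(1, 25), seed=st.integers(0, 2**31 - 1))
    def test_bijection_property(self, n_df, n_tube, seed):
        fracs = tuple(Fraction(1, k) for k in range(1, n_df + 1))
        d = StudyDesign(fracs, n_tube, 1)
        ids = assign_blinded_ids(d, seed=seed)
        assert sorted(ids.values()) == list(range(1, n_df * n_tube + 1))


class TestCsvIO:
    def test_round_trip_bit_exact(self, tmp_path, noisy_dataset):
        p = tmp_path / "counts.csv"
        write_counts_csv(noisy_dataset, p)
        table = read_counts_csv(p)
        ds = table.single()
        assert len(ds.frame) == 45
        assert len(ds.distinct_dfs()) == 5
        for col in ("target_df", "total_conc", "viable_conc", "pct_viability"):
            np.testing.assert_array_equal(
                ds.frame[col].to_numpy(), noisy_dataset.frame[col].to_numpy(), err_msg=col
            )
        # write -> read -> write reproduces the file byte for byte
        p2 = tmp_path / "again.csv"
        write_counts_csv(ds, p2)
        assert p.read_text() == p2.read_text()

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("preparation,method,target_df\n" "pbmc,m1,1\n")
        with pytest.raises(SchemaError, match="viable_conc_cells_per_ml"):
            read_counts_csv(p)

    def test_empty_file_is_schema_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(SchemaError):
            read_counts_csv(p)

    def test_non_numeric_row_reported_with_line(self, tmp_path, noisy_dataset):
        p = tmp_path / "counts.csv"
        write_counts_csv(noisy_dataset, p)
        lines = p.read_text().splitlines()
        parts = lines[3].split(",")
        parts[-2] = "oops"
        lines[3] = ",".join(parts)
        p.write_text("\n".join(lines) + "\n")
        table = read_counts_csv(p, flag_policy="warn")
        assert any("non-numeric" in v.message for v in table.report.violations)
        assert len(table.single().frame) == 44  # bad row dropped under warn
        with pytest.raises(SchemaError):
            read_counts_csv(p, flag_policy="raise")

    def test_viable_above_total_flagged_but_loaded(self, tmp_path, noisy_dataset):
        frame = noisy_dataset.frame.copy()
        frame.loc[0, "viable_conc"] = frame.loc[0, "total_conc"] * 2
        ds = noisy_dataset
        ds.frame = frame
        p = tmp_path / "counts.csv"
        write_counts_csv(ds, p)
        table = read_counts_csv(p, flag_policy="warn")
        assert any("exceeds total" in v.message for v in table.report.violations)
        assert len(table.single().frame) == 45

    def test_schema_options_rename(self, tmp_path, noisy_dataset):
        p = tmp_path / "counts.csv"
        write_counts_csv(noisy_dataset, p)
        txt = p.read_text().replace("viable_conc_cells_per_ml", "live_cells")
        p.write_text(txt)
        table = read_counts_csv(p, schema_options={"live_cells": "viable_conc_cells_per_ml"})
        assert table.single().n_obs == 45


class TestExcelAdapter:
    def test_excel_sheets_normalise_to_long_format(self, tmp_path, noisy_dataset):
        from cellcountqc.synthetic_data import SyntheticConfig, simulate_dilution_series

        other = simulate_dilution_series(SyntheticConfig(seed=5, method="method_2")).dataset
        inverse = {
            "total_conc": "total_conc_cells_per_ml",
            "viable_conc": "viable_conc_cells_per_ml",
        }
        p = tmp_path / "counts.xlsx"
        with pd.ExcelWriter(p) as xl:
            noisy_dataset.frame.rename(columns=inverse).to_excel(xl, sheet_name="pbmc_method_1", index=False)
            other.frame.rename(columns=inverse).to_excel(xl, sheet_name="pbmc_method_2", index=False)
        table = read_counts_excel(p)
        assert set(table.datasets) == {("pbmc", "method_1"), ("pbmc", "method_2")}
        assert all(ds.n_obs == 45 for ds in table.datasets.values())


class TestValidation:
    def test_consistent_dataset_has_empty_report(self, noisy_dataset):
        assert validate_dataset(noisy_dataset).ok

    def test_viability_inconsistency_flagged(self):
        ds = make_dataset({1.0: [[100.0] * 2], 0.5: [[50.0] * 2]}, viability=95.0)
        ds.frame.loc[0, "viable_conc"] = ds.frame.loc[0, "total_conc"] * 0.80  # implies 80%
        report = validate_dataset(ds)
        assert len([v for v in report.violations if "inconsistent" in v.message]) == 1

    def test_zero_total_with_nonzero_viability_flagged(self):
        ds = make_dataset({1.0: [[100.0] * 2], 0.5: [[50.0] * 2]})
        ds.frame.loc[0, ["total_conc", "viable_conc"]] = 0.0
        ds.frame.loc[0, "pct_viability"] = 50.0
        report = validate_dataset(ds)
        assert any("zero total" in v.message for v in report.violations)

    def test_rounded_viability_within_tolerance_passes(self):
        ds = make_dataset({1.0: [[100.0] * 2], 0.5: [[50.0] * 2]}, viability=90.0)
        ds.frame["pct_viability"] = 90.4  # 0.4 pp off, inside the 0.5 pp default
        assert validate_dataset(ds).ok
        assert not validate_dataset(ds, tolerance_pp=0.1).ok
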