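"""Cohort reading, validation, discretization, and marginal summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readmit_bn import study, synthetic
from readmit_bn.cohort import (
    Cohort,
    CohortSchema,
    CohortValidationError,
    DiscretizationRule,
    VariableSpec,
    discretize_cohort,
    marginal_summary,
    read_cohort_table,
    write_cohort,
)

from conftest import make_cohort


class TestVariableSpec:
    def test_needs_two_distinct_levels(self):
        with pytest.raises(CohortValidationError):
            VariableSpec("X", ("only",))
        with pytest.raises(CohortValidationError):
            VariableSpec("X", ("a", "a"))

    def test_index_rejects_unknown_label(self):
        spec = VariableSpec("X", ("a", "b"))
        assert spec.index("b") == 1
        with pytest.raises(CohortValidationError, match="maybe"):
            spec.index("maybe")


class TestDiscretization:
    @pytest.mark.parametrize(
        "column,value,expected",
        [
            ("BMI", 25.0, "≥25 kg/m2"),  # boundary goes to the upper class
            ("BMI", 24.999, "<25 kg/m2"),
            ("ALB", 3.5, "≤3.5 g/dL"),  # boundary goes to the lower class
            ("ALB", 3.51, ">3.5 g/dL"),
            ("HRA", 10, "≤10"),
            ("HRA", 11, "11–22"),
            ("HRA", 22, "11–22"),
            ("HRA", 23, ">22"),
        ],
    )
    def test_clinical_cut_points(self, column, value, expected):
        rule = next(r for r in study.discretization_rules() if r.source == column)
        assert rule.apply(np.array([value]))[0] == expected

    def test_cut_points_must_increase(self):
        with pytest.raises(CohortValidationError):
            DiscretizationRule("x", (2.0, 1.0), VariableSpec("X", ("a", "b", "c")))

    def test_level_count_must_match_intervals(self):
        with pytest.raises(CohortValidationError):
            DiscretizationRule("x", (1.0,), VariableSpec("X", ("a", "b", "c")))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=0, max_value=60, allow_nan=False))
    def test_every_value_lands_in_exactly_one_interval(self, value):
        rule = next(r for r in study.discretization_rules() if r.source == "HRA")
        label = rule.apply(np.array([value]))[0]
        assert label in rule.output.levels
        # label agrees with the cut points
        if value <= 10:
            assert label == "≤10"
        elif value <= 22:
            assert label == "11–22"
        else:
            assert label == ">22"

    def test_rebinning_categorical_column_is_rejected(self):
        cohort = make_cohort({"BMI": ["<25 kg/m2", "≥25 kg/m2"]}, specs={"BMI": study.BMI})
        rule = study.discretization_rules()[0]
        with pytest.raises(CohortValidationError, match="already categorical"):
            discretize_cohort(cohort, [rule])

    def test_raw_to_categorical_pipeline(self):
        raw = Cohort(
            [study.CANCER, study.MTX, study.NUTR, study.BTCP, study.RADIO],
            pd.DataFrame(
                {
                    "CANCER": ["Colon-rectum", "Colon-rectum"],
                    "MTX": ["No", "Yes"],
                    "NUTR": ["No", "No"],
                    "BTcP": ["Predictable", "Not predictable"],
                    "RADIO": ["No", "Yes"],
                    "BMI": [25.0, 21.3],
                    "ALB": [3.5, 4.2],
                    "HRA": [10.0, 23.0],
                }
            ),
            numeric_columns=("BMI", "ALB", "HRA"),
        )
        out = discretize_cohort(raw, study.discretization_rules())
        table = out.select(study.VARIABLE_NAMES).data
        assert list(table["BMI"]) == ["≥25 kg/m2", "<25 kg/m2"]
        assert list(table["ALB"]) == ["≤3.5 g/dL", ">3.5 g/dL"]
        assert list(table["HRA"]) == ["≤10", ">22"]


class TestReadWrite:
    def test_synthetic_csv_round_trip(self, ground_truth, tmp_path):
        cohort = synthetic.sample_cohort(ground_truth, 96, 7)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort_table(path, study.analysis_schema())
        assert back.n == 96
        assert back.n_dropped == 0
        # schema order may differ from sampling order; content must not
        pd.testing.assert_frame_equal(
            back.data[list(cohort.names)], cohort.data
        )

    def test_missing_cell_dropped_and_counted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "A,B\nyes,left\n,right\nno,left\n", encoding="utf-8"
        )
        schema = CohortSchema(
            (VariableSpec("A", ("yes", "no")), VariableSpec("B", ("left", "right")))
        )
        cohort = read_cohort_table(path, schema)
        assert cohort.n == 2
        assert cohort.n_dropped == 1

    def test_unknown_label_names_row_and_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("RADIO\nNo\nmaybe\n", encoding="utf-8")
        schema = CohortSchema((study.RADIO,))
        with pytest.raises(CohortValidationError, match=r"row 1, column 'RADIO'"):
            read_cohort_table(path, schema)

    def test_header_mismatch_is_an_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("X\n1\n", encoding="utf-8")
        with pytest.raises(CohortValidationError, match="RADIO"):
            read_cohort_table(path, CohortSchema((study.RADIO,)))

    def test_unreadable_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_cohort_table(tmp_path / "missing.csv", study.analysis_schema())


class TestMarginalSummary:
    def test_counts_sum_to_n_per_variable(self, ground_truth):
        cohort = synthetic.sample_cohort(ground_truth, 500, 3)
        summary = marginal_summary(cohort)
        per_var = summary.groupby("variable")["count"].sum()
        assert (per_var == cohort.n).all()
        props = summary.groupby("variable")["proportion"].sum()
        assert np.allclose(props, 1.0)

    def test_single_record_has_unit_proportions(self):
        cohort = make_cohort(
            {"A": ["yes"]}, specs={"A": VariableSpec("A", ("yes", "no"))}
        )
        summary = marginal_summary(cohort)
        observed = summary[summary["count"] > 0]
        assert (observed["proportion"] == 1.0).all()

    def test_empty_cohort_gives_empty_summary(self, ground_truth):
        empty = synthetic.sample_cohort(ground_truth, 0, 0)
        assert marginal_summary(empty).empty

    def test_sampled_metastasis_rate_near_published(self, ground_truth):
        cohort = synthetic.sample_cohort(ground_truth, 10_000, 11)
        prop = cohort.level_counts("MTX")["Yes"] / cohort.n
        assert abs(prop - 0.16) < 0.02  # 3 binomial sigma at this n
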