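"""Unit and property tests for the failure-aware bookkeeping layer."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methodfail.core import (
    FailureReason,
    HandlingKind,
    HandlingStrategy,
    Measure,
    MethodOutcome,
    Orientation,
    PerformanceSpec,
    PipelineSpec,
    ResultsTable,
    UNCONDITIONAL_CAVEAT,
    aggregate_complete_case,
    aggregate_conditional,
    aggregate_with_handling,
    apply_pipeline,
    evaluate_methods,
    failure_proportions,
    impute_outcomes,
    rank_methods,
    slimmed_report,
)

from conftest import make_table

BIAS = PerformanceSpec(Measure.BIAS_RAW, Orientation.LOWER_IS_BETTER)
MEAN = PerformanceSpec(Measure.MEAN_VALUE, Orientation.HIGHER_IS_BETTER)
COV = PerformanceSpec(Measure.COVERAGE, Orientation.HIGHER_IS_BETTER, worst_value=0.0)


class TestMethodOutcome:
    def test_defined_iff_reason_none(self):
        ok = MethodOutcome(1.0)
        assert not ok.failed
        bad = MethodOutcome(None, FailureReason.NONCONVERGENCE, "max iter")
        assert bad.failed and bad.message == "max iter"
        with pytest.raises(ValueError):
            MethodOutcome(1.0, FailureReason.ERROR)
        with pytest.raises(ValueError):
            MethodOutcome(None)

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            MethodOutcome(float("inf"))


class TestEvaluateMethods:
    def test_capture_semantics(self):
        def raises_on_two(x):
            if x == 2:
                raise RuntimeError("boom")
            return float(x)

        table = evaluate_methods(
            {"ok": lambda x: 1.0,
             "raises": raises_on_two,
             "nonfinite": lambda x: float("nan") if x == 3 else 0.5},
            datasets=[1, 2, 3],
        )
        assert failure_proportions(table)["ok"] == 0.0
        out = table.outcome(2, "raises")
        assert out.failure_reason is FailureReason.ERROR
        assert "boom" in out.message
        assert (table.outcome(3, "nonfinite").failure_reason
                is FailureReason.INVALID_VALUE)
        # grid complete despite failures
        assert table.values.shape == (3, 3)

    def test_malformed_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_methods({}, [1])
        with pytest.raises(ValueError):
            evaluate_methods({"m": float}, [])


class TestFailureProportions:
    def test_printed_fixture(self, overview_table):
        props = failure_proportions(overview_table)
        assert props.tolist() == [0.25, 0.0, 0.25]

    def test_paper_scale_failure_count(self):
        vals = [1.0] * 700 + [np.nan] * 300
        table = make_table({"n": vals})
        assert failure_proportions(table)["n"] == pytest.approx(0.30)


class TestAggregation:
    def test_conditional_bias_on_printed_fixture(self, overview_table):
        agg = aggregate_conditional(overview_table, BIAS)
        assert agg.at["Method 2", "value"] == pytest.approx(0.0725)
        assert round(agg.at["Method 2", "value"], 2) == 0.07
        assert agg.at["Method 2", "n_used"] == 4
        assert agg.at["Method 1", "n_used"] == 3

    def test_method_failing_everywhere_is_undefined(self):
        table = make_table({"a": [np.nan, np.nan], "b": [1.0, 3.0]})
        agg = aggregate_conditional(table, MEAN)
        assert math.isnan(agg.at["a", "value"]) and agg.at["a", "n_used"] == 0

    def test_no_failures_conditional_equals_complete_case(self):
        table = make_table({"a": [1.0, 2.0], "b": [3.0, 4.0]}, truth=[1.5, 1.5])
        for spec in (MEAN, BIAS):
            pd.testing.assert_frame_equal(
                aggregate_conditional(table, spec),
                aggregate_complete_case(table, spec))

    def test_complete_case_shares_the_retained_subset(self):
        table = make_table({"a": [1.0, 2.0, np.nan], "b": [3.0, 4.0, 5.0]})
        agg = aggregate_complete_case(table, MEAN)
        assert set(agg["n_used"]) == {2}
        assert agg.at["b", "value"] == pytest.approx(3.5)

    def test_empty_intersection_leaves_all_undefined(self):
        # 4 methods each failing on a distinct one of 4 datasets
        vals = np.ones((4, 4))
        np.fill_diagonal(vals, np.nan)
        table = make_table(pd.DataFrame(vals, columns=list("abcd")))
        agg = aggregate_complete_case(table, MEAN)
        assert agg["value"].isna().all()
        assert set(agg["n_used"]) == {0}

    def test_bias_without_truth_is_a_configuration_error(self):
        table = make_table({"a": [1.0]})
        with pytest.raises(ValueError, match="truth"):
            aggregate_conditional(table, BIAS)

    def test_conditional_invariant_to_other_methods_failures(self):
        base = make_table({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
        more = make_table({"a": [1.0, 2.0, 3.0], "b": [np.nan, 1.0, np.nan]})
        assert (aggregate_conditional(base, MEAN).at["a", "value"]
                == aggregate_conditional(more, MEAN).at["a", "value"])


class TestImputation:
    def test_no_failure_table_unchanged_under_every_strategy(self):
        table = make_table({"a": [0.5, 0.6], "b": [0.7, 0.8]})
        for kind in (HandlingKind.IMPUTE_WORST,
                     HandlingKind.IMPUTE_MEAN_OTHER_METHODS,
                     HandlingKind.IMPUTE_METHOD_MEAN,
                     HandlingKind.IMPUTE_HYBRID_THRESHOLD):
            out = impute_outcomes(table, HandlingStrategy(kind), COV)
            pd.testing.assert_frame_equal(out.values, table.values)

    def test_impute_worst_coverage_identity(self):
        # 1000 iterations, 300 failures, 378 covering among the 700 defined
        vals = [1.0] * 378 + [0.0] * 322 + [np.nan] * 300
        table = make_table({"n": vals})
        out = impute_outcomes(table, HandlingStrategy(HandlingKind.IMPUTE_WORST), COV)
        assert not out.failure_mask.any().any()
        assert out.values["n"].mean() == pytest.approx(0.378)
        # original untouched
        assert table.failure_mask["n"].sum() == 300

    def test_impute_mean_other_methods_is_the_row_mean(self):
        table = make_table({"a": [np.nan, 2.0], "b": [4.0, 6.0], "c": [8.0, 2.0]})
        out = impute_outcomes(
            table, HandlingStrategy(HandlingKind.IMPUTE_MEAN_OTHER_METHODS), MEAN)
        assert out.values.at[0, "a"] == pytest.approx(6.0)

    def test_all_methods_failing_row_flagged_unresolvable(self):
        table = make_table({"a": [np.nan, 1.0], "b": [np.nan, 2.0]})
        with pytest.warns(UserWarning, match="cannot resolve"):
            out = impute_outcomes(
                table, HandlingStrategy(HandlingKind.IMPUTE_MEAN_OTHER_METHODS), MEAN)
        assert out.failure_mask.loc[0].all()

    def test_hybrid_threshold_switches_on_failure_proportion(self):
        # f = 0.25 > 0.20: worst value fills every imputed cell
        col = [np.nan, 1.0, 1.0, 1.0]
        table = make_table({"m": col})
        out = impute_outcomes(
            table, HandlingStrategy(HandlingKind.IMPUTE_HYBRID_THRESHOLD, 0.20), COV)
        assert out.values.at[0, "m"] == 0.0
        # f = 0.25 <= 0.30: the method's own mean fills instead
        out2 = impute_outcomes(
            table, HandlingStrategy(HandlingKind.IMPUTE_HYBRID_THRESHOLD, 0.30), COV)
        assert out2.values.at[0, "m"] == pytest.approx(1.0)

    def test_worst_value_required(self):
        table = make_table({"m": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="worst_value"):
            impute_outcomes(table, HandlingStrategy(HandlingKind.IMPUTE_WORST), MEAN)

    def test_weighted_is_aggregate_level(self):
        table = make_table({"m": [np.nan, 1.0]})
        with pytest.raises(ValueError, match="aggregate"):
            impute_outcomes(table, HandlingStrategy(HandlingKind.IMPUTE_WEIGHTED), COV)

    @pytest.mark.parametrize("n_fail,expected", [(0, 1.0), (4, 0.0)])
    def test_weighted_endpoints(self, n_fail, expected):
        # f = 0 -> conditional aggregate; f = 1 -> worst value
        col = [np.nan] * n_fail + [1.0] * (4 - n_fail)
        table = make_table({"m": col})
        agg = aggregate_with_handling(
            table, COV, HandlingStrategy(HandlingKind.IMPUTE_WEIGHTED))
        assert agg.at["m", "value"] == pytest.approx(expected)

    def test_weighted_interpolates(self):
        col = [np.nan, 1.0, 1.0, 0.0]  # f = 0.25, conditional = 2/3
        table = make_table({"m": col})
        agg = aggregate_with_handling(
            table, COV, HandlingStrategy(HandlingKind.IMPUTE_WEIGHTED))
        assert agg.at["m", "value"] == pytest.approx(0.75 * (2 / 3))


class TestPipelines:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PipelineSpec(("a", "b", "c"), max_fallbacks=1)
        with pytest.raises(ValueError):
            PipelineSpec(("a", "a"))

    def test_primary_never_failing_passes_through(self):
        table = make_table({"a": [1.0, 2.0], "b": [9.0, 9.0]})
        col = apply_pipeline(PipelineSpec(("a", "b")), table)
        assert col.values.tolist() == [1.0, 2.0]
        assert col.chosen_step.tolist() == [0, 0]

    def test_fallback_fills_primary_failures(self):
        table = make_table({"a": [1.0, np.nan], "b": [9.0, 7.0]})
        col = apply_pipeline(PipelineSpec(("a", "b")), table)
        assert col.values.tolist() == [1.0, 7.0]
        assert col.chosen_step.tolist() == [0, 1]

    def test_failure_reason_comes_from_primary(self):
        table = ResultsTable(
            pd.DataFrame({"a": [np.nan], "b": [np.nan]}),
            pd.DataFrame({"a": [FailureReason.NONCONVERGENCE.value],
                          "b": [FailureReason.TIMEOUT.value]}))
        col = apply_pipeline(PipelineSpec(("a", "b")), table)
        assert col.reasons.iloc[0] == FailureReason.NONCONVERGENCE.value

    def test_unknown_step_is_a_configuration_error(self):
        table = make_table({"a": [1.0]})
        with pytest.raises(KeyError):
            apply_pipeline(PipelineSpec(("a", "zz")), table)

    def test_failure_set_is_intersection_exhaustive(self):
        """All 2^12 failure patterns of a 4-dataset, 3-step toy: the
        pipeline fails exactly where every step fails, and its failure
        proportion never exceeds the primary's."""
        steps = ("a", "b", "c")
        spec = PipelineSpec(steps)
        for pattern in itertools.product([0, 1], repeat=12):
            mask = np.array(pattern, dtype=bool).reshape(4, 3)
            vals = np.arange(12, dtype=float).reshape(4, 3)
            vals[mask] = np.nan
            table = make_table(pd.DataFrame(vals, columns=list(steps)))
            col = apply_pipeline(spec, table)
            expected = mask.all(axis=1)
            assert (col.failure_mask.to_numpy() == expected).all()
            assert col.failure_mask.mean() <= mask[:, 0].mean()


class TestRanking:
    def test_lower_better(self):
        ranks = rank_methods(pd.Series({"x": 0.1, "y": 0.3, "z": 0.2}))
        assert ranks.tolist() == [1.0, 3.0, 2.0]

    def test_ties_average(self):
        ranks = rank_methods(pd.Series({"x": 0.1, "y": 0.1, "z": 0.2}))
        assert ranks.tolist() == [1.5, 1.5, 3.0]

    def test_bias_ranks_on_absolute_value(self):
        ranks = rank_methods(pd.Series({"x": -0.05, "y": 0.2}), absolute=True)
        assert ranks.tolist() == [1.0, 2.0]

    def test_undefined_values_refused(self):
        with pytest.raises(ValueError, match="resolve"):
            rank_methods(pd.Series({"x": np.nan, "y": 1.0}))

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=12),
           st.sampled_from(list(Orientation)))
    def test_rank_sum_is_permutation_invariant(self, values, orientation):
        m = len(values)
        ranks = rank_methods(pd.Series(values, index=range(m)), orientation)
        assert ranks.sum() == pytest.approx(m * (m + 1) / 2)


class TestSlimReport:
    def test_three_parts_always_together(self, overview_table):
        rep = slimmed_report(overview_table, BIAS)
        assert rep.failure_proportions.tolist() == [0.25, 0.0, 0.25]
        assert rep.caveat == UNCONDITIONAL_CAVEAT
        assert rep.conditional.at["Method 2", "value"] == pytest.approx(0.0725)
        # complete case drops repetitions 3 and 4 for every method
        assert set(rep.complete_case["n_used"]) == {2}

    def test_no_failure_parts_coincide(self):
        table = make_table({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        rep = slimmed_report(table, MEAN)
        pd.testing.assert_frame_equal(rep.conditional, rep.complete_case)
        assert (rep.failure_proportions == 0).all()
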