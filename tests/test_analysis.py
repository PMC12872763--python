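import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stipemorph.analysis import (
    ConfusionCounts,
    EvalPairs,
    GradingConfig,
    SplitSpec,
    eval_metrics,
    grade_length,
    precision_recall,
    split_dataset,
    summary_stats,
)


class TestGrading:
    @pytest.mark.parametrize(
        "length, label",
        [
            (11.56, "extremely_short"),
            (11.57, "short"),
            (27.69, "short"),
            (27.70, "middle"),
            (43.83, "middle"),
            (59.96, "long"),
            (60.0, "extremely_long"),
            (0.0, "extremely_short"),
        ],
    )
    def test_boundary_values(self, length, label):
        assert grade_length(length) == label

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            grade_length(-1.0)

    @given(st.floats(0.0, 500.0, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_grades_partition_nonnegative_lengths(self, length):
        """Every non-negative length receives exactly one of the 5 labels."""
        assert grade_length(length) in GradingConfig().labels

    def test_bounds_must_increase(self):
        with pytest.raises(ValueError):
            GradingConfig(bounds_mm=(10.0, 5.0, 20.0, 30.0))


class TestSplit:
    @pytest.mark.parametrize(
        "n, expected", [(985, (689, 197, 99)), (10, (7, 2, 1)), (0, (0, 0, 0))]
    )
    def test_seven_two_one(self, n, expected):
        assert split_dataset(n) == expected

    @given(st.integers(0, 100_000))
    @settings(deadline=None, derandomize=True)
    def test_counts_sum_to_n(self, n):
        train, test, val = split_dataset(n)
        assert train + test + val == n
        assert min(train, test, val) >= 0

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(0.7, 0.2, 0.2)


class TestPrecisionRecall:
    def test_hand_case(self):
        assert precision_recall(ConfusionCounts(90, 10, 30)) == (0.9, 0.75)

    def test_perfect_detector(self):
        assert precision_recall(ConfusionCounts(5, 0, 0)) == (1.0, 1.0)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            precision_recall(ConfusionCounts(0, 0, 5))


class TestEvalMetrics:
    def test_perfect_fit(self):
        assert eval_metrics(EvalPairs((1, 2, 3), (1, 2, 3))) == (1.0, 0.0, 0.0, 0.0)

    def test_unit_shift(self):
        r2, rmse, mse, mae = eval_metrics(EvalPairs((2, 3, 4, 5), (1, 2, 3, 4)))
        assert r2 == pytest.approx(0.2)
        assert (rmse, mse, mae) == (1.0, 1.0, 1.0)

    def test_constant_truth_r2_undefined(self):
        with pytest.raises(ZeroDivisionError):
            eval_metrics(EvalPairs((1.0, 2.0), (3.0, 3.0)))

    @given(
        st.lists(
            st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
            min_size=2,
            max_size=30,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_metric_identities(self, pairs):
        yhat = tuple(p[0] for p in pairs)
        y = tuple(p[1] for p in pairs)
        try:
            r2, rmse, mse, mae = eval_metrics(EvalPairs(yhat, y))
        except ZeroDivisionError:
            return
        assert rmse**2 == pytest.approx(mse, rel=1e-9, abs=1e-12)
        assert mae <= rmse + 1e-9
        if yhat == y:
            assert r2 == 1.0


class TestSummaryStats:
    def test_hand_case(self):
        mean, vmax, vmin, std, median = summary_stats([1, 2, 3, 4, 5])
        assert (mean, vmax, vmin, median) == (3, 5, 1, 3)
        assert std == pytest.approx(math.sqrt(2.5))

    def test_constant_values(self):
        assert summary_stats([2, 2, 2]) == (2, 2, 2, 0, 2)

    def test_single_value_std_undefined(self):
        with pytest.raises(ValueError):
            summary_stats([7.0])
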