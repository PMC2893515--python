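"""Closed-form classical-test-theory statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from examsem import (
    CttError,
    DegenerateCohortError,
    ItemResponseMatrix,
    MissingDataError,
    ProphecyQuery,
    RangeRestrictionQuery,
    cronbach_alpha,
    items_needed_for_target,
    reliability_report,
    restriction_of_range_correlation,
    score_summary,
    sem_first_principles,
    sem_from_reliability,
    spearman_brown_prophecy,
)
from conftest import random_matrix


class TestCronbachAlpha:
    def test_hand_computed_example(self, small_matrix):
        # Σ sample item variances 0.8333, sample total variance 1.6667
        assert cronbach_alpha(small_matrix) == pytest.approx(0.75, abs=1e-12)

    def test_identical_items_give_one(self):
        m = ItemResponseMatrix.from_array([[1, 1], [1, 1], [0, 0], [1, 1]])
        assert cronbach_alpha(m) == pytest.approx(1.0, abs=1e-12)

    def test_zero_interitem_covariance_gives_zero(self):
        m = ItemResponseMatrix.from_array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert cronbach_alpha(m) == pytest.approx(0.0, abs=1e-12)

    def test_negative_alpha_returned_and_flagged(self):
        # perfectly anti-correlated items: alpha far below zero
        m = ItemResponseMatrix.from_array([[1, 0, 1], [0, 1, 0], [1, 0, 0], [0, 1, 1]])
        alpha = cronbach_alpha(m)
        assert alpha < 0
        report = reliability_report(m)
        assert report.alpha == alpha
        assert "negative_alpha" in report.warnings

    def test_identical_totals_raise(self):
        m = ItemResponseMatrix.from_array([[1, 0], [0, 1], [1, 0]])
        with pytest.raises(DegenerateCohortError, match="identical total scores"):
            cronbach_alpha(m)

    def test_invariant_to_variance_convention(self):
        # population (ddof=0) and sample (ddof=1) variances rescale the
        # numerator and denominator identically
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = random_matrix(rng)
            k = m.n_items
            pop = k / (k - 1) * (
                1.0
                - m.responses.var(axis=0, ddof=0).sum()
                / m.total_scores.var(ddof=0)
            )
            assert cronbach_alpha(m) == pytest.approx(pop, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        for _ in range(5):
            m = random_matrix(rng)
            expected = pg.cronbach_alpha(data=pd.DataFrame(m.responses))[0]
            assert cronbach_alpha(m) == pytest.approx(expected, abs=1e-10)


class TestSem:
    @pytest.mark.parametrize(
        "sd, reliability, expected",
        [
            (9.954, 0.905, 3.07),   # full simulated cohort
            (5.85, 0.704, 3.18),    # restricted (passing) cohort
        ],
    )
    def test_published_worked_values(self, sd, reliability, expected):
        assert round(sem_from_reliability(sd, reliability), 2) == expected

    def test_perfect_reliability_gives_zero(self):
        assert sem_from_reliability(12.3, 1.0) == 0.0

    def test_reliability_out_of_range_rejected(self):
        with pytest.raises(CttError):
            sem_from_reliability(10.0, 1.2)
        with pytest.raises(CttError):
            sem_from_reliability(10.0, -0.1)

    def test_first_principles_hand_example(self, small_matrix):
        assert sem_first_principles(small_matrix) == pytest.approx(
            0.6454972243679028, abs=1e-10
        )

    def test_first_principles_zero_for_perfect_items(self):
        m = ItemResponseMatrix.from_array([[1, 1], [1, 1], [0, 0], [1, 1]])
        assert sem_first_principles(m) == pytest.approx(0.0, abs=1e-10)

    def test_identity_with_reliability_route(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = random_matrix(rng)
            alpha = cronbach_alpha(m)
            if alpha < 0:
                continue
            sd = float(m.total_scores.std(ddof=1))
            assert sem_first_principles(m) == pytest.approx(
                sem_from_reliability(sd, alpha), abs=1e-10
            )

    @given(
        sd=st.floats(0.0, 50.0),
        r1=st.floats(0.0, 1.0),
        r2=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_reliability_linear_in_sd(self, sd, r1, r2):
        lo, hi = sorted((r1, r2))
        assert sem_from_reliability(sd, hi) <= sem_from_reliability(sd, lo)
        assert sem_from_reliability(2 * sd, r1) == pytest.approx(
            2 * sem_from_reliability(sd, r1), abs=1e-9
        )


class TestSpearmanBrown:
    def test_identity_at_unchanged_length(self):
        assert spearman_brown_prophecy(0.83, 1.0) == pytest.approx(0.83)

    def test_doubling_half_reliable_test(self):
        assert spearman_brown_prophecy(0.5, 2.0) == pytest.approx(2 / 3, abs=1e-12)

    def test_lengthening_projection_brackets_target(self):
        # 260-item exam at 0.83: ~450 items still misses 0.9, 480 reaches it
        assert spearman_brown_prophecy(0.83, 450 / 260) < 0.9
        assert spearman_brown_prophecy(0.83, 480 / 260) >= 0.9

    @pytest.mark.parametrize(
        "current, n_items, target, expected",
        [
            (0.83, 260, 0.90, 480),
            (0.9, 100, 0.9, 100),
            (0.5, 10, 2 / 3, 20),
        ],
    )
    def test_items_needed(self, current, n_items, target, expected):
        query = ProphecyQuery(current, n_items, target)
        assert items_needed_for_target(query) == expected

    def test_zero_current_reliability_rejected(self):
        with pytest.raises(CttError, match="no finite length"):
            items_needed_for_target(ProphecyQuery(0.0, 100, 0.5))

    @given(
        current=st.floats(0.05, 0.95),
        target=st.floats(0.05, 0.95),
        n_items=st.integers(5, 500),
    )
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_tightness(self, current, target, n_items):
        needed = items_needed_for_target(ProphecyQuery(current, n_items, target))
        assert spearman_brown_prophecy(current, needed / n_items) >= target - 1e-9
        if needed > 1:
            short = spearman_brown_prophecy(current, (needed - 1) / n_items)
            # one item fewer must fall short unless the count was exact
            exact = n_items * target * (1 - current) / (current * (1 - target))
            if needed - exact > 1e-6:
                assert short < target


class TestRestrictionOfRange:
    def test_published_worked_value(self):
        r = restriction_of_range_correlation(RangeRestrictionQuery(0.9, 10.0, 5.85))
        assert round(r, 2) == 0.77

    def test_no_restriction_is_identity(self):
        q = RangeRestrictionQuery(0.63, 8.0, 8.0)
        assert restriction_of_range_correlation(q) == pytest.approx(0.63, abs=1e-12)

    def test_direct_evaluation(self):
        q = RangeRestrictionQuery(0.5, 1.0, 0.5)
        assert restriction_of_range_correlation(q) == pytest.approx(
            0.2773500981126146, abs=1e-10
        )

    @given(r=st.floats(0.05, 0.99), u1=st.floats(0.05, 1.0), u2=st.floats(0.05, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_sd_ratio(self, r, u1, u2):
        lo, hi = sorted((u1, u2))
        r_lo = restriction_of_range_correlation(RangeRestrictionQuery(r, 1.0, lo))
        r_hi = restriction_of_range_correlation(RangeRestrictionQuery(r, 1.0, hi))
        assert r_lo <= r_hi + 1e-12

    def test_widening_rejected(self):
        with pytest.raises(CttError, match="not a restriction"):
            RangeRestrictionQuery(0.9, 5.0, 10.0)


class TestScoreSummary:
    @pytest.mark.parametrize(
        "scores, mean, sd",
        [
            ((50, 50), 50.0, 0.0),
            ((40, 60), 50.0, 14.142135623730951),
            ((0, 0, 12), 4.0, 6.928203230275509),
        ],
    )
    def test_hand_arithmetic(self, scores, mean, sd):
        got_mean, got_sd = score_summary(scores)
        assert got_mean == pytest.approx(mean, abs=1e-9)
        assert got_sd == pytest.approx(sd, abs=1e-9)

    def test_single_score_rejected(self):
        with pytest.raises(CttError):
            score_summary([50.0])


class TestItemResponseMatrix:
    def test_dimension_floor(self):
        with pytest.raises(CttError):
            ItemResponseMatrix.from_array([[1, 0]])

    def test_missing_cells_rejected(self):
        with pytest.raises(MissingDataError):
            ItemResponseMatrix.from_array([[1, np.nan], [0, 1]])

    def test_csv_round_trip(self, small_matrix, tmp_path):
        path = tmp_path / "m.csv"
        small_matrix.to_csv(path)
        back = ItemResponseMatrix.from_csv(path)
        np.testing.assert_array_equal(back.responses, small_matrix.responses)
        assert back.item_ids == small_matrix.item_ids

    def test_csv_blank_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("candidate,i1,i2\nc1,1,0\nc2,,1\n")
        with pytest.raises(MissingDataError, match="missing cell"):
            ItemResponseMatrix.from_csv(path)

    def test_report_json_keys(self, small_matrix):
        import json

        payload = json.loads(reliability_report(small_matrix).to_json())
        assert set(payload) == {
            "n_candidates", "n_items", "alpha", "score_sd", "sem", "warnings"
        }
        assert payload["alpha"] == pytest.approx(0.75)
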