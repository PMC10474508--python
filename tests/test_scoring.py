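import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dss import (
    AttemptRecord,
    Method,
    MilestoneDefinition,
    ScoreQuery,
    dss,
    score_dmas,
    score_frame,
    score_lmas,
    score_table,
)
from dss.scoring import attempts_to_frame

from conftest import random_milestone


class TestDiscreteScore:
    @pytest.mark.parametrize("age", [3, 10, 18])
    def test_attained_scores_zero_at_any_age(self, walk, age):
        assert score_dmas(walk, age, attained=True) == 0

    @pytest.mark.parametrize(
        ("age", "expected"), [(4, 1), (8, 2), (10, 3), (15, 4)]
    )
    def test_failure_scores_bracket_index(self, walk, age, expected):
        assert score_dmas(walk, age, attained=False) == expected


class TestLinearizedScore:
    def test_interpolates_within_bracket(self, walk):
        assert score_lmas(walk, 10.5, attained=False) == pytest.approx(2.5)

    def test_endpoints(self, walk):
        assert score_lmas(walk, walk.t0, attained=False) == 0.0
        assert score_lmas(walk, walk.t100, attained=False) == 4.0
        assert score_lmas(walk, walk.t75, attained=False) == pytest.approx(1.0)

    def test_attained_is_zero(self, walk):
        assert score_lmas(walk, 10.5, attained=True) == 0.0

    def test_degenerate_bracket_takes_right_limit(self):
        m = MilestoneDefinition("step", "language", 3, 5, 5, 8, 10)
        assert score_lmas(m, 5, attained=False) == 2.0

    def test_random_draws_bounds_ceiling_and_monotonicity(self):
        """LMAS stays in [0,4], ceils to DMAS inside brackets, grows with age."""
        rng = np.random.default_rng(77)
        n_checked = 0
        for _ in range(500):
            m = random_milestone(rng)
            ages = np.sort(rng.uniform(m.t0 - 1, m.t100 + 1, 20))
            values = [score_lmas(m, a, attained=False) for a in ages]
            assert all(0.0 <= v <= 4.0 for v in values)
            assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
            bounds = m.thresholds
            for a, v in zip(ages, values):
                i = score_dmas(m, a, attained=False)
                if bounds[i - 1] < a < bounds[i]:  # strictly inside the bracket
                    assert math.ceil(v) == i
                    n_checked += 1
        assert n_checked > 5000

    @settings(max_examples=300, derandomize=True)
    @given(
        ts=st.lists(st.floats(0, 60, allow_nan=False), min_size=5, max_size=5),
        frac=st.floats(-0.2, 1.2),
    )
    def test_score_pair_invariants_hold_for_any_milestone(self, ts, frac):
        """For arbitrary valid thresholds and ages: both scores are in
        range, attainment zeroes both, and LMAS never exceeds DMAS."""
        ts = sorted(ts)
        m = MilestoneDefinition("m", "language", *ts)
        a = ts[0] + frac * (ts[4] - ts[0])
        d = score_dmas(m, a, attained=False)
        l = score_lmas(m, a, attained=False)
        assert 1 <= d <= 4
        assert 0.0 <= l <= 4.0
        assert l <= d + 1e-12
        assert score_dmas(m, a, attained=True) == 0
        assert score_lmas(m, a, attained=True) == 0.0

    def test_continuity_at_bracket_boundaries(self):
        """|LMAS(b - eps) - LMAS(b + eps)| vanishes at every boundary.

        The finite-difference check needs non-vanishing bracket widths on
        both sides; near-degenerate brackets are covered by the explicit
        right-limit tests above.
        """
        rng = np.random.default_rng(78)
        eps = 1e-6
        for _ in range(200):
            m = random_milestone(rng)
            bounds = m.thresholds
            for i, boundary in enumerate((m.t75, m.t90, m.t95), start=1):
                if bounds[i] - bounds[i - 1] < 0.05 or bounds[i + 1] - bounds[i] < 0.05:
                    continue
                lo = score_lmas(m, boundary - eps, attained=False)
                hi = score_lmas(m, boundary + eps, attained=False)
                assert abs(hi - lo) < 1e-4


class TestVectorizedScoring:
    def test_matches_scalar_functions(self, toy_scale):
        rng = np.random.default_rng(5)
        ids = list(toy_scale.milestones)
        records = [
            AttemptRecord("c1", rng.choice(ids), float(rng.uniform(0, 20)),
                          bool(rng.random() < 0.5))
            for _ in range(300)
        ]
        scored = score_frame(attempts_to_frame(records), toy_scale)
        for rec, row in zip(records, scored.itertuples(index=False)):
            m = toy_scale[rec.milestone_id]
            assert row.dmas == score_dmas(m, rec.age, rec.attained)
            assert row.lmas == pytest.approx(score_lmas(m, rec.age, rec.attained), abs=1e-12)

    def test_unknown_milestone_named_in_error(self, toy_scale):
        frame = attempts_to_frame([AttemptRecord("c1", "levitates", 5.0, True)])
        with pytest.raises(KeyError, match="levitates"):
            score_frame(frame, toy_scale)


class TestSurveillanceScore:
    def test_mean_of_per_attempt_scores(self, walk, toy_scale):
        # dmas scores: 0 (attained), 0 (attained), 2 (failed in b2), 1 (failed in b1)
        frame = attempts_to_frame([
            AttemptRecord("c1", "walk", 10.0, True),
            AttemptRecord("c1", "walk", 11.0, True),
            AttemptRecord("c1", "walk", 8.0, False),
            AttemptRecord("c1", "walk", 4.0, False),
        ])
        q = ScoreQuery(window=(0, 36), domains=frozenset({"gross_motor"}), method="dmas")
        assert dss(frame, toy_scale, q) == pytest.approx(0.75)

    def test_all_attained_is_zero_not_undefined(self, toy_scale):
        frame = attempts_to_frame(
            [AttemptRecord("c1", "walk", 10.0, True), AttemptRecord("c1", "pincer", 9.0, True)]
        )
        q = ScoreQuery(window=(0, 36), domains="motor")
        assert dss(frame, toy_scale, q) == 0.0

    def test_no_matching_attempts_is_undefined(self, toy_scale):
        frame = attempts_to_frame([AttemptRecord("c1", "walk", 10.0, True)])
        q = ScoreQuery(window=(20, 30), domains="motor")
        assert dss(frame, toy_scale, q) is None

    def test_invalid_queries_rejected(self):
        with pytest.raises(ValueError):
            ScoreQuery(window=(12, 12), domains="motor")
        with pytest.raises(ValueError):
            ScoreQuery(window=(0, 12), domains=frozenset())

    def test_matches_brute_force_oracle(self, toy_scale):
        """DSS equals a one-pass mean over individually filtered attempts."""
        rng = np.random.default_rng(9)
        ids = list(toy_scale.milestones)
        for _ in range(100):
            records = [
                AttemptRecord(f"c{rng.integers(3)}", rng.choice(ids),
                              float(rng.uniform(0, 25)), bool(rng.random() < 0.7))
                for _ in range(rng.integers(1, 40))
            ]
            start = float(rng.uniform(0, 10))
            window = (start, start + float(rng.uniform(2, 20)))
            group = rng.choice(["motor", "language_social"])
            q = ScoreQuery(window=window, domains=group)
            expected_scores = []
            for rec in records:
                m = toy_scale[rec.milestone_id]
                if m.group.value != group or not window[0] <= rec.age < window[1]:
                    continue
                expected_scores.append(score_lmas(m, rec.age, rec.attained))
            got = dss(attempts_to_frame(records), toy_scale, q)
            if not expected_scores:
                assert got is None
            else:
                assert got == pytest.approx(np.mean(expected_scores), abs=1e-12)

    def test_disjoint_union_is_weighted_mean(self, toy_scale):
        rng = np.random.default_rng(10)
        ids = list(toy_scale.milestones)
        q = ScoreQuery(window=(0, 36), domains=frozenset(["language", "personal_social",
                                                          "fine_motor", "gross_motor"]))
        for _ in range(50):
            records = [
                AttemptRecord("c1", rng.choice(ids), float(rng.uniform(0, 30)),
                              bool(rng.random() < 0.6))
                for _ in range(rng.integers(2, 30))
            ]
            k = rng.integers(1, len(records))
            part_a, part_b = records[:k], records[k:]
            da = dss(attempts_to_frame(part_a), toy_scale, q)
            db = dss(attempts_to_frame(part_b), toy_scale, q)
            dab = dss(attempts_to_frame(records), toy_scale, q)
            combined = (len(part_a) * da + len(part_b) * db) / len(records)
            assert dab == pytest.approx(combined, abs=1e-12)


class TestScoreTable:
    def test_missing_years_stay_undefined(self, toy_scale):
        frame = attempts_to_frame([AttemptRecord("c1", "walk", 10.0, False)])
        table = score_table(frame, toy_scale)
        cell = table[(table.child_id == "c1") & (table.group == "motor")]
        year1 = cell[cell.window_start == 0].iloc[0]
        assert year1.n_attempts == 1 and not np.isnan(year1.dss)
        for start in (12.0, 24.0):
            row = cell[cell.window_start == start].iloc[0]
            assert row.n_attempts == 0 and np.isnan(row.dss)

    def test_identical_children_identical_rows(self, toy_scale):
        frame = attempts_to_frame([
            AttemptRecord(c, "walk", 8.0, False) for c in ("c1", "c2")
        ] + [AttemptRecord(c, "babbles", 9.0, True) for c in ("c1", "c2")])
        table = score_table(frame, toy_scale)
        a = table[table.child_id == "c1"].drop(columns="child_id").reset_index(drop=True)
        b = table[table.child_id == "c2"].drop(columns="child_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_motor_cell_uses_only_motor_attempts(self, toy_scale):
        frame = attempts_to_frame([
            AttemptRecord("c1", "walk", 8.0, False),     # motor, lmas (8-6)/3+1
            AttemptRecord("c1", "pincer", 9.5, False),   # motor
            AttemptRecord("c1", "babbles", 9.0, False),  # language: excluded
        ])
        m_walk = toy_scale["walk"]
        m_pincer = toy_scale["pincer"]
        expected = np.mean([
            score_lmas(m_walk, 8.0, False), score_lmas(m_pincer, 9.5, False)
        ])
        table = score_table(frame, toy_scale)
        row = table[(table.group == "motor") & (table.window_start == 0)].iloc[0]
        assert row.n_attempts == 2
        assert row.dss == pytest.approx(expected)

    def test_final_window_includes_36_months(self, toy_scale):
        frame = attempts_to_frame([AttemptRecord("c1", "walk", 36.0, True)])
        table = score_table(frame, toy_scale)
        row = table[(table.group == "motor") & (table.window_start == 24)].iloc[0]
        assert row.n_attempts == 1
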