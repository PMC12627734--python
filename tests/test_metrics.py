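"""Coordination and leadership metrics: oracles, identities, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadboard import metrics as met
from dyadboard.signals import SegmentSequence


def seq(states, kind="hand", dt=0.001):
    return SegmentSequence(states=np.asarray(states, dtype=int), dt=dt, kind=kind)


class TestClassifyInteraction:
    @pytest.mark.parametrize(
        "left, right, expected",
        [
            (2, 0, "aligned"),  # up / down
            (0, 2, "aligned"),  # down / up
            (2, 2, "opposed"),  # both up
            (0, 0, "opposed"),  # both down
            (2, 1, "single"),
            (1, 0, "single"),
            (1, 1, "stationary"),
        ],
    )
    def test_category_table(self, left, right, expected):
        tl = met.classify_interaction(seq([left] * 10), seq([right] * 10))
        assert met.CATEGORY_LABELS[tl.categories[0]] == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            met.classify_interaction(seq([1] * 5), seq([1] * 6))

    def test_hand_swap_leaves_categories_unchanged(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(0, 3, 200), rng.integers(0, 3, 200)
        t1 = met.classify_interaction(seq(a), seq(b))
        t2 = met.classify_interaction(seq(b), seq(a))
        np.testing.assert_array_equal(t1.categories, t2.categories)


class TestCoordinationRatios:
    def test_durations_divide_completion_time(self):
        # 5001 samples span exactly 5.0 s at 1 kHz
        cats = np.concatenate([
            np.zeros(2000), np.ones(1000), np.full(1000, 2), np.full(1001, 3),
        ]).astype(int)
        tl = met.InteractionTimeline(categories=cats, dt=0.001)
        ratios = met.coordination_ratios(tl, completion_time=5.0)
        assert ratios == pytest.approx(
            {"aligned": 0.4, "opposed": 0.2, "single": 0.2, "stationary": 0.2}
        )
        assert sum(ratios.values()) == pytest.approx(1.0)

    def test_all_stationary(self):
        tl = met.InteractionTimeline(categories=np.full(3001, 3), dt=0.001)
        ratios = met.coordination_ratios(tl, 3.0)
        assert ratios["stationary"] == pytest.approx(1.0)

    def test_zero_completion_time_rejected(self):
        tl = met.InteractionTimeline(categories=np.zeros(10, dtype=int), dt=0.001)
        with pytest.raises(ValueError):
            met.coordination_ratios(tl, 0.0)


def _delay_fixture(onset_l_ms, onset_r_ms, n=3000, move_ms=500):
    """Board ccw rotation with left-down / right-up onsets at given times."""
    left = np.ones(n, dtype=int)
    right = np.ones(n, dtype=int)
    board = np.ones(n, dtype=int)
    left[onset_l_ms : onset_l_ms + move_ms] = 0   # down
    right[onset_r_ms : onset_r_ms + move_ms] = 2  # up
    start = min(onset_l_ms, onset_r_ms)
    board[start : start + move_ms + abs(onset_l_ms - onset_r_ms)] = 2  # ccw
    return seq(board, kind="board"), seq(left), seq(right)


class TestAlignedDelays:
    def test_right_leads_gives_positive_delay(self):
        board, left, right = _delay_fixture(onset_l_ms=1120, onset_r_ms=1000)
        obs, skipped = met.aligned_delays(board, left, right)
        assert skipped == 0
        assert len(obs) == 1
        assert obs[0].delay == pytest.approx(0.12)
        assert obs[0].abs_delay == pytest.approx(0.12)

    def test_simultaneous_onsets_give_zero_delay(self):
        board, left, right = _delay_fixture(1000, 1000)
        obs, _ = met.aligned_delays(board, left, right)
        assert obs[0].delay == 0.0

    def test_single_dominated_segment_is_excluded(self):
        # right barely overlaps: the rotation is mostly one-sided
        board, left, right = _delay_fixture(onset_l_ms=1000, onset_r_ms=1280)
        obs, _ = met.aligned_delays(board, left, right)
        assert obs == []

    def test_recovered_lag_on_synthetic_dyad(self, asym_case):
        """The imposed 120 ms follower lag is recovered within 20 ms."""
        summary = asym_case.summary
        assert summary.n_delays >= 20
        assert 0.10 <= summary.mean_abs_delay <= 0.14
        assert summary.mean_delay < 0  # left led


class TestMovementRatio:
    def test_exact_linear_synthetic_shares(self):
        theta = np.linspace(-0.05, 0.05, 40)
        z_l = -0.7 * theta + 0.01
        z_r = 0.3 * theta + 0.01
        fit = met.movement_ratio_from_points(theta, z_l, z_r)
        assert fit.p_left == pytest.approx(0.7, abs=1e-12)
        assert fit.p_right == pytest.approx(0.3, abs=1e-12)
        assert fit.r2_left == pytest.approx(1.0)
        assert fit.leader == "L"

    def test_symmetric_shares_give_no_leader(self):
        theta = np.linspace(-0.05, 0.05, 20)
        fit = met.movement_ratio_from_points(theta, -0.5 * theta, 0.5 * theta)
        assert fit.p_left == pytest.approx(0.5)
        assert fit.leader == "none"

    def test_offset_moves_intercept_not_share(self):
        theta = np.linspace(-0.05, 0.05, 20)
        base = met.movement_ratio_from_points(theta, -0.6 * theta, 0.4 * theta)
        moved = met.movement_ratio_from_points(theta, -0.6 * theta + 0.3, 0.4 * theta + 0.3)
        assert moved.p_left == pytest.approx(base.p_left)
        assert moved.b_left == pytest.approx(base.b_left + 0.3)

    def test_undefined_when_gain_sum_nonpositive(self):
        theta = np.linspace(-0.05, 0.05, 20)
        fit = met.movement_ratio_from_points(theta, 0.5 * theta, -0.5 * theta)
        assert not fit.defined
        assert math.isnan(fit.p_left)
        assert fit.leader == "none"

    def test_too_few_points_rejected(self):
        theta = np.linspace(0, 1, 4)
        with pytest.raises(ValueError):
            met.movement_ratio_from_points(theta, theta, theta)

    def test_share_recovery_on_synthetic_dyad(self, asym_case):
        assert asym_case.summary.fit.p_left == pytest.approx(0.7, abs=0.05)


def corrective_bruteforce(z, k=200):
    """Direct double-loop transcription of the corrective-movement definition."""
    n = len(z)
    total = 0.0
    for t in range(1, n + 1):
        w = min(k, t)
        avg = sum(z[t - 1 - j] for j in range(w)) / w
        total += abs(z[t - 1] - avg)
    return total / n


class TestCorrectiveMovement:
    def test_constant_positions_flagged(self):
        res = met.corrective_ratio(np.full(500, 0.2), np.full(500, -0.1))
        assert res.c_left <= 1e-12 and res.c_right <= 1e-12
        assert res.flagged
        assert res.cr_left == 0.5

    def test_one_moving_side_takes_all(self):
        ramp = np.linspace(0, 1, 500)
        res = met.corrective_ratio(np.full(500, 0.3), ramp)
        assert res.cr_right == pytest.approx(1.0)
        assert res.leader == "R"

    def test_ramp_deviation_approaches_closed_form(self):
        v, k = 0.001, 200
        z = v * np.arange(5000)
        c = met.corrective_movement(z, k)
        # far from the start, |z - trailing mean| -> v (k - 1) / 2
        assert c == pytest.approx(v * (k - 1) / 2, rel=0.05)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            z = rng.normal(size=rng.integers(10, 400))
            assert met.corrective_movement(z) == pytest.approx(
                corrective_bruteforce(z), abs=1e-12
            )


class TestUnilateralRatio:
    def _setup(self, dl, dr):
        n = 1000
        left_states = np.ones(n, dtype=int)
        right_states = np.ones(n, dtype=int)
        z_l = np.zeros(n)
        z_r = np.zeros(n)
        left_states[100:300] = 2
        z_l[100:300] = np.linspace(0, dl, 200)
        z_l[300:] = dl
        right_states[500:700] = 0
        z_r[500:700] = np.linspace(0, -dr, 200)
        z_r[700:] = -dr
        tl = met.classify_interaction(seq(left_states), seq(right_states))
        return tl, seq(left_states), seq(right_states), z_l, z_r

    def test_path_length_shares(self):
        tl, sl, sr, z_l, z_r = self._setup(0.03, 0.01)
        res = met.unilateral_ratio(tl, sl, sr, z_l, z_r)
        assert res.ratio_left == pytest.approx(0.75, abs=0.01)
        assert res.ratio_right == pytest.approx(0.25, abs=0.01)

    def test_single_sided_movement(self):
        tl, sl, sr, z_l, z_r = self._setup(0.03, 0.0)
        res = met.unilateral_ratio(tl, sl, sr, z_l, z_r)
        assert res.ratio_left == pytest.approx(1.0, abs=1e-6)
        assert res.leader == "L"

    def test_offset_invariance(self):
        tl, sl, sr, z_l, z_r = self._setup(0.02, 0.04)
        a = met.unilateral_ratio(tl, sl, sr, z_l, z_r)
        b = met.unilateral_ratio(tl, sl, sr, z_l + 5.0, z_r + 5.0)
        assert a.ratio_left == pytest.approx(b.ratio_left)

    def test_undefined_without_single_intervals(self):
        n = 100
        tl = met.InteractionTimeline(categories=np.full(n, met.STATIONARY), dt=0.001)
        res = met.unilateral_ratio(tl, seq([1] * n), seq([1] * n), np.zeros(n), np.zeros(n))
        assert not res.defined
        assert math.isnan(res.ratio_left)


def minjerk(n_move, amplitude, n_total, onset):
    s = np.zeros(n_total)
    tau = np.linspace(0, 1, n_move)
    s[onset : onset + n_move] = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    s[onset + n_move :] = amplitude
    return s


class TestMTTA:
    def test_required_movement_formula(self):
        # a 0 -> 0.1 rad rotation with l = 0.25 m requires 49.9167 mm in total
        theta_start, theta_end = 0.0, 0.1
        l_req = 2 * 0.25 * (math.sin(theta_end) - math.sin(theta_start))
        assert l_req == pytest.approx(0.0499167, abs=1e-6)

    def _dyad_trial(self, share_l, n=4000, onset=1000, n_move=300, d=0.02):
        z_l = -share_l * minjerk(n_move, d, n, onset)
        z_r = (1 - share_l) * minjerk(n_move, d, n, onset)
        theta = np.arcsin((z_r - z_l) / 0.5)
        states = np.ones(n, dtype=int)
        states[onset : onset + n_move] = 2
        return theta, z_l, z_r, seq(states, kind="board")

    def test_exact_share_construction_yields_plateaus(self):
        """A 0.7/0.3 dyad with simultaneous movements: NT plateaus at the shares."""
        trial = self._dyad_trial(0.7)
        curves = met.mtta([trial], half_length=0.25)
        leader, follower = curves["leader"], curves["follower"]
        onset_idx = np.flatnonzero(leader.time == 0.0)[0]
        assert leader.nt[onset_idx] == 0.0
        assert follower.nt[onset_idx] == 0.0
        assert leader.nt[-1] == pytest.approx(0.70, abs=1e-6)
        assert follower.nt[-1] == pytest.approx(0.30, abs=1e-6)

    def test_one_sided_rotation(self):
        """When the right hand alone rotates the board, its NT rises to 1."""
        trial = self._dyad_trial(0.0)
        curves = met.mtta([trial], half_length=0.25,
                          roles={"L": "follower", "R": "leader"})
        assert curves["leader"].nt[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.abs(curves["follower"].nt).max() < 1e-9

    def test_scale_invariance(self):
        a = met.mtta([self._dyad_trial(0.7, d=0.01)], half_length=0.25)
        b = met.mtta([self._dyad_trial(0.7, d=0.03)], half_length=0.25)
        np.testing.assert_allclose(a["leader"].nt, b["leader"].nt, atol=1e-9)

    def test_window_crossing_trial_boundary_dropped(self):
        trial = self._dyad_trial(0.7, onset=100)  # window starts before 0
        curves = met.mtta([trial], half_length=0.25)
        assert curves == {}


class TestDyadicImprovement:
    @pytest.mark.parametrize(
        "t, tp, td, expected",
        [
            (10.0, 8.0, 8.0, (0.2, 0.2)),
            (8.0, 8.0, 8.0, (0.0, 0.0)),
            (8.0, 10.0, 8.0, (-0.25, 0.0)),
        ],
    )
    def test_points(self, t, tp, td, expected):
        pt = met.dyadic_improvement(t, tp, td)
        assert (pt.x, pt.y) == (pytest.approx(expected[0]), pytest.approx(expected[1]))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            met.dyadic_improvement(0.0, 1.0, 1.0)


class TestLeadershipConsensus:
    def test_all_metrics_name_left_leader(self, asym_case):
        leaders = asym_case.summary.metric_leaders()
        assert set(leaders.values()) == {"L"}
        assert asym_case.summary.leader == "L"

    def test_balanced_dyad_has_no_leader(self, balanced_case):
        summary = balanced_case.summary
        assert abs(summary.fit.p_left - 0.5) < 0.05
        assert summary.leader == "none"

    def test_mirror_property(self, asym_case):
        """Mirroring the apparatus (swap sides, negate tilt) swaps every
        left/right metric and negates the delay."""
        recs, segs = asym_case.successes, asym_case.segmentations
        from dyadboard.pipeline import pooled_leadership, TrialSegmentation

        mirrored_segs = [
            TrialSegmentation(
                left=s.right,
                right=s.left,
                board=SegmentSequence(states=2 - s.board.states, dt=s.board.dt, kind="board"),
                z_left=s.z_right,
                z_right=s.z_left,
                theta=-s.theta,
            )
            for s in segs
        ]
        orig = asym_case.summary
        mirr = pooled_leadership(recs, mirrored_segs)
        assert mirr.fit.p_left == pytest.approx(orig.fit.p_right)
        assert mirr.corrective.cr_left == pytest.approx(orig.corrective.cr_right)
        assert mirr.unilateral.ratio_left == pytest.approx(orig.unilateral.ratio_right)
        assert mirr.mean_delay == pytest.approx(-orig.mean_delay)
        assert mirr.leader == "R"


class TestNormalization:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_ratio_normalizations(self, seed):
        rng = np.random.default_rng(seed)
        a = seq(rng.integers(0, 3, 500))
        b = seq(rng.integers(0, 3, 500))
        tl = met.classify_interaction(a, b)
        ratios = met.coordination_ratios(tl, 499 * 0.001)
        assert sum(ratios.values()) == pytest.approx(1.0)
        z_l, z_r = rng.normal(size=500), rng.normal(size=500)
        corr = met.corrective_ratio(z_l, z_r)
        assert corr.cr_left + corr.cr_right == pytest.approx(1.0)
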