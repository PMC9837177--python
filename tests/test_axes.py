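"""Tests of trial grouping, state axes, projections, and d' cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mesochoice import axes as ax
from mesochoice import synth


def _toy_table():
    """Handcrafted trial table with known rule outcomes."""
    n = 12
    table = pd.DataFrame(
        {
            "stim_onset": np.full(n, 30),
            "left_angle": np.linspace(-80, 80, n),
            "right_angle": np.zeros(n),
            "theta": np.linspace(-80, 80, n),
            "difficulty": np.abs(np.linspace(-80, 80, n)),
            "choice": ["left", "right"] * 5 + ["timeout"] * 2,
            "correct": [True] * n,
            "first_move_time": [0.8, 1.0, 0.3, 0.9, 1.2, 0.7, 1.1, 0.6, 1.3, 0.95, np.nan, np.nan],
            "first_move_dir": ["cw", "ccw", "cw", "ccw", "cw", "ccw", "cw", "ccw", "cw", "ccw", None, None],
            "saccade_times": [[]] * 2 + [[0.1]] + [[0.6]] + [[]] * 8,  # trial 3 saccade 0.3 s before move
            "pupil_change": np.linspace(-2, 2, n),
            "attention_latent": np.linspace(-2, 2, n),
            "n_frames": np.full(n, 105),
        }
    )
    return table


class TestBuildGroupPair:
    def test_wheel_rules_brute_force(self):
        table = _toy_table()
        pair = ax.build_group_pair(table, "wheel", 30.0, seed=0)
        # oracle: movement >= 0.5 s and no saccade in [t-0.5, t)
        qualifying = set()
        for i in range(len(table)):
            t = table["first_move_time"].iloc[i]
            if np.isnan(t) or t < 0.5:
                continue
            if any(t - 0.5 <= s < t for s in table["saccade_times"].iloc[i]):
                continue
            qualifying.add(i)
        assert set(pair.trials_a) <= qualifying
        # balanced against the 2 no-movement trials
        assert len(pair.trials_a) == len(pair.trials_b) == 2
        assert set(pair.trials_b) == {10, 11}

    def test_early_movement_excluded(self):
        table = _toy_table()
        pair = ax.build_group_pair(table, "choice", 30.0, seed=0)
        assert 2 not in pair.trials_a and 2 not in pair.trials_b  # moved at 0.3 s
        assert 3 not in pair.trials_a and 3 not in pair.trials_b  # saccade before move

    def test_choice_split_by_direction(self):
        table = _toy_table()
        pair = ax.build_group_pair(table, "choice", 30.0, seed=0)
        dirs_a = table["first_move_dir"].iloc[pair.trials_a]
        dirs_b = table["first_move_dir"].iloc[pair.trials_b]
        assert (dirs_a == "ccw").all() and (dirs_b == "cw").all()

    def test_attention_tertiles_balanced(self):
        rng = np.random.default_rng(0)
        table = _toy_table()
        big = pd.concat([table] * 25, ignore_index=True)
        big["pupil_change"] = rng.normal(size=len(big))
        big = synth.label_attention(big)
        pair = ax.build_group_pair(big, "attention", 30.0, seed=0)
        assert len(pair.trials_a) == len(pair.trials_b) == 100

    def test_empty_group_raises_with_rule(self):
        table = _toy_table()
        table["first_move_time"] = 1.0  # every trial moves -> wheel B empty
        table["saccade_times"] = [[] for _ in range(len(table))]
        with pytest.raises(ValueError, match="no movement"):
            ax.build_group_pair(table, "wheel", 30.0, seed=0)

    def test_stimulus_alignment_shift(self):
        table = _toy_table()
        pair = ax.build_group_pair(table, "stimulus", 30.0, seed=0)
        np.testing.assert_allclose(pair.align_a - pair.align_b, 0.5 * 30.0)

    def test_disjoint_groups_enforced(self):
        with pytest.raises(ValueError, match="disjoint"):
            ax.TrialGroupPair(
                "choice",
                np.array([0, 1]),
                np.array([1, 2]),
                np.zeros(2),
                np.zeros(2),
                (-0.5, 0.5),
            )


class TestStateAxis:
    def test_recovers_planted_direction(self):
        temporal, labels = synth.gaussian_component_trials(
            3.0, 500, n_components=4, seed=1
        )
        axis = ax.state_axis(temporal[labels], temporal[~labels], mode="window")
        assert abs(axis[0]) > 0.99
        assert np.linalg.norm(axis) == pytest.approx(1.0)

    def test_identical_groups_raise(self):
        data = np.ones((10, 3, 5))
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ax.state_axis(data, data, mode="window")

    def test_zero_variance_component_warns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 3, 4))
        b = rng.normal(size=(20, 3, 4)) + 1.0
        a[:, 2] = 5.0
        b[:, 2] = 5.0
        with pytest.warns(RuntimeWarning, match="zero pooled SD"):
            axis = ax.state_axis(a, b, mode="window")
        assert axis[2] == 0.0


class TestProject:
    def test_basis_vector_returns_component(self):
        rng = np.random.default_rng(0)
        temporal = rng.normal(size=(7, 4, 9))
        e1 = np.eye(4)[0]
        np.testing.assert_allclose(ax.project(e1, temporal), temporal[:, 0, :])

    def test_linearity(self):
        rng = np.random.default_rng(1)
        temporal = rng.normal(size=(5, 3, 6))
        s = rng.normal(size=3)
        np.testing.assert_allclose(
            ax.project(2.5 * s, temporal), 2.5 * ax.project(s, temporal)
        )

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(2)
        temporal = rng.normal(size=(4, 5, 6))
        s_t = rng.normal(size=(5, 6))
        got = ax.project(s_t, temporal)
        expected = np.empty((4, 6))
        for n in range(4):
            for t in range(6):
                expected[n, t] = sum(s_t[k, t] * temporal[n, k, t] for k in range(5))
        np.testing.assert_allclose(got, expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            ax.project(np.ones(3), np.zeros((2, 4, 5)))


class TestDPrimeCurve:
    def test_planted_delta_recovered(self):
        temporal, labels = synth.gaussian_component_trials(
            1.0, 400, n_components=2, n_frames=31, seed=3
        )
        curve = ax.dprime_curve(
            temporal[labels], temporal[~labels], 30.0, (-0.5, 0.5), seed=0
        )
        assert curve.per_fold.shape[0] == 5
        assert curve.dprime.mean() == pytest.approx(1.0, abs=0.15)

    def test_shuffled_labels_null(self):
        rng = np.random.default_rng(4)
        temporal, labels = synth.gaussian_component_trials(
            1.0, 400, n_components=2, n_frames=31, seed=5
        )
        shuffled = rng.permutation(labels)
        curve = ax.dprime_curve(
            temporal[shuffled], temporal[~shuffled], 30.0, (-0.5, 0.5), seed=0
        )
        assert abs(curve.dprime.mean()) < 0.25

    def test_scale_invariance(self):
        temporal, labels = synth.gaussian_component_trials(1.0, 200, n_frames=31, seed=6)
        c1 = ax.dprime_curve(temporal[labels], temporal[~labels], 30.0, (-0.5, 0.5), seed=1)
        c2 = ax.dprime_curve(
            7.0 * temporal[labels], 7.0 * temporal[~labels], 30.0, (-0.5, 0.5), seed=1
        )
        np.testing.assert_allclose(c1.dprime, c2.dprime, atol=1e-10)

    def test_group_swap_antisymmetry(self):
        # the d' statistic itself is exactly antisymmetric under group swap;
        # the cross-validated curve is antisymmetric in expectation (the CV
        # fold draw differs), so it is checked at statistical tolerance
        rng = np.random.default_rng(7)
        pa, pb = rng.normal(1.0, 1.0, (50, 9)), rng.normal(0.0, 1.0, (50, 9))
        np.testing.assert_allclose(ax.dprime(pa, pb), -ax.dprime(pb, pa))
        # re-estimating the axis flips its sign under swap as well, so the
        # reported |d'| curve is swap-invariant
        temporal, labels = synth.gaussian_component_trials(1.0, 400, n_frames=31, seed=7)
        c1 = ax.dprime_curve(temporal[labels], temporal[~labels], 30.0, (-0.5, 0.5), seed=2)
        c2 = ax.dprime_curve(temporal[~labels], temporal[labels], 30.0, (-0.5, 0.5), seed=2)
        np.testing.assert_allclose(np.abs(c1.dprime), np.abs(c2.dprime), atol=0.25)

    def test_insufficient_trials_raise(self):
        temporal, labels = synth.gaussian_component_trials(1.0, 8, seed=8)
        with pytest.raises(ValueError):
            ax.dprime_curve(temporal[labels], temporal[~labels], 30.0, (-0.5, 0.5))


class TestAxisStability:
    def test_constant_axis_all_ones(self):
        s = np.tile(np.array([1.0, 2.0, 2.0])[:, None], (1, 10))
        r = ax.axis_stability(s)
        np.testing.assert_allclose(r, 1.0)

    def test_rotation_block_structure(self):
        s = np.zeros((2, 20))
        s[0, :10] = 1.0
        s[1, 10:] = 1.0
        r = ax.axis_stability(s, smoothing=1)
        assert r[2, 7] == pytest.approx(1.0)
        assert r[12, 18] == pytest.approx(1.0)
        assert r[2, 18] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=(5, 15))
        r = ax.axis_stability(s)
        np.testing.assert_allclose(r, r.T)

    def test_stable_window_center(self):
        s = np.zeros((2, 40))
        s[0, :4] = 1.0
        s[1, 4:] = 1.0
        t_star = ax.stable_window_center(ax.axis_stability(s, smoothing=1))
        assert 12 <= t_star <= 32


class TestAreaAxis:
    def test_planted_localization(self):
        rng = np.random.default_rng(10)
        n = 400
        labels = np.zeros(n, dtype=bool)
        labels[: n // 2] = True
        temporal = rng.normal(size=(n, 6, 31))
        temporal[labels, 2, :] += 1.2  # signal only on component 2 ("area L")
        area_l = np.array([2])
        other = np.array([0, 1])
        full = ax.dprime_curve(temporal[labels], temporal[~labels], 30.0, (-0.5, 0.5), seed=0)
        d_l = ax.area_dprime_curve(
            temporal[labels], temporal[~labels], area_l, 30.0, (-0.5, 0.5), seed=0
        )
        d_other = ax.area_dprime_curve(
            temporal[labels], temporal[~labels], other, 30.0, (-0.5, 0.5), seed=0
        )
        assert d_l.dprime.mean() == pytest.approx(full.dprime.mean(), abs=0.2)
        assert abs(d_other.dprime.mean()) < 0.2
        # restricting to a subset cannot beat the full component set
        assert d_l.peak <= full.peak + 0.25

    def test_empty_area_raises(self):
        temporal = np.zeros((10, 3, 5))
        with pytest.raises(ValueError):
            ax.area_dprime_curve(temporal, temporal, np.array([]), 30.0, (-0.5, 0.5))


class TestOrthogonalization:
    def test_self_orthogonalization_errors(self):
        v = np.array([1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            ax.orthogonalize(v, [v])

    def test_orthogonal_nuisance_no_change(self):
        v = np.array([1.0, 0.0, 0.0])
        w = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(ax.orthogonalize(v, [w]), v)

    def test_two_correlated_signals_both_survive(self):
        # two independent planted directions whose trial occurrences are
        # correlated; after mutual orthogonalization each retains d' > 0.5
        rng = np.random.default_rng(11)
        n = 600
        lab1 = np.zeros(n, dtype=bool)
        lab1[: n // 2] = True
        # second label correlated with the first (80% agreement)
        lab2 = lab1 ^ (rng.random(n) < 0.2)
        temporal = rng.normal(size=(n, 8, 31))
        temporal[lab1, 0, :] += 1.5
        temporal[lab2, 1, :] += 1.5
        axis1 = ax.state_axis(temporal[lab1], temporal[~lab1], mode="window")
        axis2 = ax.state_axis(temporal[lab2], temporal[~lab2], mode="window")
        d1 = ax.orthogonalized_dprime(
            temporal[lab1], temporal[~lab1], [axis2], 30.0, (-0.5, 0.5), seed=0
        )
        d2 = ax.orthogonalized_dprime(
            temporal[lab2], temporal[~lab2], [axis1], 30.0, (-0.5, 0.5), seed=0
        )
        assert abs(d1.dprime.mean()) > 0.5
        assert abs(d2.dprime.mean()) > 0.5


class TestAttentionAxisTransfer:
    def test_outcome_independent_attention_axis_transfers(self):
        """Axes fit on one outcome subset discriminate the other subset."""
        rng = np.random.default_rng(12)
        n = 800
        att = np.zeros(n, dtype=bool)
        att[: n // 2] = True
        outcome = rng.random(n) < 0.6  # correct/incorrect, independent of attention
        temporal = rng.normal(size=(n, 6, 31))
        temporal[att, 3, :] += 1.0
        axis_correct = ax.state_axis(
            temporal[att & outcome], temporal[~att & outcome], mode="window"
        )
        pa = ax.project(axis_correct, temporal[att & ~outcome])
        pb = ax.project(axis_correct, temporal[~att & ~outcome])
        d = ax.dprime(pa, pb).mean()
        assert d > 0.7
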