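"""Tests of the psychometric generator, atlas, session tensor, and RNN data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesochoice import synth


class TestPsychometric:
    def test_symmetry_at_zero(self):
        p = synth.PsychometricParams(lapse=0.2)
        assert synth.psychometric_prob(0.0, p, "low") == pytest.approx(0.5)

    def test_saturation_limit(self):
        p = synth.PsychometricParams(lapse=0.2)
        assert synth.psychometric_prob(1e9, p, "high") == pytest.approx(0.9)
        assert synth.psychometric_prob(-1e9, p, "high") == pytest.approx(0.1)

    def test_printed_formula_value(self):
        # direct numerical evaluation: 0.8 * sigmoid(5) + 0.1 at theta=90,
        # alpha=5/90, lapse=0.2
        p = synth.PsychometricParams(lapse=0.2, slope_high=5.0 / 90.0)
        expected = 0.8 / (1.0 + np.exp(-5.0)) + 0.1
        assert synth.psychometric_prob(90.0, p, "high") == pytest.approx(expected)
        assert expected == pytest.approx(0.8946, abs=1e-4)

    def test_invalid_attention_label(self):
        with pytest.raises(ValueError, match="attention"):
            synth.psychometric_prob(0.0, synth.PsychometricParams(), "medium")

    @given(
        theta=st.floats(-90, 89),
        d=st.floats(0.1, 1.0),
        lapse=st.floats(0, 0.9),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, theta, d, lapse):
        p = synth.PsychometricParams(lapse=lapse)
        lo = synth.psychometric_prob(theta, p, "low")
        hi = synth.psychometric_prob(theta + d, p, "low")
        assert hi > lo
        assert lapse / 2 <= lo <= 1 - lapse / 2

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            synth.PsychometricParams(lapse=1.5)
        with pytest.raises(ValueError):
            synth.PsychometricParams(slope_low=-1.0)


class TestSimulateChoices:
    @pytest.mark.parametrize("attention", ["low", "high"])
    def test_fraction_correct_matches_expectation(self, attention):
        p = synth.PsychometricParams()
        levels = synth.standard_difficulties()
        n = 4000
        _, fc = synth.simulate_choices(levels, n, p, attention, seed=7)
        expected = synth.expected_fraction_correct(levels, p, attention)
        se = np.sqrt(expected * (1 - expected) / (n * levels.size))
        assert abs(fc - expected) < 3 * se

    def test_pure_lapse_is_chance(self):
        p = synth.PsychometricParams(lapse=1.0)
        _, fc = synth.simulate_choices([45.0, -45.0], 5000, p, "low", seed=0)
        assert fc == pytest.approx(0.5, abs=0.03)

    def test_empty_difficulties_raises(self):
        with pytest.raises(ValueError):
            synth.simulate_choices([], 10, synth.PsychometricParams(), "low")

    def test_reproducible(self):
        p = synth.PsychometricParams()
        df1, _ = synth.simulate_choices([0.0, 30.0], 50, p, "low", seed=3)
        df2, _ = synth.simulate_choices([0.0, 30.0], 50, p, "low", seed=3)
        pd.testing.assert_frame_equal(df1, df2)

    def test_lapse_recovery_by_mle(self):
        p = synth.PsychometricParams()
        df, _ = synth.simulate_choices(synth.standard_difficulties(), 4000, p, "low", seed=5)
        alpha, lapse = synth.fit_psychometric(df["theta"], df["choice"] == "left")
        # the MLE sampling SD of lapse at this n is ~0.015 (alpha and lapse
        # trade off when the logistic is unsaturated at +-90 deg)
        assert lapse == pytest.approx(p.lapse, abs=0.05)
        assert alpha == pytest.approx(p.slope_low, rel=0.15)


class TestAtlas:
    def test_ten_disjoint_nonempty_areas(self):
        atlas = synth.make_atlas(seed=4)
        ids = np.unique(atlas.label_map)
        assert set(ids) == set(range(11))
        for k in range(1, 11):
            assert atlas.area_mask(k).sum() > 0

    def test_areas_contiguous(self):
        from scipy import ndimage

        atlas = synth.make_atlas(seed=2)
        for k in range(1, 11):
            _, n = ndimage.label(atlas.area_mask(k))
            assert n == 1

    def test_invalid_label_map_rejected(self):
        bad = np.zeros((8, 8), dtype=int)
        bad[0, 0] = 3
        with pytest.raises(ValueError):
            synth.AreaAtlas(label_map=bad)


class TestSession:
    def test_reproducible_bitwise(self, atlas, session_params):
        spec = synth.default_signal_spec()
        t1, tab1 = synth.simulate_session(atlas, spec, session_params, 10, seed=9)
        t2, tab2 = synth.simulate_session(atlas, spec, session_params, 10, seed=9)
        np.testing.assert_array_equal(t1.data, t2.data)
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_behavior_invariants(self, session):
        _, table = session
        has_time = table["first_move_time"].notna()
        has_dir = table["first_move_dir"].notna()
        assert (has_time == has_dir).all()
        np.testing.assert_allclose(table["difficulty"], np.abs(table["theta"]))
        counts = table["attention"].value_counts()
        # tertile labels: high and low each about a third of trials
        assert abs(counts["high"] - len(table) / 3) <= 2
        assert abs(counts["low"] - len(table) / 3) <= 2
        # choice is measured from the first-movement direction
        moved = table[has_time]
        assert ((moved["choice"] == "left") == (moved["first_move_dir"] == "cw")).all()

    def test_min_trials(self, atlas, session_params):
        with pytest.raises(ValueError):
            synth.simulate_session(
                atlas, synth.default_signal_spec(), session_params, 1, seed=0
            )

    def test_choice_amplitude_scales_separation(self, atlas, session_params):
        """Doubling the choice amplitude never decreases the planted contrast."""
        silent = synth.PlantedSignal(
            carrier_areas=("V1",), amplitude=0.0, trial_noise_sd=0.0,
            temporal_profile="step",
        )
        seps = []
        for amp in (0.004, 0.008):
            spec2 = synth.SignalSpec(
                stimulus=silent,
                wheel=silent,
                saccade=silent,
                attention=silent,
                choice=synth.PlantedSignal(
                    carrier_areas=synth.AREA_NAMES,
                    amplitude=amp,
                    trial_noise_sd=0.0,
                    spatial_sparsity=0.2,
                    temporal_profile="ramp",
                ),
                noise_sd=0.0,
                global_fluct_sd=0.0,
            )
            tensor, table = synth.simulate_session(atlas, spec2, session_params, 60, seed=3)
            moved = table["first_move_time"].notna().to_numpy()
            left = (table["choice"] == "left").to_numpy()
            frame = tensor.n_frames - 1
            mean_l = tensor.data[moved & left, :, :, frame].mean()
            mean_r = tensor.data[moved & ~left, :, :, frame].mean()
            seps.append(mean_l - mean_r)
        assert seps[1] >= seps[0] > 0


class TestGaussianComponentTrials:
    def test_closed_form_separation(self):
        temporal, labels = synth.gaussian_component_trials(2.0, 4000, seed=0)
        proj = temporal[:, 0, :].mean(axis=1)
        d = (proj[labels].mean() - proj[~labels].mean())
        assert d == pytest.approx(2.0, abs=0.1)


class TestRNNDataset:
    def test_structure_and_levels(self):
        p = synth.PsychometricParams()
        ds = synth.make_rnn_dataset(p, 50, difficulties=[-90.0, 0.0, 90.0], seed=0)
        x = ds.inputs
        assert x.shape == (50 * 3 * 2, 25, 3)
        # pre-stimulus frames carry only noise on the stimulus channels
        pre = x[:, :10, :2]
        assert abs(pre.mean()) < 0.01
        assert pre.std() == pytest.approx(0.1, abs=0.01)
        # stimulus channels are scaled to angle / 90 (per-level average
        # removes the per-frame input noise)
        post_diff = (x[:, 10:, 0] - x[:, 10:, 1]).mean(axis=1)
        theta = ds.meta["theta"].to_numpy()
        for level in (-90.0, 0.0, 90.0):
            sel = np.isclose(theta, level)
            assert post_diff[sel].mean() == pytest.approx(level / 90.0, abs=0.03)
        # attention channel is a noiseless constant 0/1
        att = x[:, :, 2]
        assert set(np.unique(att)) <= {0.0, 1.0}
        assert (att.std(axis=1) == 0).all()

    def test_targets_one_hot(self):
        ds = synth.make_rnn_dataset(synth.PsychometricParams(), 20, seed=1)
        assert np.all(ds.targets[:, 0] == [0, 0, 1])
        assert set(ds.targets[:, 1].argmax(axis=1)) <= {0, 1}
        assert np.all(ds.targets.sum(axis=2) == 1)

    def test_label_frequency_matches_psychometric(self):
        p = synth.PsychometricParams()
        n = 6400
        ds = synth.make_rnn_dataset(
            p, n, difficulties=[30.0], attention_levels=("high",), seed=2
        )
        frac_left = (ds.meta["choice"] == "left").mean()
        expected = synth.psychometric_prob(30.0, p, "high")
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac_left - expected) < 3 * se

    def test_out_of_range_difficulty_rejected(self):
        with pytest.raises(ValueError):
            synth.make_rnn_dataset(synth.PsychometricParams(), 5, difficulties=[120.0])
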