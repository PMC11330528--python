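"""Tests for ΔF/F, epoch extraction, classification, decoding, bootstrap
and the encoding model."""

import numpy as np
import pandas as pd
import pytest

from taskswitch.neural_analysis import (CalciumRecording, EpochSpec,
                                        bootstrap_proportion_ci,
                                        build_design_matrix, classify_neurons,
                                        compute_dff, decode_timecourse,
                                        epoch_responses, fit_encoding_model,
                                        sustained_significance,
                                        transition_epoch_times, _frames)


class TestComputeDff:
    def test_constant_trace_is_zero(self):
        f = np.full((1, 500), 100.0)
        baseline, dff, valid = compute_dff(f, frame_rate=10.0)
        assert valid.all()
        assert np.allclose(baseline, 100.0)
        assert np.allclose(dff, 0.0)

    def test_step_trace_windowed_min_oracle(self):
        # after a step 100 -> 150 the baseline stays at the pre-step level
        # for the 60 s window, giving dF/F = 0.5
        fs = 10.0
        f = np.concatenate([np.full(700, 100.0), np.full(900, 150.0)])
        baseline, dff, _ = compute_dff(f[None, :], frame_rate=fs)
        # 100 frames after the step (smoothing settled), within the window
        seg = slice(720, 700 + int(60 * fs) - 10)
        assert np.allclose(baseline[0, seg], 100.0)
        assert np.allclose(dff[0, seg], 0.5)
        # once the 60 s window has passed the step, the baseline catches up
        assert np.allclose(baseline[0, 700 + int(60 * fs) + 10:], 150.0)

    def test_brute_force_causal_min_of_smoothed_trace(self):
        # independent oracle: explicit causal moving average followed by an
        # explicit windowed minimum over the preceding 60 s
        rng = np.random.default_rng(0)
        fs = 4.8
        f = 100 + np.cumsum(rng.normal(0, 1, 300))
        f = np.abs(f) + 5
        k, m = _frames(0.75, fs), _frames(60.0, fs)
        # edge-replication padding: partial start windows reuse the first value
        pad = np.concatenate([np.full(k - 1, f[0]), f])
        sm = np.array([pad[i:i + k].mean() for i in range(len(f))])
        oracle = np.array([sm[max(0, i - m + 1):i + 1].min()
                           for i in range(len(f))])
        baseline, dff, _ = compute_dff(f[None, :], frame_rate=fs)
        assert np.allclose(baseline[0], oracle)
        assert np.allclose(dff[0], (f - oracle) / oracle)

    def test_window_rounding_rule(self):
        assert _frames(0.75, 4.8) == 4   # 3.6 frames rounds to 4
        assert _frames(0.05, 4.8) == 1   # never below one frame

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        f = np.abs(100 + np.cumsum(rng.normal(0, 1, 400))) + 5
        _, dff1, _ = compute_dff(f[None, :], 10.0)
        _, dff2, _ = compute_dff(3.7 * f[None, :], 10.0)
        assert np.allclose(dff1, dff2)

    def test_nonpositive_baseline_flagged(self):
        f = np.vstack([np.full(300, 50.0), np.full(300, -1.0)])
        _, dff, valid = compute_dff(f, 10.0)
        assert valid.tolist() == [True, False]
        assert np.isnan(dff[1]).all()


def _tiny_recording(fs=4.0):
    """One odour-to-visual transition with hand-placed epochs."""
    trials = pd.DataFrame([
        # odour block (block 0): three eligible odour trials
        dict(trial_index=0, block_index=0, block_type="ODOUR",
             transition_phase=False, t_start=0.0, visual_cue="VISUAL_1",
             visual_onset_s=0.5, visual_offset_s=2.3, licked_visual=False,
             odour_cue="ODOUR_1", odour_onset_s=4.3, licked_odour=True,
             relevant_correct=True),
        dict(trial_index=1, block_index=0, block_type="ODOUR",
             transition_phase=False, t_start=8.0, visual_cue="VISUAL_2",
             visual_onset_s=8.5, visual_offset_s=10.3, licked_visual=False,
             odour_cue="ODOUR_2", odour_onset_s=12.3, licked_odour=False,
             relevant_correct=True),
        dict(trial_index=2, block_index=0, block_type="ODOUR",
             transition_phase=False, t_start=16.0, visual_cue="VISUAL_1",
             visual_onset_s=16.5, visual_offset_s=18.3, licked_visual=False,
             odour_cue="ODOUR_1", odour_onset_s=20.3, licked_odour=True,
             relevant_correct=True),
        # visual block (block 1): prediction-error trial then V2 trials
        dict(trial_index=3, block_index=1, block_type="VISUAL",
             transition_phase=True, t_start=24.0, visual_cue="VISUAL_1",
             visual_onset_s=24.5, visual_offset_s=26.3, licked_visual=False,
             odour_cue="", odour_onset_s=np.nan, licked_odour=False,
             relevant_correct=False),
    ] + [
        dict(trial_index=4 + j, block_index=1, block_type="VISUAL",
             transition_phase=False, t_start=32.0 + 8.0 * j,
             visual_cue="VISUAL_2", visual_onset_s=32.5 + 8.0 * j,
             visual_offset_s=34.3 + 8.0 * j, licked_visual=False,
             odour_cue="", odour_onset_s=np.nan, licked_odour=False,
             relevant_correct=True)
        for j in range(12)
    ])
    n_frames = int(200 * fs)
    dff = np.zeros((1, n_frames))
    return trials, dff, fs


class TestEpochExtraction:
    def test_epoch_times_follow_stated_rules(self):
        trials, _, _ = _tiny_recording()
        spec = EpochSpec()
        (e,) = transition_epoch_times(trials, spec)
        assert e["pe_time"] == pytest.approx(26.3 + 2.0)
        assert e["odour_times"] == [4.3, 12.3, 20.3]  # all 3, up to 7 allowed
        # 12 V2 trials, last 10 of the block excluded -> trials 4 and 5 only
        assert e["no_odour_times"] == pytest.approx([34.3 + 2.0, 42.3 + 2.0])

    def test_licked_first_grating_drops_transition(self):
        trials, _, _ = _tiny_recording()
        trials.loc[3, "licked_visual"] = True
        (e,) = transition_epoch_times(trials, EpochSpec())
        assert e["pe_time"] is None

    def test_window_start_frame_index_oracle(self):
        trials, dff, fs = _tiny_recording()
        spec = EpochSpec()
        t_pe = 26.3 + 2.0
        i0 = int(round(t_pe * fs))
        n_win = _frames(spec.window_s, fs)
        dff[0, i0:i0 + n_win] = 2.0   # marker exactly in the epoch window
        rec = CalciumRecording(dff=dff, frame_rate=fs, trials=trials)
        er = epoch_responses(rec, spec)
        assert er.responses[0, 0, 0] == pytest.approx(2.0)
        assert er.responses[0, 1, 0] == pytest.approx(0.0)

    def test_seven_nearest_trials_cap(self):
        trials, dff, fs = _tiny_recording()
        extra = []
        for j in range(7):  # 7 more eligible odour trials before the others
            extra.append(dict(
                trial_index=-1, block_index=0, block_type="ODOUR",
                transition_phase=False, t_start=-80.0 + 8 * j,
                visual_cue="VISUAL_1", visual_onset_s=-79.5 + 8 * j,
                visual_offset_s=-77.7 + 8 * j, licked_visual=False,
                odour_cue="ODOUR_1", odour_onset_s=-75.7 + 8 * j,
                licked_odour=True, relevant_correct=True))
        trials2 = pd.concat([pd.DataFrame(extra), trials], ignore_index=True)
        trials2["trial_index"] = range(len(trials2))
        (e,) = transition_epoch_times(trials2, EpochSpec())
        assert len(e["odour_times"]) == 7
        # the 7 *nearest* the transition: the original three are kept
        assert e["odour_times"][-3:] == [4.3, 12.3, 20.3]


class TestClassifyNeurons:
    def _responses(self, rng, n, n_trans=20, pe=0.0, odour=0.0, no_odour=0.0):
        r = rng.normal(0, 1, (n, 3, n_trans))
        r[:, 0] += pe
        r[:, 1] += odour
        r[:, 2] += no_odour
        return r

    def test_planted_positive_neurons_recovered(self):
        rng = np.random.default_rng(2)
        r = self._responses(rng, 50, pe=3.0)
        cls = classify_neurons(r, alpha=0.05)
        assert (cls.labels == "prediction_error_positive").mean() >= 0.9

    def test_single_comparison_types(self):
        rng = np.random.default_rng(3)
        r_a = self._responses(rng, 40, odour=-3.0)   # differs from odour only
        assert (classify_neurons(r_a).labels == "type_A").mean() > 0.8
        r_b = self._responses(rng, 40, no_odour=-3.0)
        assert (classify_neurons(r_b).labels == "type_B").mean() > 0.8

    def test_null_dual_criterion_rate_below_two_percent(self):
        rng = np.random.default_rng(4)
        r = self._responses(rng, 1000)
        labels = classify_neurons(r, alpha=0.05).labels
        pe_rate = np.char.startswith(labels.astype(str),
                                     "prediction_error").mean()
        assert pe_rate <= 0.02

    def test_too_few_transitions_indeterminate(self):
        rng = np.random.default_rng(5)
        cls = classify_neurons(self._responses(rng, 5, n_trans=4))
        assert set(cls.labels) == {"indeterminate"}


class TestSustainedSignificance:
    fs = 10.0

    def test_identical_traces_empty_mask(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, (10, 50))
        mask = sustained_significance(a, a + rng.normal(0, 1e-12, a.shape),
                                      self.fs)
        assert not mask.any()

    @pytest.mark.parametrize("dur_frames, expect", [(6, True), (4, False)])
    def test_run_length_threshold(self, dur_frames, expect):
        # 6 frames at 10 Hz = 600 ms (> 500 ms); 4 frames = 400 ms
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.1, (12, 50))
        b = a.copy()
        b[:, 20:20 + dur_frames] += 5.0
        mask = sustained_significance(a, b, self.fs, alpha=0.01,
                                      min_duration_s=0.5)
        assert mask[20:20 + dur_frames].all() == expect
        assert mask.sum() == (dur_frames if expect else 0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sustained_significance(np.zeros((2, 10)), np.ones((2, 10)), 10.0)


class TestDecoding:
    def test_separable_and_shuffled(self):
        rng = np.random.default_rng(8)
        n_tr, n_nr, n_fr = 60, 40, 10
        y = np.array(["V"] * 30 + ["O"] * 30)
        X = rng.normal(0, 1, (n_tr, n_nr, n_fr))
        X[:30, :20, 5:] += 2.5
        X[30:, 20:, 5:] += 2.5
        res = decode_timecourse(X, y, seed=0)
        assert res.accuracy[5:].mean() >= 0.95
        assert res.accuracy.max() <= 1.0
        res0 = decode_timecourse(rng.normal(0, 1, X.shape),
                                 rng.permutation(y), seed=0)
        assert abs(res0.accuracy.mean() - 0.5) < 0.05

    def test_class_balancing_subsamples_larger_class(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (100, 10, 3))
        y = np.array(["A"] * 40 + ["B"] * 60)
        res = decode_timecourse(X, y, seed=0)
        assert res.class_size == 40

    def test_undersized_class_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            decode_timecourse(rng.normal(0, 1, (8, 5, 2)),
                              ["A"] * 4 + ["B"] * 4, n_folds=5)


class TestBootstrap:
    def test_degenerate_population(self):
        ci = bootstrap_proportion_ci(np.zeros(100), n_boot=1000)
        assert (ci.lower, ci.upper) == (0.0, 0.0)

    def test_percentile_levels(self):
        rng = np.random.default_rng(11)
        pop = (rng.random(2000) < 0.09).astype(float)
        ci = bootstrap_proportion_ci(pop, subset_n=410, n_boot=5000,
                                     level=0.99, reference=0.05, seed=3)
        assert ci.lower < pop.mean() < ci.upper
        # a much smaller reference proportion falls outside the interval
        assert ci.reference_outside

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            bootstrap_proportion_ci([0, 1], subset_n=5)
        with pytest.raises(ValueError):
            bootstrap_proportion_ci([0, 1], n_boot=10)


class TestEncodingModel:
    fs = 4.0

    def _regressors(self, T, rng):
        lick = (rng.random(T) < 0.05).astype(float)
        vis = np.zeros(T)
        vis[np.arange(20, T - 20, 40)] = 1.0
        run = np.clip(rng.normal(0, 1, T).cumsum() * 0.01 + 0.5, 0, None)
        return {"visual": vis, "lick": lick, "running": run}

    def test_design_matrix_shifts(self):
        reg = {"visual": np.eye(1, 50, 10).ravel(), "lick": np.zeros(50)}
        X, is_motor = build_design_matrix(reg, self.fs, motor_names=("lick",))
        fwd, back = _frames(2.0, self.fs), _frames(0.5, self.fs)
        assert X.shape[1] == (fwd + 1) + (fwd + back + 1)
        assert is_motor.sum() == fwd + back + 1
        # sensory copies shift the impulse forward in time only
        sensory = X[:, ~is_motor]
        assert sensory[10, 0] == 1.0 and sensory[10 + fwd, fwd] == 1.0

    def test_generative_recovery_and_null(self):
        rng = np.random.default_rng(12)
        T = 800
        reg = self._regressors(T, rng)
        kernel = np.exp(-np.arange(8) / 2.0)
        y = np.convolve(reg["lick"], kernel)[:T]  # noiseless lick neuron
        noise = rng.normal(0, 1, T)
        fit = fit_encoding_model(np.vstack([y, noise]), self.fs, reg,
                                 motor_names=("lick", "running"))
        assert fit.r2_full[0] >= 0.95
        assert fit.r2_full[1] <= 0.05
        # removing the motor regressors destroys the lick neuron's fit
        assert fit.delta_r2[0] > 0.5
        assert fit.penalty[0] in np.logspace(-2, 5, 36)
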