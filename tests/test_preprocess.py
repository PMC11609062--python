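"""Event detection, filtering, epoching, normalization, cycle tallies."""
import numpy as np
import pytest
from scipy import signal as sps

from emgsynergy import preprocess
from emgsynergy.exceptions import (
    EpochingError,
    EventDetectionError,
    NormalizationError,
    ParameterError,
)
from emgsynergy.types import CycleTensor, EmgRecording, EventTimes, MUSCLES

FS = 1111.0


def impulse_train(times_s, fs=FS, duration=None, amp=1.0):
    duration = duration or (max(times_s) + 1.0)
    x = np.zeros(int(duration * fs))
    x[(np.asarray(times_s) * fs).round().astype(int)] = amp
    return x


class TestDetectEvents:
    def test_impulse_train_recovered_at_beat_spacing(self):
        truth = 1.0 + 0.75 * np.arange(8)
        ev = preprocess.detect_events(impulse_train(truth), FS)
        assert len(ev) == 8
        np.testing.assert_allclose(ev.times_s, truth, atol=1.0 / FS)
        np.testing.assert_allclose(np.diff(ev.times_s), 0.75, atol=2.0 / FS)

    def test_all_zero_signal_raises(self):
        with pytest.raises(EventDetectionError):
            preprocess.detect_events(np.zeros(5000), FS)

    def test_empty_signal_rejected(self):
        with pytest.raises(ParameterError):
            preprocess.detect_events(np.array([]), FS)

    def test_full_recall_under_noise(self):
        # impulse train at SNR 20 (power ratio): every planted event found
        rng = np.random.default_rng(0)
        truth = 1.0 + 0.75 * np.arange(10)
        x = impulse_train(truth)
        noise_sigma = np.sqrt(np.mean(x**2) / 20.0)
        ev = preprocess.detect_events(x + rng.normal(0, noise_sigma, x.size), FS)
        # recall: every true event matched within 5 ms
        matched = [np.min(np.abs(ev.times_s - t)) < 0.005 for t in truth]
        assert all(matched)


class TestFilterEmg:
    def test_constant_channel_becomes_zero(self):
        rec = EmgRecording(np.full((10, 2000), 3.7))
        out = preprocess.filter_emg(rec)
        np.testing.assert_allclose(out.signals, 0.0, atol=1e-9)

    def test_passband_and_stopband_match_design_response(self):
        # oracle: the designed Butterworth magnitude response (squared for
        # the forward-backward pass)
        t = np.arange(0, 8.0, 1 / FS)
        for freq in (5.0, 100.0):
            x = np.sin(2 * np.pi * freq * t)
            rec = EmgRecording(np.tile(np.abs(x), (10, 1)))
            # feed the rectified sine directly through the low-pass helper to
            # isolate the filter from the rectification nonlinearity
            y = preprocess.lowpass(x, FS, 20.0)
            gain = np.max(np.abs(y[2000:-2000]))
            _, h = sps.sosfreqz(
                sps.butter(4, 20.0, btype="low", fs=FS, output="sos"), worN=[freq], fs=FS
            )
            assert gain == pytest.approx(np.abs(h[0]) ** 2, abs=0.02)
            if freq == 5.0:
                assert gain > 0.95
            else:
                assert gain < 0.01

    def test_offset_invariance_of_pipeline(self):
        # demeaning precedes rectification, so a constant offset drops out
        rng = np.random.default_rng(1)
        x = rng.random((10, 4000))
        a = preprocess.filter_emg(EmgRecording(x))
        b = preprocess.filter_emg(EmgRecording(x + 5.0))
        np.testing.assert_allclose(a.signals, b.signals, atol=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        rec = EmgRecording(np.zeros((10, 100)), fs_hz=30.0)
        with pytest.raises(ParameterError):
            preprocess.filter_emg(rec, cutoff_hz=20.0)


class TestEpochCycles:
    def test_window_sample_count_and_interpolation(self):
        # 1.5 s at 1111 Hz spans 1667 raw samples mapped onto 151 points
        assert int(round(1.5 * FS)) + 1 == 1667
        rng = np.random.default_rng(2)
        rec = EmgRecording(rng.random((10, int(3 * FS))))
        ev = EventTimes([1.5])
        res = preprocess.epoch_cycles(rec, ev)
        assert res.cycles.data.shape == (10, 151, 1)
        # oracle: direct interpolation of one channel
        t = np.arange(rec.n_samples) / FS
        grid = 1.5 + np.linspace(-0.75, 0.75, 151)
        expect = np.clip(np.interp(grid, t, rec.signals[3]), 0, None)
        np.testing.assert_allclose(res.cycles.data[3, :, 0], expect, atol=1e-12)

    def test_event_too_close_to_edge_dropped(self):
        rec = EmgRecording(np.ones((10, int(10 * FS))))
        res = preprocess.epoch_cycles(rec, EventTimes([0.1, 5.0]))
        assert res.n_dropped == 1
        assert res.cycles.n_cycles == 1

    def test_all_valid_events_kept(self):
        rec = EmgRecording(np.ones((10, int(6 * FS))))
        res = preprocess.epoch_cycles(rec, EventTimes([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.cycles.n_cycles == 5

    def test_no_valid_events_raises(self):
        rec = EmgRecording(np.ones((10, 200)))
        with pytest.raises(EpochingError):
            preprocess.epoch_cycles(rec, EventTimes([0.05]))


class TestNormalize:
    def _tensor_from_rows(self, rows):
        n = len(rows[0])
        assert n % 151 == 0 or n == 151
        data = np.tile(np.asarray(rows, dtype=float)[:, :, None], (1, 1, 1))
        # pad rows to 151 points by repeating the last value
        if data.shape[1] != 151:
            reps = int(np.ceil(151 / data.shape[1]))
            data = np.tile(data, (1, reps, 1))[:, :151, :]
        return CycleTensor(data, muscle_labels=MUSCLES[: data.shape[0]])

    def test_hand_example_range_then_unit_variance(self):
        row = np.array([2.0, 6.0, 10.0])
        x = np.tile(row, (10, 51))[:, :151]
        cycles = CycleTensor(x[:, :, None])
        norm = preprocess.normalize(cycles)
        ranged = (x[0] - 2.0) / 8.0  # [0, .5, 1] pattern
        np.testing.assert_allclose(
            norm.matrix[0], ranged / ranged.std(), atol=1e-12
        )
        assert np.var(norm.matrix[0]) == pytest.approx(1.0, abs=1e-9)

    def test_every_row_has_unit_variance(self, default_sim):
        norm = preprocess.normalize(default_sim.cycles_b)
        np.testing.assert_allclose(np.var(norm.matrix, axis=1), 1.0, atol=1e-9)

    def test_constant_row_raises_naming_the_muscle(self, default_sim):
        data = default_sim.cycles_b.data.copy()
        data[4] = 2.0  # TA
        with pytest.raises(NormalizationError, match="TA"):
            preprocess.normalize(CycleTensor(data))

    def test_denormalize_round_trip(self, default_sim):
        cycles = default_sim.cycles_b
        norm = preprocess.normalize(cycles)
        np.testing.assert_allclose(
            preprocess.denormalize(norm), cycles.flatten(), atol=1e-9
        )

    def test_literal_max_divisor_variant(self, default_sim):
        norm = preprocess.normalize(default_sim.cycles_b, divisor="max")
        np.testing.assert_allclose(np.var(norm.matrix, axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            preprocess.denormalize(norm), default_sim.cycles_b.flatten(), atol=1e-9
        )


class TestTallyCycles:
    def test_reported_trial_bookkeeping(self):
        # two 60-bar trials; 11 and 9 symptomatic downbeats; 3 artifact
        # exclusions among the asymptomatic beats -> 20 with / 97 without
        trials = [
            preprocess.TrialAnnotation(60, symptom_cycles=list(range(11))),
            preprocess.TrialAnnotation(
                60, symptom_cycles=list(range(9)), artifact_cycles=[20, 30, 40]
            ),
        ]
        assert preprocess.tally_cycles(trials) == (20, 97)

    def test_clean_trial(self):
        assert preprocess.tally_cycles([preprocess.TrialAnnotation(60)]) == (0, 60)

    def test_all_artifacts_excluded(self):
        t = preprocess.TrialAnnotation(5, artifact_cycles=[0, 1, 2, 3, 4])
        assert preprocess.tally_cycles([t]) == (0, 0)

    def test_symptom_artifact_conflict_resolved_as_artifact(self):
        t = preprocess.TrialAnnotation(3, symptom_cycles=[0], artifact_cycles=[0])
        assert preprocess.tally_cycles([t]) == (0, 2)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ParameterError):
            preprocess.TrialAnnotation(3, symptom_cycles=[3])
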