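"""Ground-truth generator: structure, noise scaling, sessions, round trips."""
from dataclasses import replace

import numpy as np
import pytest

import emgsynergy as es
from emgsynergy import nmf, preprocess
from emgsynergy.exceptions import ParameterError
from emgsynergy.synthetic import spec_from_dict, spec_to_dict
from emgsynergy.types import CONDITION_A, CONDITION_B


class TestDefaultSpec:
    def test_six_templates_per_condition(self):
        spec = es.default_spec()
        assert len(spec.templates(CONDITION_A)) == 6  # 5 shared + 1 specific
        assert len(spec.templates(CONDITION_B)) == 6

    def test_reported_cycle_counts(self):
        spec = es.default_spec()
        assert spec.n_cycles_a == 97
        assert spec.n_cycles_b == 20

    def test_symptomatic_override_shifts_dorsiflexor(self):
        spec = es.default_spec()
        by_name_a = {t.name: t for t in spec.templates(CONDITION_A)}
        by_name_b = {t.name: t for t in spec.templates(CONDITION_B)}
        da, db = by_name_a["dorsiflexion"], by_name_b["dorsiflexion"]
        assert db.peak_time_ms - da.peak_time_ms == pytest.approx(-100.0)
        assert db.amplitude / da.amplitude == pytest.approx(2.9)

    def test_without_mods_conditions_share_activations(self):
        spec = es.default_spec()
        spec = replace(spec, condition_mods={})
        a = {t.name: t for t in spec.templates(CONDITION_A)}
        b = {t.name: t for t in spec.templates(CONDITION_B)}
        for name in set(a) & set(b):
            assert a[name].peak_time_ms == b[name].peak_time_ms
            assert a[name].amplitude == b[name].amplitude

    def test_round_trips_through_dict(self):
        spec = es.default_spec(seed=5)
        spec2 = spec_from_dict(spec_to_dict(spec))
        assert spec2.seed == 5
        np.testing.assert_allclose(
            spec2.synergies_shared[0].weights, spec.synergies_shared[0].weights
        )
        sim1 = es.simulate_cycles(spec)
        sim2 = es.simulate_cycles(spec2)
        np.testing.assert_array_equal(sim1.cycles_a.data, sim2.cycles_a.data)


class TestSimulateCycles:
    def test_output_shapes_match_reported_design(self, default_sim):
        assert default_sim.cycles_a.data.shape == (10, 151, 97)
        assert default_sim.cycles_b.data.shape == (10, 151, 20)

    def test_all_values_nonnegative(self, default_sim):
        assert default_sim.cycles_a.data.min() >= 0
        assert default_sim.cycles_b.data.min() >= 0

    def test_reproducible_for_same_seed(self):
        s1 = es.simulate_cycles(es.default_spec(seed=3))
        s2 = es.simulate_cycles(es.default_spec(seed=3))
        np.testing.assert_array_equal(s1.cycles_b.data, s2.cycles_b.data)

    def test_noiseless_single_synergy_is_rank_one(self):
        syn = es.GroundTruthSynergy(
            "solo", np.eye(10)[0] * 0.8 + 0.2, -100.0, amplitude=1.0
        )
        spec = es.SyntheticSpec(
            synergies_shared=[syn], synergies_specific_a=[], synergies_specific_b=[],
            n_cycles_a=5, n_cycles_b=5, snr=None,
            cycle_amp_sigma=0.0, cycle_time_jitter_ms=0.0, seed=0,
        )
        sim = es.simulate_cycles(spec)
        M = sim.cycles_a.data[:, :, 0]
        assert np.linalg.matrix_rank(M, tol=1e-10) == 1

    def test_empirical_snr_near_requested(self):
        spec = replace(es.default_spec(seed=2), n_cycles_a=100)
        sim = es.simulate_cycles(spec)
        assert 8.0 <= sim.truth_a.snr_empirical <= 12.0

    def test_noiseless_ground_truth_reconstructs_exactly(self):
        spec = replace(
            es.default_spec(seed=4), snr=None, cycle_amp_sigma=0.0,
            cycle_time_jitter_ms=0.0,
        )
        sim = es.simulate_cycles(spec)
        recon = np.einsum("mk,ktc->mtc", sim.truth_b.W, sim.truth_b.C)
        assert nmf.vaf(
            sim.cycles_b.data.reshape(10, -1), recon.reshape(10, -1)
        ) == pytest.approx(100.0, abs=1e-9)

    def test_spec_with_no_synergies_rejected(self):
        with pytest.raises(ParameterError):
            spec = es.SyntheticSpec(
                synergies_shared=[], synergies_specific_a=[],
                synergies_specific_b=[], n_cycles_a=5, n_cycles_b=5, seed=0,
            )
            es.simulate_cycles(spec)

    def test_nmf_recovers_true_weights_noiselessly(self, tiny_spec):
        spec = replace(tiny_spec, snr=None, cycle_time_jitter_ms=0.0)
        sim = es.simulate_cycles(spec)
        S = nmf.extract(sim.cycles_a.flatten(), 3, seed=0)
        from emgsynergy.features import match_and_similarity

        _, r = match_and_similarity(sim.truth_a.W, S.W)
        assert np.all(r > 0.99)


class TestSimulateSession:
    def test_click_train_at_beat_period(self, tiny_spec):
        spec = replace(tiny_spec, n_cycles_a=4)
        sess = es.simulate_session(spec, beats_per_cycle=1)
        assert len(sess.click_times) == 4
        np.testing.assert_allclose(np.diff(sess.click_times.times_s), 0.75)

    def test_every_epoch_window_fits_in_recording(self, tiny_spec):
        sess = es.simulate_session(tiny_spec)
        assert sess.event_times.times_s[0] >= 0.75
        assert sess.event_times.times_s[-1] + 0.75 <= sess.recording.duration_s

    def test_zero_amplitude_noiseless_session_is_silent(self):
        syn = es.GroundTruthSynergy("mute", np.ones(10), 0.0, amplitude=0.0)
        spec = es.SyntheticSpec(
            synergies_shared=[syn], synergies_specific_a=[], synergies_specific_b=[],
            n_cycles_a=3, n_cycles_b=3, snr=None, seed=0,
        )
        sess = es.simulate_session(spec)
        assert np.all(sess.recording.signals == 0.0)

    def test_detected_clicks_at_beat_spacing(self, tiny_spec):
        sess = es.simulate_session(tiny_spec)
        ev = preprocess.detect_events(sess.click, sess.recording.fs_hz)
        np.testing.assert_allclose(np.diff(ev.times_s), 0.75, atol=2 / 1111.0)

    def test_round_trip_matches_cycle_level_output(self, tiny_spec):
        # session -> event detection -> filter -> epoch correlates with the
        # generator's own clean cycles
        sess = es.simulate_session(tiny_spec)
        clicks = preprocess.detect_events(sess.click, sess.recording.fs_hz)
        downbeats = preprocess.select_downbeats(clicks, every=4)
        filtered = preprocess.filter_emg(sess.recording)
        res = preprocess.epoch_cycles(filtered, downbeats)
        assert res.cycles.n_cycles == sess.clean_cycles.n_cycles
        for c in range(res.cycles.n_cycles):
            got = res.cycles.data[:, :, c].ravel()
            want = sess.clean_cycles.data[:, :, c].ravel()
            assert np.corrcoef(got, want)[0, 1] > 0.98

    def test_clean_cycles_match_simulate_cycles_for_same_seed(self, tiny_spec):
        sess = es.simulate_session(tiny_spec, condition=CONDITION_A)
        sim = es.simulate_cycles(tiny_spec)
        np.testing.assert_allclose(
            sess.clean_cycles.data, np.clip(sim.truth_a.clean, 0, None), atol=1e-12
        )
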