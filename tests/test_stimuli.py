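"""Ripple synthesis, staircase convergence, stimulus sets, trial schedules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import wmconn as w
from wmconn.stimuli import PROBE_TYPES, staircase_target_proportion


class TestRippleSynthesis:
    def test_sample_count(self):
        wave = w.synthesize_ripple(w.RippleSpec(omega=8.0), sample_rate=16000)
        assert len(wave) == 16000

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            w.synthesize_ripple(w.RippleSpec(omega=8.0), sample_rate=3000)

    def test_zero_depth_gives_flat_envelopes(self):
        # D = 0: every carrier has the constant envelope D0, so a single
        # carrier's analytic envelope is flat
        spec = w.RippleSpec(omega=8.0, depth=0.0, density=1, f_hi=400.0)
        wave = w.synthesize_ripple(spec, sample_rate=8000)
        env = np.abs(signal.hilbert(wave))
        mid = env[400:-400]  # hilbert edge effects
        assert mid.std() / mid.mean() < 0.01

    def test_zero_spectral_density_closed_form(self):
        # Omega = 0: the envelope is the same omega-Hz sinusoid in every band;
        # check one carrier against D0 + D*cos(2 pi omega t + psi)
        spec = w.RippleSpec(omega=4.0, Omega=0.0, depth=0.5, density=1,
                            f_hi=400.0, phase=0.3)
        sr = 8000
        wave = w.synthesize_ripple(spec, sample_rate=sr, peak_dbfs=0.0)
        env = np.abs(signal.hilbert(wave))
        t = np.arange(len(wave)) / sr
        expected = spec.base + spec.depth * np.cos(2 * np.pi * spec.omega * t + spec.phase)
        sl = slice(400, -400)
        rho = np.corrcoef(env[sl], expected[sl])[0, 1]
        assert rho > 0.99

    def test_envelope_drift_matches_omega_over_Omega(self):
        # omega=4, Omega=1: every band's envelope modulates at omega Hz and
        # its phase advances 2*pi*Omega per octave, i.e. the spectrogram
        # ridge drifts at omega/Omega = 4 octaves/s
        spec = w.RippleSpec(omega=4.0, Omega=1.0, depth=0.9, duration=2.0, seed=3)
        sr = 16000
        wave = w.synthesize_ripple(spec, sample_rate=sr)
        f, t, S = signal.spectrogram(wave, fs=sr, nperseg=256, noverlap=192)
        band = (f >= 1.2 * spec.f0) & (f <= 0.8 * spec.f_hi)
        fb, rows = f[band], S[band]
        frame_rate = 1.0 / (t[1] - t[0])
        freqs = np.fft.rfftfreq(rows.shape[1], d=1.0 / frame_rate)
        spectra = np.fft.rfft(rows - rows.mean(axis=1, keepdims=True), axis=1)
        # dominant temporal-envelope frequency = omega in every band
        peak_f = freqs[np.argmax(np.abs(spectra), axis=1)]
        assert np.median(peak_f) == pytest.approx(spec.omega, abs=0.3)
        # envelope phase vs octave position: slope 2*pi*Omega
        k = np.argmin(np.abs(freqs - spec.omega))
        octaves = np.log2(fb / spec.f0)
        phase = np.unwrap(np.angle(spectra[:, k]))
        slope = np.polyfit(octaves, phase, 1)[0]
        assert abs(slope) / (2 * np.pi) == pytest.approx(spec.Omega, rel=0.15)

    def test_deterministic_given_seed(self):
        spec = w.RippleSpec(omega=8.0, seed=42)
        w1 = w.synthesize_ripple(spec)
        w2 = w.synthesize_ripple(spec)
        assert np.array_equal(w1, w2)

    def test_wav_roundtrip(self, tmp_path):
        from scipy.io import wavfile

        wave = w.synthesize_ripple(w.RippleSpec(omega=8.0), sample_rate=16000)
        path = tmp_path / "ripple.wav"
        w.write_wav(path, wave, 16000)
        sr, data = wavfile.read(path)
        assert sr == 16000 and len(data) == len(wave)


class TestStaircase:
    def test_oracle_listener_descends_to_floor(self):
        # an always-correct listener drives the track monotonically down
        res = w.run_staircase(lambda x: 1.0, rule="2d1u", start_interval=1.0,
                              stop_reversals=4, max_trials=300, seed=0)
        track = res.track["interval"].to_numpy()
        assert np.all(np.diff(track) <= 0)
        assert not res.converged  # no reversals without errors

    def test_rule_targets(self):
        assert staircase_target_proportion("2d1u") == pytest.approx(0.7071, abs=1e-3)
        assert staircase_target_proportion("1d2u") == pytest.approx(0.2929, abs=1e-3)
        assert staircase_target_proportion("1d1u") == pytest.approx(0.5)

    def test_2down1up_converges_to_70_7_percent_point(self):
        # closed-form target of the transformed up-down rule vs simulation
        listener = w.LogisticListener(threshold=0.3, slope=0.06)
        target = listener.interval_at(staircase_target_proportion("2d1u"))
        res = w.run_staircase(
            listener, rule="2d1u", start_interval=1.0, initial_step=0.1,
            final_step=0.02, stop_reversals=220, averaged_reversals=200,
            max_trials=20000, seed=5,
        )
        assert res.converged
        assert res.jnd == pytest.approx(target, abs=0.03)

    def test_one_down_two_up_tracks_low_proportion(self):
        # 1-down/2-up as configured by default tracks the 29.3% point
        listener = w.LogisticListener(threshold=0.3, slope=0.06)
        target = listener.interval_at(staircase_target_proportion("1d2u"))
        res = w.run_staircase(
            listener, rule="1d2u", start_interval=1.0, initial_step=0.1,
            final_step=0.02, stop_reversals=220, averaged_reversals=200,
            max_trials=20000, seed=5,
        )
        assert res.jnd == pytest.approx(target, abs=0.03)

    def test_deterministic_given_seed(self):
        listener = w.LogisticListener()
        r1 = w.run_staircase(listener, seed=9)
        r2 = w.run_staircase(listener, seed=9)
        assert r1.jnd == r2.jnd
        assert r1.track.equals(r2.track)

    def test_nonconverging_track_flagged_not_raised(self):
        res = w.run_staircase(lambda x: 1.0, stop_reversals=50, max_trials=20, seed=0)
        assert not res.converged

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown staircase rule"):
            w.run_staircase(w.LogisticListener(), rule="3d1u")


class TestStimulusSet:
    def test_pool_and_class_counts(self):
        s = w.build_stimulus_set(jnd=0.2)
        assert len(s.pool) == 17
        assert len(s.class_pool_indices) == 6

    def test_class_grid_arithmetic(self):
        # classes at 1.5*JND spacing on the 0.5*JND pool grid -> indices 0,3,...,15
        s = w.build_stimulus_set(jnd=0.2)
        assert s.class_pool_indices == (0, 3, 6, 9, 12, 15)
        gaps = np.diff(s.class_log2v)
        assert np.allclose(gaps, 1.5 * 0.2)

    def test_pool_spacing_half_jnd(self):
        s = w.build_stimulus_set(jnd=0.3)
        assert np.allclose(np.diff(s.pool_log2v), 0.15)

    def test_lowest_velocity_is_4(self):
        s = w.build_stimulus_set(jnd=0.2)
        assert s.pool[0].omega == pytest.approx(4.0)

    def test_out_of_range_jnd_rejected(self):
        with pytest.raises(ValueError, match="admissible range"):
            w.build_stimulus_set(jnd=0.5)  # 4 * 2^(8*0.5) = 64 > 48 c/s
        with pytest.raises(ValueError):
            w.build_stimulus_set(jnd=-0.1)

    def test_irrelevant_offset_half_jnd(self):
        s = w.build_stimulus_set(jnd=0.2)
        for c in range(6):
            gap = math.log2(s.irrelevant_spec(c).omega) - math.log2(s.class_spec(c).omega)
            assert gap == pytest.approx(0.5 * 0.2)


class TestTrialSchedule:
    def test_trial_counts(self, schedule):
        assert len(schedule.trials) == 96
        assert all(len(schedule.run_trials(r)) == 24 for r in range(4))

    def test_probe_type_mix_50_25_25(self, schedule):
        counts = schedule.trials["probe_type"].value_counts()
        assert counts["match"] == 48
        assert counts["nonmatch_neither"] == 24
        assert counts["irrelevant_match"] == 24

    def test_cued_class_balanced_within_run(self, schedule):
        for r in range(4):
            hist = schedule.run_trials(r)["cued_class"].value_counts()
            assert sorted(hist) == [4] * 6

    def test_retrocue_position_balanced(self, schedule):
        for r in range(4):
            pos = schedule.run_trials(r)["retrocue_pos"]
            assert (pos == 1).sum() == (pos == 2).sum() == 12

    def test_uncued_class_balanced_and_distinct(self, schedule):
        for r in range(4):
            sub = schedule.run_trials(r)
            assert sorted(sub["uncued_class"].value_counts()) == [4] * 6
            assert (sub["uncued_class"] != sub["cued_class"]).all()

    def test_cued_item_at_retrocue_position(self, schedule):
        t = schedule.trials
        at_1 = t[t["retrocue_pos"] == 1]
        at_2 = t[t["retrocue_pos"] == 2]
        assert (at_1["item1_class"] == at_1["cued_class"]).all()
        assert (at_2["item2_class"] == at_2["cued_class"]).all()

    def test_probe_velocity_consistency(self, schedule):
        t = schedule.trials
        match = t[t["probe_type"] == "match"]
        irr = t[t["probe_type"] == "irrelevant_match"]
        neither = t[t["probe_type"] == "nonmatch_neither"]
        assert np.allclose(match["probe_log2v"], match["cued_log2v"])
        assert np.allclose(irr["probe_log2v"], irr["irrelevant_log2v"])
        assert (neither["probe_log2v"] != neither["cued_log2v"]).all()
        assert (neither["probe_log2v"] != neither["irrelevant_log2v"]).all()

    def test_events_table_structure(self, schedule):
        ev = schedule.events(0)
        assert set(ev["trial_type"]) == {
            "alert", "item1", "item2", "retrocue", "probe", "response_cue"
        }
        probes = ev[ev["trial_type"] == "probe"].sort_values("trial")
        cues = ev[ev["trial_type"] == "retrocue"].sort_values("trial")
        maintenance = probes["onset"].to_numpy() - (
            cues["onset"].to_numpy() + schedule.timing.retrocue_dur
        )
        assert np.allclose(maintenance, 15.0)

    def test_events_tsv_roundtrip(self, schedule, tmp_path):
        import pandas as pd

        path = tmp_path / "events.tsv"
        schedule.to_events_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == len(schedule.events())

    def test_deterministic_given_seed(self):
        s1 = w.generate_trial_schedule(seed=5)
        s2 = w.generate_trial_schedule(seed=5)
        assert s1.trials.equals(s2.trials)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="cannot satisfy"):
            w.generate_trial_schedule(trials_per_run=18)

    def test_invariants_hold_across_1000_seeds(self):
        stimset = w.build_stimulus_set(jnd=0.2)
        for seed in range(1000):
            sched = w.generate_trial_schedule(stimset, n_runs=1, seed=seed)
            sub = sched.trials
            assert len(sub) == 24
            assert sorted(sub["cued_class"].value_counts()) == [4] * 6
            assert sorted(sub["uncued_class"].value_counts()) == [4] * 6
            assert (sub["uncued_class"] != sub["cued_class"]).all()
            counts = sub["probe_type"].value_counts()
            assert counts["match"] == 12
            assert counts["nonmatch_neither"] == counts["irrelevant_match"] == 6
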