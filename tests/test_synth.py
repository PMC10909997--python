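"""Generators: n-back sequences, schedules, IPFM RR, ECG, behavior, TLX."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import welch

from hrvdt.ecg import RRSeries
from hrvdt.hrv import PowerSpectrum, band_powers, resample_tachogram
from hrvdt.synth import (ALL_CONDITIONS, TASK_ORDERS, AutonomicParams,
                         BehaviorParams, Condition, EffectMap, NoiseSpec,
                         TLXBase, build_run_schedule, gen_ecg,
                         gen_nback_sequence, gen_response_log, gen_rr_series,
                         gen_study_dataset, gen_tlx_response)


def lag_scan(letters, n_back):
    """Exhaustive-scan oracle: positions matching the letter n_back earlier."""
    return [i for i in range(n_back, len(letters))
            if letters[i] == letters[i - n_back]]


class TestNBackSequence:
    @pytest.mark.parametrize("n_back", [1, 2, 3])
    def test_exact_target_count_by_exhaustive_scan(self, n_back):
        for seed in range(50):
            t = gen_nback_sequence(n_back, 20, 5, seed=seed)
            assert len(lag_scan(t.letters, n_back)) == 5
            assert t.n_targets == 5
            assert [i for i, f in enumerate(t.target_flags) if f] == \
                lag_scan(t.letters, n_back)

    @given(st.integers(1, 4), st.integers(0, 6), st.integers(0, 2**31 - 1))
    def test_target_count_property(self, n_back, n_targets, seed):
        t = gen_nback_sequence(n_back, 20, n_targets, seed=seed)
        assert len(lag_scan(t.letters, n_back)) == n_targets

    def test_zero_targets_no_adjacent_repeats(self):
        t = gen_nback_sequence(1, 3, 0, seed=7)
        assert all(a != b for a, b in zip(t.letters, t.letters[1:]))

    def test_infeasible_constraints_raise(self):
        with pytest.raises(ValueError):
            gen_nback_sequence(3, 20, 18, seed=0)  # only 17 eligible slots
        with pytest.raises(ValueError):
            gen_nback_sequence(2, 20, 5, alphabet=("A",), seed=0)

    def test_onsets_follow_stimulus_timing(self):
        t = gen_nback_sequence(2, 20, 5, seed=0)
        assert t.stimulus_onsets == tuple(i * 2.0 for i in range(20))


class TestRunSchedule:
    @pytest.mark.parametrize("n_trials,per_trial,total", [
        (6, 50.0, 300.0),   # the 5-min run
        (1, 50.0, 50.0),
        (6, 48.0, 288.0),
    ])
    def test_total_duration(self, n_trials, per_trial, total):
        t = gen_nback_sequence(2, 20, 5, seed=1)
        sched = build_run_schedule(t, n_trials, per_trial)
        assert sched.total_duration == total
        starts = sched.trial_starts
        assert all(b > a for a, b in zip(starts, starts[1:]))

    def test_too_short_trial_duration_raises(self):
        t = gen_nback_sequence(2, 20, 5, seed=1)
        with pytest.raises(ValueError):
            build_run_schedule(t, 6, 30.0)


class TestIPFM:
    def test_unmodulated_metronome(self):
        rr = gen_rr_series(AutonomicParams(mean_rr=1000, a_lf=0, a_hf=0,
                                           jitter_sd=0, seed=0), 60.0)
        assert len(rr.beat_times) == 60
        np.testing.assert_allclose(rr.intervals, 1000.0, rtol=1e-9)

    def test_hf_modulation_concentrates_power(self):
        rr = gen_rr_series(AutonomicParams(mean_rr=800, a_lf=0.0, a_hf=0.05,
                                           jitter_sd=0, seed=4), 300.0)
        y = resample_tachogram(rr, 4.0)
        f, pxx = welch(y, fs=4.0, nperseg=256)
        fd = band_powers(PowerSpectrum(f, pxx, 0, 4.0))
        assert fd.nHF > 0.9
        assert abs(f[np.argmax(pxx)] - 0.25) < 0.02

    def test_determinism(self):
        p = AutonomicParams(seed=99)
        a, b = gen_rr_series(p, 120.0), gen_rr_series(p, 120.0)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AutonomicParams(a_lf=0.6, a_hf=0.5)
        with pytest.raises(ValueError):
            AutonomicParams(f_hf=0.1)


class TestSyntheticECG:
    def test_noise_free_r_peak_placement(self, clean_ecg, short_rr):
        fs = clean_ecg.fs
        for b in short_rr.beat_times:
            lo, hi = int((b - 0.05) * fs), int((b + 0.05) * fs)
            peak = (lo + np.argmax(clean_ecg.samples[lo:hi])) / fs
            assert abs(peak - b) <= 1.0 / fs

    def test_powerline_component_at_stated_frequency(self, short_rr):
        clean = gen_ecg(short_rr, 256.0, NoiseSpec())
        noisy = gen_ecg(short_rr, 256.0, NoiseSpec(powerline_amp=100.0))
        resid = noisy.samples - clean.samples
        f = np.fft.rfftfreq(len(resid), 1 / 256.0)
        peak_hz = f[np.argmax(np.abs(np.fft.rfft(resid)))]
        assert abs(peak_hz - 50.0) < 0.5

    def test_empty_rr_gives_zero_record(self):
        rec = gen_ecg(None, 256.0, NoiseSpec(), duration=3.0)
        assert rec.duration == pytest.approx(3.0)
        assert np.all(rec.samples == 0)

    def test_impossible_interval_raises(self):
        rr = RRSeries(np.array([0.0, 0.05, 0.10]), np.array([50.0, 50.0]))
        with pytest.raises(ValueError):
            gen_ecg(rr, 256.0)


class TestResponseLog:
    def test_degenerate_distribution_hits_all_targets(self):
        t = gen_nback_sequence(2, 20, 5, seed=0)
        base = BehaviorParams(rt_sigma=0.0, miss_prob=0.0, false_alarm_prob=0.0)
        log = gen_response_log(t, Condition(1, "none"), EffectMap.identity(),
                               seed=0, base=base)
        hits = [e for e in log.events if e.is_target and e.responded]
        assert len(hits) == 5
        assert all(e.rt_ms == pytest.approx(500.0) for e in hits)
        assert not any(e.responded for e in log.events if not e.is_target)

    def test_all_miss(self):
        t = gen_nback_sequence(2, 20, 5, seed=0)
        base = BehaviorParams(miss_prob=1.0)
        log = gen_response_log(t, Condition(1, "none"), EffectMap.identity(),
                               seed=0, base=base)
        assert not any(e.responded for e in log.events if e.is_target)

    def test_loaded_condition_lengthens_mean_rt(self):
        effects = EffectMap.default()
        t = gen_nback_sequence(1, 20, 5, seed=0)
        t3 = gen_nback_sequence(3, 20, 5, seed=0)
        rts = {"low": [], "high": []}
        for seed in range(1000):
            lo = gen_response_log(t, Condition(1, "none"), effects, seed=seed)
            hi = gen_response_log(t3, Condition(3, "high"), effects, seed=seed)
            rts["low"] += [e.rt_ms for e in lo.events if e.is_target and e.responded]
            rts["high"] += [e.rt_ms for e in hi.events if e.is_target and e.responded]
        assert np.mean(rts["high"]) > np.mean(rts["low"])


class TestTLXGeneration:
    def test_zero_noise_midpoint(self):
        base = TLXBase(means={d: 10.0 for d in
                              ("mental", "physical", "temporal",
                               "performance", "effort", "frustration")},
                       rating_sd=0.0)
        resp = gen_tlx_response(Condition(1, "none"), EffectMap.identity(),
                                seed=0, base=base)
        assert all(r == 10 for r in resp.ratings.values())

    def test_determinism(self):
        a = gen_tlx_response(Condition(2, "medium"), EffectMap.default(), seed=5)
        b = gen_tlx_response(Condition(2, "medium"), EffectMap.default(), seed=5)
        assert a == b

    def test_high_load_raises_mean_total(self):
        from hrvdt.taskload import score_tlx
        effects = EffectMap.default()
        lo = [score_tlx(gen_tlx_response(Condition(1, "none"), effects, seed=s))
              for s in range(500)]
        hi = [score_tlx(gen_tlx_response(Condition(3, "high"), effects, seed=s))
              for s in range(500)]
        assert np.mean(hi) > np.mean(lo)


class TestStudyDataset:
    def test_structure_and_counterbalancing(self):
        ds = gen_study_dataset(7, EffectMap.identity(), seed=2)
        assert len(ds.subjects) == 7
        sizes = np.bincount([s.subgroup for s in ds.subjects], minlength=3)
        assert sizes.max() - sizes.min() <= 1
        for s in ds.subjects:
            assert set(s.conditions) == set(ALL_CONDITIONS)
            assert s.task_order == TASK_ORDERS[s.subgroup]

    def test_minimal_rotation_uses_each_order_once(self):
        ds = gen_study_dataset(3, EffectMap.identity(), seed=0)
        assert sorted(s.task_order for s in ds.subjects) == sorted(TASK_ORDERS)

    def test_subject_random_effects_shared_across_conditions(self):
        ds = gen_study_dataset(2, EffectMap.identity(), seed=1)
        # identity map: within a subject, all 9 mean RRs share one baseline
        for s in ds.subjects:
            means = [np.mean(c.rr.intervals) for c in s.conditions.values()]
            assert np.ptp(means) < 50  # far below the 50 ms between-subject sd
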