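import numpy as np
import pytest

from multistress.schedule import StressState, Segment, StressorSchedule, make_protocol_schedule
from multistress.simulate import (
    CortisolResponse,
    EffectProfile,
    SamplingRates,
    SubjectVariability,
    beat_times_from_hr,
    cortisol_concentration,
    default_effect_profiles,
    read_cohort,
    simulate_cohort,
    simulate_cortisol,
    simulate_ecg,
    simulate_gsr,
    simulate_rap,
    write_cohort,
)


class TestEcg:
    def test_beat_count_at_sixty_bpm(self):
        ecg = simulate_ecg(60, 60, 128, 0.0, 0)
        # R peaks are exact sample maxima of the template
        from multistress.features import detect_r_peaks

        assert 59 <= len(detect_r_peaks(ecg)) <= 61

    def test_mean_rr_matches_hr_within_one_percent(self):
        for hr in (55, 90, 150):
            beats = beat_times_from_hr(120, hr)
            assert np.mean(np.diff(beats)) == pytest.approx(60.0 / hr, rel=0.01)

    def test_determinism_same_seed(self):
        a = simulate_ecg(30, 80, 128, 0.05, 9)
        b = simulate_ecg(30, 80, 128, 0.05, 9)
        assert np.array_equal(a.samples, b.samples)

    def test_hr_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_ecg(10, 25, 128, 0, 0)
        with pytest.raises(ValueError):
            simulate_ecg(10, 230, 128, 0, 0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_ecg(10, 60, 32, 0, 0)


class TestGsr:
    def test_zero_rate_equals_tonic(self):
        ch = simulate_gsr(30, 5.0, 0.0, 0.3, 0)
        assert np.ptp(ch.samples) < 1e-12

    def test_poisson_mean_event_count(self):
        counts = [
            len(simulate_gsr(600, 5.0, 6.0, 0.3, s, return_events=True)[1])
            for s in range(40)
        ]
        # 40 draws of Poisson(60): SE of the mean ~ sqrt(60/40) ~ 1.2
        assert np.mean(counts) == pytest.approx(60.0, abs=4)

    def test_negative_tonic_rejected(self):
        with pytest.raises(ValueError):
            simulate_gsr(10, -1.0, 1.0, 0.3, 0)

    def test_determinism(self):
        a = simulate_gsr(60, 5.0, 6.0, 0.3, 4)
        b = simulate_gsr(60, 5.0, 6.0, 0.3, 4)
        assert np.array_equal(a.samples, b.samples)


class TestRap:
    def test_flat_when_amplitude_zero(self):
        ch = simulate_rap(30, 60, 150.0, 0.0, 0)
        assert np.ptp(ch.samples) == 0

    def test_shared_beat_clock_with_ecg(self):
        hr = np.linspace(60, 100, 60)
        assert np.array_equal(beat_times_from_hr(60, hr), beat_times_from_hr(60, hr))


class TestCortisol:
    def test_circadian_endpoints(self):
        sched = StressorSchedule((Segment(0, 600, StressState.REST),))
        ch = simulate_cortisol(sched, circadian=(105.0, 79.0), sample_every_s=60)
        assert ch.values[0] == pytest.approx(105.0)
        assert ch.values[-1] == pytest.approx(79.0)

    def test_quiz_profile_peaks_at_printed_maximum(self):
        sched = make_protocol_schedule(1, 600, 600)
        t = np.arange(0, 1800.0)
        c = cortisol_concentration(t, sched, circadian=(86.0, 86.0))
        assert c.max() == pytest.approx(113.0, abs=0.01)

    def test_stressor_response_lags_by_sweat_transport_delay(self):
        sched = make_protocol_schedule(1, 600, 600)
        t = np.arange(0, 1800.0)
        c = cortisol_concentration(t, sched, circadian=(86.0, 86.0), lag_s=300.0)
        # stressor starts at 600 s; nothing should move before 600 + 300 s
        assert np.allclose(c[t < 900], 86.0)
        assert c[t == 950] > 86.0

    def test_sample_spacing(self):
        sched = StressorSchedule((Segment(0, 600, StressState.REST),))
        ch = simulate_cortisol(sched, sample_every_s=60)
        assert np.allclose(np.diff(ch.times_s), 60.0)

    def test_sub_incubation_spacing_warns(self):
        sched = StressorSchedule((Segment(0, 600, StressState.REST),))
        with pytest.warns(UserWarning, match="incubation"):
            simulate_cortisol(sched, sample_every_s=30)

    def test_values_within_sensed_range(self):
        sched = make_protocol_schedule(5, 600, 600)
        ch = simulate_cortisol(sched, noise_sd=5.0, seed=0)
        assert np.all(ch.values >= 1.0) and np.all(ch.values <= 10_000.0)


class TestEffectProfiles:
    def test_default_profiles_cover_all_states(self):
        profiles = default_effect_profiles()
        assert set(profiles) == set(StressState)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            EffectProfile(scr_rate_per_min=-1.0)

    def test_cortisol_outside_sensed_range_rejected(self):
        with pytest.raises(ValueError):
            EffectProfile(cortisol=CortisolResponse(baseline_nM=0.5))


class TestCohort:
    def test_cohort_shape_and_subject_ids(self, tiny_cohort):
        assert len(tiny_cohort) == 6
        assert len({r.subject_id for r in tiny_cohort}) == 3

    def test_determinism_bit_identical(self, tiny_rates):
        sched = make_protocol_schedule(1, 30, 30)
        a = simulate_cohort(2, 1, sched, rates=tiny_rates, seed=5)
        b = simulate_cohort(2, 1, sched, rates=tiny_rates, seed=5)
        for ra, rb in zip(a, b):
            for name in ra.channels:
                va = getattr(ra.channels[name], "samples", None)
                vb = getattr(rb.channels[name], "samples", None)
                if va is None:
                    va, vb = ra.channels[name].values, rb.channels[name].values
                assert np.array_equal(va, vb)

    def test_rest_only_cohort_all_rest_labels(self, tiny_rates):
        sched = make_protocol_schedule(0, 60, 60)
        recs = simulate_cohort(1, 1, sched, rates=tiny_rates, seed=1)
        assert all(seg.label is StressState.REST for seg in recs[0].schedule.segments)

    def test_subject_effects_shared_across_sessions(self, tiny_rates):
        # noise off: the two sessions of a subject are identical, while
        # different subjects differ (between-subject effects persist)
        sched = make_protocol_schedule(1, 30, 30)
        recs = simulate_cohort(2, 2, sched, SubjectVariability.noiseless(), rates=tiny_rates, seed=3)
        by = {(r.subject_id, r.session_id): r for r in recs}
        s1a = by[("S01", "sess1")].channels["st"].samples
        s1b = by[("S01", "sess2")].channels["st"].samples
        assert np.array_equal(s1a, s1b)

    def test_physiological_ranges(self, tiny_cohort):
        for rec in tiny_cohort:
            st = rec.channels["st"].samples
            assert np.all(st > 25.0) and np.all(st < 40.0)
            cort = rec.channels["cortisol"].values
            assert np.all(cort >= 1.0) and np.all(cort <= 10_000.0)

    def test_cortisol_cadence_at_least_incubation_time(self, tiny_cohort):
        for rec in tiny_cohort:
            gaps = np.diff(rec.channels["cortisol"].times_s)
            assert np.all(gaps >= 60.0 - 1e-9)


class TestCohortIO:
    def test_round_trip(self, tmp_path, tiny_rates):
        sched = make_protocol_schedule(1, 30, 30)
        recs = simulate_cohort(2, 1, sched, rates=tiny_rates, seed=8)
        write_cohort(tmp_path / "cohort", recs)
        back = read_cohort(tmp_path / "cohort")
        assert len(back) == len(recs)
        for ra, rb in zip(recs, back):
            assert ra.subject_id == rb.subject_id
            assert rb.schedule == ra.schedule
            assert np.allclose(ra.channels["ecg"].samples, rb.channels["ecg"].samples)
            assert np.allclose(ra.channels["cortisol"].values, rb.channels["cortisol"].values)
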