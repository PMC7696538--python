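"""Generator contracts: spectra, coupling waveform, event bookkeeping,
cohort logs."""

import numpy as np
import pytest
from scipy.signal import periodogram

from lfpac import (
    SyntheticSpec,
    CohortSpec,
    generate_background,
    add_coupled_oscillations,
    inject_ied_events,
    generate_session,
    generate_seizure_log,
    seizure_log_frame,
    build_schedule,
    relative_band_power,
)
from lfpac.signals import SignalTrace, analytic_envelope, bandpass, instantaneous_phase
from lfpac.synth import imposed_theta_fraction


class TestBackground:
    def test_length_and_zero_mean(self):
        tr = generate_background(10, 5000, 1.0, 10.0, seed=1)
        assert tr.n_samples == 50_000
        assert abs(tr.samples.mean()) < 1e-9

    @pytest.mark.parametrize("beta", [0.5, 1.0, 1.5])
    def test_power_law_slope(self, beta):
        tr = generate_background(60, 1500, beta, 10.0, seed=4)
        f, p = periodogram(tr.samples, fs=1500)
        sel = (f >= 1) & (f <= 500)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-beta, abs=0.2)

    def test_rms_scaling_and_determinism(self):
        a = generate_background(20, 1000, 1.0, 35.0, seed=9)
        b = generate_background(20, 1000, 1.0, 35.0, seed=9)
        assert np.sqrt(np.mean(a.samples**2)) == pytest.approx(35.0, rel=1e-9)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("dur,fs", [(0, 1000), (-1, 1000), (10, 0)])
    def test_invalid_arguments(self, dur, fs):
        with pytest.raises(ValueError):
            generate_background(dur, fs)


class TestCoupledOscillations:
    def test_kappa_zero_constant_envelope(self):
        base = SignalTrace(samples=np.zeros(60_000), fs=1000)
        tr = add_coupled_oscillations(base, 2.5, 0.0, [(80.0, 10.0, 0.0)])
        env = analytic_envelope(bandpass(tr.samples, 1000, 60, 100))
        core = env[4000:-4000]  # trim filter edges
        assert np.std(core) / np.mean(core) < 0.05

    def test_kappa_one_envelope_peaks_at_phase_zero(self):
        base = SignalTrace(samples=np.zeros(120_000), fs=1000)
        tr = add_coupled_oscillations(base, 2.5, 20.0, [(80.0, 10.0, 1.0)])
        env = analytic_envelope(bandpass(tr.samples, 1000, 60, 100))
        phase = instantaneous_phase(bandpass(tr.samples, 1000, 1, 4))
        # envelope maxima coincide with delta phase 0 (within ±10 ms)
        t = np.arange(tr.n_samples) / 1000.0
        period = 1 / 2.5
        for k in range(5, 250, 40):
            t_peak = k * period  # cos(2π·2.5·t) = 1 at multiples of the period
            i = int(t_peak * 1000)
            w = env[i - 100 : i + 100]
            i_max = np.argmax(w) + i - 100
            assert abs(t[i_max] - t_peak) < 0.010
            assert abs(phase[i]) < 0.3

    def test_nyquist_carrier_rejected(self):
        base = SignalTrace(samples=np.zeros(1000), fs=1000)
        with pytest.raises(ValueError):
            add_coupled_oscillations(base, 2.5, 1.0, [(600.0, 1.0, 0.5)])

    def test_invalid_kappa_rejected(self):
        base = SignalTrace(samples=np.zeros(1000), fs=1000)
        with pytest.raises(ValueError):
            add_coupled_oscillations(base, 2.5, 1.0, [(80.0, 1.0, 1.5)])


class TestIEDInjection:
    def test_ground_truth_complete_and_inside_support(self):
        bg = generate_background(600, 1000, 1.0, 10.0, seed=5)
        out, truth = inject_ied_events(
            bg, {"spike": 3.61, "polyspike": 0.5, "sharp_wave": 0.5}, 8, seed=5
        )
        assert len(truth.ied_events) > 0
        for t_ev, sub, amp, dur in truth.ied_events:
            assert 0 <= t_ev < 600
            assert sub in ("spike", "polyspike", "sharp_wave")
        # event count is the ground-truth list length and roughly Poisson-mean
        n_spikes = sum(1 for e in truth.ied_events if e[1] == "spike")
        assert 36.1 - 4 * np.sqrt(36.1) < n_spikes < 36.1 + 4 * np.sqrt(36.1)

    def test_spike_widths_in_range(self):
        bg = generate_background(300, 1000, 1.0, 10.0, seed=6)
        _, truth = inject_ied_events(bg, {"spike": 4.0}, 8, seed=6)
        for _t, sub, _a, dur in truth.ied_events:
            assert sub == "spike" and 20.0 <= dur <= 70.0

    def test_zero_rates_leave_trace_unchanged(self):
        bg = generate_background(30, 1000, 1.0, 10.0, seed=7)
        out, truth = inject_ied_events(bg, {"spike": 0.0}, 8, seed=7)
        assert truth.ied_events == []
        assert np.array_equal(out.samples, bg.samples)

    def test_negative_rate_rejected(self):
        bg = generate_background(30, 1000, 1.0, 10.0, seed=8)
        with pytest.raises(ValueError):
            inject_ied_events(bg, {"spike": -1.0})


class TestSession:
    def test_determinism(self):
        spec = SyntheticSpec(duration_s=30, fs=500, seed=7)
        s1, t1 = generate_session(spec)
        s2, t2 = generate_session(spec)
        for ch in s1.traces:
            assert np.array_equal(s1.traces[ch].samples, s2.traces[ch].samples)
        assert t1.ied_events == t2.ied_events

    def test_independent_noise_shared_events(self):
        spec = SyntheticSpec(duration_s=30, fs=500, seed=7)
        sess, _ = generate_session(spec)
        l, r = sess.traces["left_hipp"].samples, sess.traces["right_hipp"].samples
        assert not np.array_equal(l, r)

    def test_schedule_longer_than_session_rejected(self):
        sched = build_schedule(n_trains=2, train_s=10, pause_s=30, pre_s=60, post_s=60)
        with pytest.raises(ValueError):
            generate_session(SyntheticSpec(duration_s=100, fs=500), sched)

    def test_post_train_theta_boost_measurable(self, dbs_session, short_schedule):
        sess, _ = dbs_session
        off = short_schedule.last_offset_s
        pre = sess.traces["left_hipp"].slice(short_schedule.first_onset_s - 30,
                                             short_schedule.first_onset_s)
        post = sess.traces["left_hipp"].slice(off, off + 30)
        assert relative_band_power(post) > relative_band_power(pre)

    def test_imposed_theta_fraction_parseval(self):
        # noiseless deterministic components: measured theta fraction of the
        # named-band total matches the analytic amplitude-squared bookkeeping
        spec = SyntheticSpec(
            duration_s=120, fs=1500, noise_scale=0.0, delta_freq_jitter=0.0,
            ied_rates={}, seed=1,
        )
        sess, truth = generate_session(spec)
        tr = sess.traces["left_hipp"]
        measured = relative_band_power(tr, "theta")
        assert measured == pytest.approx(truth.imposed_theta_fraction, abs=0.02)
        assert truth.imposed_theta_fraction == pytest.approx(
            imposed_theta_fraction(spec), rel=1e-12
        )


class TestCohort:
    def test_null_multipliers_give_null_change(self):
        cs = CohortSpec(
            n_animals=200, dbs_rate_multiplier=1.0, dbs_duration_multiplier=1.0,
            seed=3,
        )
        logs = generate_seizure_log(cs)
        changes = [lg.rate("before") - lg.rate("dbs") for lg in logs]
        se = np.std(changes) / np.sqrt(len(changes))
        assert abs(np.mean(changes)) < 3 * se + 1e-12

    def test_negative_slope_gives_negative_correlation(self):
        cs = CohortSpec(n_animals=200, pac_outcome_slope=-0.01, seed=4)
        logs = generate_seizure_log(cs)
        changes = [lg.rate("before") - lg.rate("dbs") for lg in logs]
        pac = [lg.pac_level for lg in logs]
        assert np.corrcoef(changes, pac)[0, 1] < 0

    def test_duration_scaling(self):
        cs = CohortSpec(
            n_animals=150, mean_duration_s=60.84, dbs_duration_multiplier=0.734,
            seed=5,
        )
        df = seizure_log_frame(generate_seizure_log(cs))
        mb = df[df.phase == "before"].duration_s.mean()
        md = df[df.phase == "dbs"].duration_s.mean()
        assert mb == pytest.approx(60.84, rel=0.05)
        assert md / mb == pytest.approx(0.734, rel=0.1)

    def test_grades_in_quantified_range(self):
        df = seizure_log_frame(generate_seizure_log(CohortSpec(n_animals=20, seed=6)))
        assert df.racine_grade.between(3, 6).all()

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_animals=1)
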