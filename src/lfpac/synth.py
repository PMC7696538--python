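"""Synthetic LFP sessions and cohort seizure logs with known ground truth.

The generator emulates the statistical structure the analysis assumes in a
chronically epileptic rat's hippocampal LFP:

* a 1/f^β broadband background, synthesized in the frequency domain with
  random phases (β = 1 by default, flattened below 1 Hz to avoid unbounded
  drift);
* a delta rhythm (1–4 Hz) whose phase modulates the amplitude of one or
  more fast carriers (30–600 Hz) through a normalized envelope
  ``(1 + κ·cos φδ)/(1 + κ)`` with modulation depth κ ∈ [0, 1] — the peak
  envelope is κ-independent, so coupling strength varies without changing
  band power;
* a theta rhythm (4–12 Hz) whose amplitude can step up after the last
  stimulation train (the short-term theta amplification the analysis is
  designed to detect), while κ can simultaneously step down;
* interictal discharges of three subtypes (spike 20–70 ms, sharp wave
  70–200 ms, polyspike = 2–4 spikes inside 500 ms counted as one event)
  injected at Poisson rates with amplitude parameterized as a multiple of
  the background SD;
* a cohort seizure log with Poisson daily counts before/during DBS,
  lognormal durations, and a latent per-animal PAC level linearly tied to
  the realized seizure-rate change.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import SignalTrace, RecordingSession
from .session import StimulationSchedule

IED_SUBTYPES = ("spike", "polyspike", "sharp_wave")

#: nominal template width ranges per subtype, milliseconds
SPIKE_WIDTH_MS = (20.0, 70.0)
SHARP_WAVE_WIDTH_MS = (70.0, 200.0)
POLYSPIKE_SPAN_MS = 500.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic LFP channel/session.

    ``coupling`` lists ``(fA_carrier_hz, fA_amp_uv, kappa)`` triples; κ is
    the delta-phase modulation depth of that carrier's envelope.
    ``post_theta_multiplier`` and ``post_kappa_multiplier`` rescale the
    theta amplitude and every κ after the last stimulation train, emulating
    the post-stimulation state.
    """

    duration_s: float = 1700.0
    fs: float = 5000.0
    noise_exponent: float = 1.0
    noise_scale: float = 50.0
    delta_freq: float = 2.5
    delta_freq_jitter: float = 0.3
    delta_amp: float = 40.0
    theta_freq: float = 7.0
    theta_amp: float = 30.0
    coupling: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(80.0, 8.0, 0.8)]
    )
    ied_rates: dict[str, float] = field(
        default_factory=lambda: {"spike": 2.6, "polyspike": 0.4, "sharp_wave": 0.6}
    )
    ied_amp_sd_multiple: float = 6.0
    post_theta_multiplier: float = 1.0
    post_kappa_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        for f_c, _amp, kappa in self.coupling:
            if not 0.0 <= kappa <= 1.0:
                raise ValueError(f"kappa must be in [0, 1], got {kappa}")
            if f_c >= self.fs / 2:
                raise ValueError(f"carrier {f_c} Hz at or above Nyquist")
        for sub, r in self.ied_rates.items():
            if r < 0:
                raise ValueError(f"negative IED rate for {sub}")


@dataclass
class GroundTruth:
    """What was actually injected, for validating the detectors.

    ``ied_events`` rows are ``(time_s, subtype, amplitude_uv, duration_ms)``
    with ``time_s`` the (first) peak time. ``imposed_theta_fraction`` is the
    analytic theta share of the noiseless deterministic components'
    mean-square power (Parseval bookkeeping).
    """

    ied_events: list[tuple[float, str, float, float]] = field(default_factory=list)
    imposed_couplings: list[tuple[float, float]] = field(default_factory=list)
    imposed_theta_fraction: float = 0.0


def _component_mean_squares(spec: SyntheticSpec) -> dict[str, float]:
    """Mean-square (time-averaged power) of each deterministic component."""
    out = {"delta": spec.delta_amp**2 / 2.0, "theta": spec.theta_amp**2 / 2.0}
    fast = 0.0
    for _f, amp, kappa in spec.coupling:
        # mean square of a·(1+κcosφ)/(1+κ)·cos(2πf t) over incommensurate φ
        fast += (amp**2 / 2.0) * (1.0 + kappa**2 / 2.0) / (1.0 + kappa) ** 2
    out["fast"] = fast
    return out


def imposed_theta_fraction(spec: SyntheticSpec) -> float:
    ms = _component_mean_squares(spec)
    total = sum(ms.values())
    return ms["theta"] / total if total > 0 else 0.0


def generate_background(
    duration_s: float,
    fs: float = 5000.0,
    noise_exponent: float = 1.0,
    noise_scale: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> SignalTrace:
    """Power-law (1/f^β) background noise, synthesized spectrally.

    Fourier amplitudes follow ``f^(−β/2)`` (flat below 1 Hz), phases are
    uniform; the output is demeaned and scaled to RMS ``noise_scale`` µV.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = np.maximum(freqs[nz], 1.0) ** (-noise_exponent / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= noise_scale / rms
    return SignalTrace(samples=x, fs=fs, channel="background")


def add_coupled_oscillations(
    trace: SignalTrace,
    delta_freq: float,
    delta_amp: float,
    couplings: list[tuple[float, float, float]],
    theta_freq: float | None = None,
    theta_amp: float = 0.0,
    theta_gain: np.ndarray | None = None,
    kappa_gain: np.ndarray | None = None,
    freq_jitter: float = 0.0,
    jitter_corr_s: float = 2.0,
    rng: np.random.Generator | None = None,
) -> SignalTrace:
    """Superimpose the delta rhythm, phase-coupled fast carriers, and theta.

    Adds ``delta_amp·cos(φδ(t))`` with ``φδ = 2π·delta_freq·t`` and, per
    coupling entry ``(f_c, a, κ)``,
    ``a·(1 + κ·cos φδ)/(1 + κ)·cos(2π f_c t)``. κ = 0 gives a constant
    envelope; κ = 1 a fully modulated one. ``theta_gain``/``kappa_gain`` are
    optional per-sample multipliers (used for post-train state changes).

    ``freq_jitter`` > 0 lets the delta frequency wander (an AR-smoothed
    deviation with SD ``freq_jitter`` Hz and correlation time
    ``jitter_corr_s``), emulating the irregular period of in-vivo delta; a
    strictly periodic rhythm is both unrealistic and invisible to
    circular-shift surrogate testing.
    """
    fs = trace.fs
    for f_c, _a, kappa in couplings:
        if f_c >= fs / 2:
            raise ValueError(f"carrier {f_c} Hz at or above Nyquist {fs / 2} Hz")
        if not 0.0 <= kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {kappa}")
    t = np.arange(trace.n_samples) / fs
    if freq_jitter > 0:
        from scipy import signal as _sps

        rng = rng or np.random.default_rng(0)
        alpha = 1.0 / (jitter_corr_s * fs)
        w = rng.standard_normal(trace.n_samples)
        df = _sps.lfilter([alpha], [1.0, -(1.0 - alpha)], w)
        sd = np.std(df)
        if sd > 0:
            df *= freq_jitter / sd
        inst_f = np.clip(delta_freq + df, 0.2, None)
        phi = 2.0 * np.pi * np.cumsum(inst_f) / fs
    else:
        phi = 2.0 * np.pi * delta_freq * t
    x = trace.samples + delta_amp * np.cos(phi)
    for f_c, a, kappa in couplings:
        k = kappa if kappa_gain is None else np.clip(kappa * kappa_gain, 0.0, 1.0)
        env = (1.0 + k * np.cos(phi)) / (1.0 + k)
        x = x + a * env * np.cos(2.0 * np.pi * f_c * t)
    if theta_freq is not None and theta_amp > 0:
        g = 1.0 if theta_gain is None else theta_gain
        x = x + theta_amp * g * np.cos(2.0 * np.pi * theta_freq * t)
    return SignalTrace(samples=x, fs=fs, channel=trace.channel, t0=trace.t0)


def _hann_bump(width_s: float, fs: float) -> np.ndarray:
    """Unit-amplitude raised-cosine deflection of nominal width ``width_s``.

    Its full width at half maximum is width/2, so twice the measured FWHM
    recovers the nominal width — the convention the detector uses.
    """
    n = max(3, int(round(width_s * fs)))
    return np.hanning(n)


def _render_ied_events(
    n: int,
    fs: float,
    ied_rates: dict[str, float],
    amp: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    """Render Poisson IED trains into an events-only array (negative bumps)."""
    x = np.zeros(n)
    duration_s = n / fs
    dur_min = duration_s / 60.0
    margin = 0.6  # keep templates (incl. polyspike span) inside the trace
    truth = GroundTruth()

    def _place(center_s: float, width_ms: float) -> None:
        bump = _hann_bump(width_ms / 1e3, fs) * amp
        i0 = int(round(center_s * fs)) - bump.size // 2
        x[i0 : i0 + bump.size] -= bump

    for sub in IED_SUBTYPES:
        rate = float(ied_rates.get(sub, 0.0))
        n_ev = rng.poisson(rate * dur_min) if duration_s > 2 * margin else 0
        times = np.sort(rng.uniform(margin, duration_s - margin, n_ev))
        for t_ev in times:
            if sub == "spike":
                w = float(rng.uniform(*SPIKE_WIDTH_MS))
                _place(t_ev, w)
                truth.ied_events.append((float(t_ev), sub, amp, w))
            elif sub == "sharp_wave":
                w = float(rng.uniform(*SHARP_WAVE_WIDTH_MS))
                _place(t_ev, w)
                truth.ied_events.append((float(t_ev), sub, amp, w))
            else:  # polyspike: 2–4 spike deflections within 500 ms, ONE event
                n_pk = int(rng.integers(2, 5))
                widths = rng.uniform(*SPIKE_WIDTH_MS, n_pk)
                span_s = float(rng.uniform(0.25, POLYSPIKE_SPAN_MS / 1e3 - 0.05))
                offs = np.linspace(0.0, span_s, n_pk)
                for off, w in zip(offs, widths):
                    _place(t_ev + off, float(w))
                truth.ied_events.append(
                    (float(t_ev), sub, amp, span_s * 1e3 + float(widths[-1]))
                )
    truth.ied_events.sort(key=lambda e: e[0])
    return x, truth


def inject_ied_events(
    trace: SignalTrace,
    ied_rates: dict[str, float],
    ied_amp_sd_multiple: float = 6.0,
    seed: int | np.random.Generator = 0,
    background_sd: float | None = None,
) -> tuple[SignalTrace, GroundTruth]:
    """Inject Poisson trains of interictal discharges; return trace + truth.

    Event times per subtype follow a homogeneous Poisson process; spikes
    are 20–70 ms negative deflections, sharp waves 70–200 ms, and a
    polyspike is 2–4 spike deflections inside 500 ms counted as ONE event.
    Amplitude is ``ied_amp_sd_multiple`` × the background SD (robust MAD
    estimate of the input trace unless given).
    """
    for sub, r in ied_rates.items():
        if r < 0:
            raise ValueError(f"negative rate for {sub!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if background_sd is None:
        med = np.median(trace.samples)
        background_sd = 1.4826 * np.median(np.abs(trace.samples - med))
    amp = ied_amp_sd_multiple * background_sd
    ev, truth = _render_ied_events(trace.n_samples, trace.fs, ied_rates, amp, rng)
    out = SignalTrace(
        samples=trace.samples + ev, fs=trace.fs, channel=trace.channel, t0=trace.t0
    )
    return out, truth


def generate_session(
    spec: SyntheticSpec,
    schedule: StimulationSchedule | None = None,
    animal_id: str = "synt01",
    group: str = "DBS-Pilo",
    day_index: int = 1,
    include_epidural: bool = False,
) -> tuple[RecordingSession, GroundTruth]:
    """Assemble a full multichannel session with shared ground truth.

    Left and right hippocampal channels carry the same deterministic
    components and IED times but independent background noise (seeds spawned
    from ``spec.seed``). After the last train, theta amplitude and κ are
    rescaled by the spec's post-train multipliers.
    """
    if schedule is not None and schedule.total_duration_s > spec.duration_s + 1e-9:
        raise ValueError(
            f"schedule ({schedule.total_duration_s:.1f} s) longer than the "
            f"session ({spec.duration_s:.1f} s)"
        )
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(5)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    theta_gain = np.ones(n)
    kappa_gain = np.ones(n)
    if schedule is not None:
        post = t >= schedule.last_offset_s
        theta_gain[post] = spec.post_theta_multiplier
        kappa_gain[post] = spec.post_kappa_multiplier

    # shared event stream rendered once, added to both hippocampal channels;
    # amplitude is relative to the composite background RMS (noise + rhythms),
    # which is known analytically for the generated components
    composite_sd = float(
        np.sqrt(spec.noise_scale**2 + sum(_component_mean_squares(spec).values()))
    )
    ev_rng = np.random.default_rng(child[2])
    events, ev_truth = _render_ied_events(
        n, spec.fs, spec.ied_rates, spec.ied_amp_sd_multiple * composite_sd, ev_rng
    )
    truth = GroundTruth(
        ied_events=ev_truth.ied_events,
        imposed_couplings=[(f, k) for f, _a, k in spec.coupling],
        imposed_theta_fraction=imposed_theta_fraction(spec),
    )
    traces = {}
    for ch, seedseq in (("left_hipp", child[0]), ("right_hipp", child[1])):
        bg = generate_background(
            spec.duration_s,
            spec.fs,
            spec.noise_exponent,
            spec.noise_scale,
            np.random.default_rng(seedseq),
        )
        tr = add_coupled_oscillations(
            bg,
            spec.delta_freq,
            spec.delta_amp,
            spec.coupling,
            theta_freq=spec.theta_freq,
            theta_amp=spec.theta_amp,
            theta_gain=theta_gain,
            kappa_gain=kappa_gain,
            freq_jitter=spec.delta_freq_jitter,
            rng=np.random.default_rng(child[4]),  # same delta phase both sides
        )
        tr = SignalTrace(samples=tr.samples + events, fs=spec.fs, channel=ch)
        traces[ch] = tr
    if include_epidural:
        ep_rng = np.random.default_rng(child[3])
        for ch in ("epidural_1", "epidural_2"):
            traces[ch] = generate_background(
                spec.duration_s, spec.fs, spec.noise_exponent,
                spec.noise_scale * 0.5, ep_rng,
            )
            traces[ch].channel = ch
    session = RecordingSession(
        traces=traces,
        animal_id=animal_id,
        group=group,
        day_index=day_index,
        schedule=schedule,
    )
    return session, truth


# --------------------------------------------------------------------------
# Cohort seizure logs
# --------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Design of a synthetic before/during-DBS cohort.

    Ten "before" days with daily seizure counts Poisson(``baseline``) are
    followed by ten "DBS" days at ``baseline × dbs_rate_multiplier``;
    durations are lognormal with the stated mean and coefficient of
    variation, scaled by ``dbs_duration_multiplier`` during DBS. Each animal
    carries a latent PAC level ``pac_base + pac_outcome_slope ×
    rate_change + noise`` tying coupling strength to its realized outcome.
    """

    n_animals: int = 9
    n_days: int = 10
    baseline_seizure_rate: float = 1.0
    dbs_rate_multiplier: float = 0.77
    mean_duration_s: float = 60.84
    dbs_duration_multiplier: float = 0.734
    duration_cv: float = 0.4
    pac_outcome_slope: float = -0.01
    pac_base: float = 0.02
    pac_noise_sd: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("cohort needs at least 2 animals")
        if min(self.dbs_rate_multiplier, self.dbs_duration_multiplier) <= 0:
            raise ValueError("multipliers must be positive")


@dataclass
class SeizureLog:
    """Behavioral seizures of one animal; entries are
    (day, phase, seizure_time_s, racine_grade, duration_s)."""

    animal_id: str
    entries: list[tuple[int, str, float, int, float]] = field(default_factory=list)
    pac_level: float = float("nan")

    def rate(self, phase: str, n_days: int = 10) -> float:
        return sum(1 for e in self.entries if e[1] == phase) / n_days

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.entries,
            columns=["day", "phase", "seizure_time_s", "racine_grade", "duration_s"],
        )
        df.insert(0, "animal_id", self.animal_id)
        return df


def generate_seizure_log(spec: CohortSpec) -> list[SeizureLog]:
    """Simulate the cohort's seizure diary with a latent PAC predictor."""
    rng = np.random.default_rng(spec.seed)
    sigma2 = np.log(1.0 + spec.duration_cv**2)
    sigma = np.sqrt(sigma2)
    logs: list[SeizureLog] = []
    for i in range(spec.n_animals):
        log = SeizureLog(animal_id=f"rat{i + 1:02d}")
        for phase, rate_mult, dur_mult in (
            ("before", 1.0, 1.0),
            ("dbs", spec.dbs_rate_multiplier, spec.dbs_duration_multiplier),
        ):
            lam = spec.baseline_seizure_rate * rate_mult
            for day in range(1, spec.n_days + 1):
                n_sz = rng.poisson(lam)
                for _ in range(n_sz):
                    mu = np.log(spec.mean_duration_s * dur_mult) - sigma2 / 2.0
                    dur = float(rng.lognormal(mu, sigma))
                    log.entries.append(
                        (
                            day,
                            phase,
                            float(rng.uniform(0.0, 86400.0)),
                            int(rng.integers(3, 7)),
                            dur,
                        )
                    )
        change = log.rate("before", spec.n_days) - log.rate("dbs", spec.n_days)
        log.pac_level = (
            spec.pac_base
            + spec.pac_outcome_slope * change
            + rng.normal(0.0, spec.pac_noise_sd)
        )
        logs.append(log)
    return logs


def seizure_log_frame(logs: list[SeizureLog]) -> pd.DataFrame:
    """Concatenate per-animal logs into the canonical CSV layout."""
    if not logs:
        return pd.DataFrame(
            columns=["animal_id", "day", "phase", "seizure_time_s",
                     "racine_grade", "duration_s"]
        )
    return pd.concat([lg.to_frame() for lg in logs], ignore_index=True)
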