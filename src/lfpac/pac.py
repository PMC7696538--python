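"""Time-resolved delta→fast-oscillation phase-amplitude coupling (tPAC).

For each sliding window (18 s, 50% overlap by default) the estimator

1. band-passes the window to the fast band of interest and locates the
   dominant modulated frequency fA* — the frequency of maximum spectral
   power inside the band;
2. re-filters the raw window narrowly around fA* (bandwidth at least twice
   the upper phase-band edge, so the modulation sidebands at fA* ± fP are
   kept) and takes the analytic-signal envelope A(t);
3. extracts the instantaneous delta phase φ(t) from the phase band
   (1–4 Hz by default);
4. computes the coupling as the normalized mean-vector length
   ``|⟨A·e^{iφ}⟩| / sqrt(⟨A²⟩)`` ∈ [0, 1], with the preferred phase the
   argument of the mean vector.

Two seconds of filter edge are trimmed from each window before averaging
(Hilbert edge artifacts at 1-Hz phase are substantial). MaxPAC is the
maximum over the fast-frequency grid of the across-window mean coupling,
ties broken toward the lowest frequency. A Kullback–Leibler modulation
index (phase-binned mean envelope against uniformity) is provided as an
independent cross-check, and circular-shift surrogates give a significance
threshold — the headline coupling values remain raw (un-normalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signals import SignalTrace, bandpass, analytic_envelope, instantaneous_phase
from .spectral import BandDefinition
from .session import Epoch, epoch_trace
from .signals import RecordingSession

DEFAULT_FP_BAND = BandDefinition("delta", 1.0, 4.0)
DEFAULT_FA_BANDS = (
    BandDefinition("gamma", 30.0, 100.0),
    BandDefinition("hfo", 100.0, 150.0),
    BandDefinition("ripple", 150.0, 250.0),
    BandDefinition("fast_ripple", 250.0, 600.0),
)
EDGE_TRIM_S = 2.0


@dataclass
class PACConfig:
    fp_band: BandDefinition = DEFAULT_FP_BAND
    fa_bands: tuple[BandDefinition, ...] = DEFAULT_FA_BANDS
    window_s: float = 18.0
    overlap: float = 0.5
    fa_grid_step_low: float = 2.0   # grid step below 150 Hz
    fa_grid_step_high: float = 5.0  # grid step at/above 150 Hz
    n_surrogates: int = 200

    def __post_init__(self) -> None:
        for b in self.fa_bands:
            if b.f_low <= self.fp_band.f_high:
                raise ValueError(
                    f"fast band {b.name} overlaps the phase band"
                )

    def fa_grid(self, band: BandDefinition) -> np.ndarray:
        step = self.fa_grid_step_low if band.f_low < 150 else self.fa_grid_step_high
        return np.arange(band.f_low, band.f_high + 1e-9, step)

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)


@dataclass
class PACResult:
    """tPAC output for one (epoch, channel, fast band)."""

    per_window: list[tuple[float, float, float, float]]  # (t_center, coupling, fA, phase)
    max_pac: float
    max_pac_fa: float
    fa_band: str = ""
    epoch: str = ""
    channel: str = ""
    comodulogram: np.ndarray | None = None

    @property
    def mean_coupling(self) -> float:
        return float(np.mean([w[1] for w in self.per_window]))


def n_windows(duration_s: float, window_s: float, overlap: float) -> int:
    """Full windows fitting a duration: floor((T − w)/hop) + 1."""
    hop = window_s * (1.0 - overlap)
    if duration_s < window_s:
        return 0
    return int(np.floor((duration_s - window_s) / hop + 1e-9)) + 1


def _coupling_stat(envelope: np.ndarray, phase: np.ndarray) -> tuple[float, float]:
    """Normalized mean-vector coupling and preferred phase.

    ``|⟨A e^{iφ}⟩| / sqrt(⟨A²⟩)`` is scale-invariant and ≤ 1 by
    Cauchy–Schwarz.
    """
    mv = np.mean(envelope * np.exp(1j * phase))
    rms = np.sqrt(np.mean(envelope**2))
    if rms == 0:
        return 0.0, 0.0
    return float(np.abs(mv) / rms), float(np.angle(mv))


def _narrowband_envelope(
    x: np.ndarray, fs: float, f_center: float, fp_high: float
) -> np.ndarray:
    """Envelope after a narrow band-pass around ``f_center``.

    Half-bandwidth is 1.5× the upper phase-band edge so both modulation
    sidebands survive the filter.
    """
    half_bw = 1.5 * fp_high
    lo = max(f_center - half_bw, 0.5 * f_center, fp_high + 1.0)
    hi = min(f_center + half_bw, fs / 2 * 0.999)
    return analytic_envelope(bandpass(x, fs, lo, hi))


def _dominant_frequency(
    x_band: np.ndarray, fs: float, band: BandDefinition
) -> float:
    """Frequency of maximum spectral power of a band-limited window."""
    freqs, pxx = sps.periodogram(x_band, fs=fs, window="hann")
    sel = (freqs >= band.f_low) & (freqs < band.f_high)
    if not np.any(sel):
        raise ValueError(f"band {band.name} empty at this resolution")
    return float(freqs[sel][np.argmax(pxx[sel])])


def _window_slices(n: int, fs: float, window_s: float, overlap: float):
    wlen = int(round(window_s * fs))
    hop = int(round(window_s * (1.0 - overlap) * fs))
    starts = range(0, n - wlen + 1, hop)
    return [(s, s + wlen) for s in starts]


def _snap_to_grid(f: float, grid: np.ndarray) -> float:
    return float(grid[np.argmin(np.abs(grid - f))])


def tpac(
    trace: SignalTrace,
    config: PACConfig | None = None,
    fa_band: BandDefinition | None = None,
) -> PACResult:
    """Time-resolved PAC between the delta phase and one fast band.

    Returns per-window couplings with each window's dominant fast
    frequency, and MaxPAC — the maximum over the fast-frequency grid of the
    across-window mean coupling (ties to the lowest frequency).
    """
    config = config or PACConfig()
    fa_band = fa_band or config.fa_bands[0]
    if fa_band.f_low <= config.fp_band.f_high:
        raise ValueError("fast band overlaps the phase band")
    fs = trace.fs
    if trace.duration_s < config.window_s:
        raise ValueError(
            f"trace ({trace.duration_s:.1f} s) shorter than one "
            f"{config.window_s}-s window"
        )
    x = trace.samples
    phase_full = instantaneous_phase(
        bandpass(x, fs, config.fp_band.f_low, config.fp_band.f_high)
    )
    broad = bandpass(x, fs, fa_band.f_low, min(fa_band.f_high, fs / 2 * 0.999))
    trim = int(round(EDGE_TRIM_S * fs))
    grid = config.fa_grid(fa_band)

    per_window = []
    for s, e in _window_slices(x.size, fs, config.window_s, config.overlap):
        f_dom = _dominant_frequency(broad[s:e], fs, fa_band)
        env = _narrowband_envelope(x[s:e], fs, f_dom, config.fp_band.f_high)
        sl = slice(trim, e - s - trim) if e - s > 2 * trim + 10 else slice(None)
        coupling, pref = _coupling_stat(env[sl], phase_full[s:e][sl])
        t_center = trace.t0 + (s + (e - s) / 2) / fs
        per_window.append((t_center, coupling, _snap_to_grid(f_dom, grid), pref))

    max_pac, max_fa = _max_over_grid(per_window)
    return PACResult(
        per_window=per_window,
        max_pac=max_pac,
        max_pac_fa=max_fa,
        fa_band=fa_band.name,
        channel=trace.channel,
    )


def _max_over_grid(per_window) -> tuple[float, float]:
    """MaxPAC: max over grid frequencies of the mean coupling of the windows
    whose dominant frequency landed there; ties toward low frequency."""
    by_f: dict[float, list[float]] = {}
    for _t, c, f, _p in per_window:
        by_f.setdefault(f, []).append(c)
    best_f, best = None, -1.0
    for f in sorted(by_f):
        m = float(np.mean(by_f[f]))
        if m > best + 1e-15:
            best, best_f = m, f
    return best, best_f


def comodulogram(
    trace: SignalTrace,
    fp_grid: np.ndarray,
    fa_grid: np.ndarray,
    config: PACConfig | None = None,
    fp_bw: float = 2.0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Coupling matrix over (phase frequency × fast frequency) grids.

    Cell (i, j) is the across-window mean coupling between the phase of the
    ``fp_grid[i] ± fp_bw/2`` band and the envelope at ``fa_grid[j]``.
    Returns the matrix and the (fp*, fa*) location of its maximum.
    """
    config = config or PACConfig()
    fp_grid = np.atleast_1d(np.asarray(fp_grid, dtype=float))
    fa_grid = np.atleast_1d(np.asarray(fa_grid, dtype=float))
    if fp_grid.size == 0 or fa_grid.size == 0:
        raise ValueError("empty frequency grid")
    fs = trace.fs
    x = trace.samples
    trim = int(round(EDGE_TRIM_S * fs))
    slices = _window_slices(x.size, fs, config.window_s, config.overlap)
    if not slices:
        raise ValueError("trace shorter than one window")

    phases = []
    for fp in fp_grid:
        lo = max(fp - fp_bw / 2, 0.3)
        phases.append(instantaneous_phase(bandpass(x, fs, lo, fp + fp_bw / 2)))
    envs = []
    fp_high = float(fp_grid.max() + fp_bw / 2)
    for fa in fa_grid:
        envs.append(_narrowband_envelope(x, fs, fa, fp_high))

    mat = np.zeros((fp_grid.size, fa_grid.size))
    for i, ph in enumerate(phases):
        for j, env in enumerate(envs):
            vals = []
            for s, e in slices:
                sl = slice(s + trim, e - trim) if e - s > 2 * trim + 10 else slice(s, e)
                c, _ = _coupling_stat(env[sl], ph[sl])
                vals.append(c)
            mat[i, j] = np.mean(vals)
    i_star, j_star = np.unravel_index(np.argmax(mat), mat.shape)
    return mat, (float(fp_grid[i_star]), float(fa_grid[j_star]))


def epoch_pac(
    session: RecordingSession,
    epochs: list[Epoch],
    config: PACConfig | None = None,
    epoch_labels: tuple[str, ...] = ("pre5", "post5"),
) -> pd.DataFrame:
    """tPAC for every (epoch, hippocampal channel, fast band) combination.

    With the default four fast bands and two epochs per channel this yields
    16 results per session: 2 epochs × 2 channels × 4 bands.
    """
    config = config or PACConfig()
    rows = []
    for ep in epochs:
        if ep.label not in epoch_labels:
            continue
        tr = epoch_trace(session, ep)
        for band in config.fa_bands:
            res = tpac(tr, config, band)
            rows.append(
                {
                    "animal_id": session.animal_id,
                    "day_index": session.day_index,
                    "epoch": ep.label,
                    "channel": ep.channel,
                    "fa_band": band.name,
                    "max_pac": res.max_pac,
                    "max_pac_fa": res.max_pac_fa,
                    "mean_coupling": res.mean_coupling,
                    "n_windows": len(res.per_window),
                }
            )
    return pd.DataFrame(rows)


def tort_mi_oracle(
    trace: SignalTrace,
    fp_band: BandDefinition = DEFAULT_FP_BAND,
    fa_band: BandDefinition = DEFAULT_FA_BANDS[0],
    n_bins: int = 18,
) -> float:
    """Kullback–Leibler modulation index: an independent PAC measure.

    The fast-band envelope is averaged inside ``n_bins`` phase bins and
    normalized to a distribution P; MI = KL(P‖uniform)/log(n_bins) ∈ [0, 1].
    """
    fs = trace.fs
    min_len = 10.0 / fp_band.f_low
    if trace.duration_s < min_len:
        raise ValueError(f"need ≥ {min_len:.0f} s (10 slow cycles)")
    phase = instantaneous_phase(bandpass(trace.samples, fs, fp_band.f_low, fp_band.f_high))
    env = analytic_envelope(
        bandpass(trace.samples, fs, fa_band.f_low, min(fa_band.f_high, fs / 2 * 0.999))
    )
    trim = int(round(EDGE_TRIM_S * fs))
    if trace.n_samples > 2 * trim + 10:
        phase, env = phase[trim:-trim], env[trim:-trim]
    if np.all(env == 0):
        raise ValueError("degenerate zero envelope: MI undefined")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    means = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        means[b] = env[sel].mean() if np.any(sel) else 0.0
    total = means.sum()
    if total == 0:
        raise ValueError("degenerate zero envelope: MI undefined")
    p = means / total
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n_bins)))
    return kl / np.log(n_bins)


def surrogate_threshold(
    trace: SignalTrace,
    config: PACConfig | None = None,
    fa_band: BandDefinition | None = None,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Circular-shift surrogate significance threshold for the coupling.

    The fast envelope is circularly shifted against the phase by uniform
    random offsets of at least one slow cycle; the (1 − alpha) quantile of
    the surrogate across-window mean couplings is returned.
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates")
    config = config or PACConfig()
    fa_band = fa_band or config.fa_bands[0]
    fs = trace.fs
    x = trace.samples
    phase_full = instantaneous_phase(
        bandpass(x, fs, config.fp_band.f_low, config.fp_band.f_high)
    )
    broad = bandpass(x, fs, fa_band.f_low, min(fa_band.f_high, fs / 2 * 0.999))
    trim = int(round(EDGE_TRIM_S * fs))
    pairs = []  # (envelope, phase) per window, trimmed
    for s, e in _window_slices(x.size, fs, config.window_s, config.overlap):
        f_dom = _dominant_frequency(broad[s:e], fs, fa_band)
        env = _narrowband_envelope(x[s:e], fs, f_dom, config.fp_band.f_high)
        sl = slice(trim, e - s - trim) if e - s > 2 * trim + 10 else slice(None)
        pairs.append((env[sl], phase_full[s:e][sl]))
    if not pairs:
        raise ValueError("trace shorter than one window")

    rng = np.random.default_rng(seed)
    min_shift = int(round(fs / config.fp_band.f_low))
    stats = np.empty(n_surrogates)
    for i in range(n_surrogates):
        vals = []
        for env, ph in pairs:
            hi = env.size - min_shift
            off = int(rng.integers(min_shift, max(hi, min_shift + 1)))
            c, _ = _coupling_stat(np.roll(env, off), ph)
            vals.append(c)
        stats[i] = np.mean(vals)
    if alpha >= 1.0:
        return float(stats.min())
    return float(np.quantile(stats, 1.0 - alpha))
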