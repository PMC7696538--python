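"""Core signal containers and band-limited filtering primitives.

A :class:`SignalTrace` is one channel of local field potential (LFP) in
microvolts with its sampling rate; a :class:`RecordingSession` bundles the
channels of one daily recording together with the animal's metadata and the
stimulation schedule. Time is expressed in seconds from recording start;
intervals are half-open ``[start, end)`` and the sample index of a time t is
``floor(t * fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import signal as sps

HIPPOCAMPAL_CHANNELS = ("left_hipp", "right_hipp")
EXPECTED_CHANNELS = ("left_hipp", "right_hipp", "epidural_1", "epidural_2")


@dataclass
class SignalTrace:
    """One channel of LFP samples.

    Parameters
    ----------
    samples : ndarray
        Signal in microvolts (µV).
    fs : float
        Sampling rate in Hz; the study's acquisition rate is 5 kHz.
    channel : str
        Channel label, e.g. ``"left_hipp"``.
    t0 : float
        Time of the first sample in seconds from recording start.
    """

    samples: np.ndarray
    fs: float
    channel: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def slice(self, start_s: float, end_s: float) -> "SignalTrace":
        """Return the half-open sub-trace ``[start_s, end_s)`` (recording time)."""
        if not (self.t0 <= start_s < end_s <= self.t0 + self.duration_s + 1e-9):
            raise ValueError(
                f"requested [{start_s}, {end_s}) outside trace support "
                f"[{self.t0}, {self.t0 + self.duration_s})"
            )
        i0 = int(np.floor((start_s - self.t0) * self.fs))
        i1 = int(np.floor((end_s - self.t0) * self.fs))
        return replace(self, samples=self.samples[i0:i1], t0=start_s)

    def copy(self) -> "SignalTrace":
        return replace(self, samples=self.samples.copy())


@dataclass
class RecordingSession:
    """A daily multichannel recording with metadata.

    ``traces`` maps channel labels to :class:`SignalTrace`; the analysis
    expects at least the two hippocampal depth channels. ``schedule`` is the
    day's stimulation schedule, or ``None`` for sham (unstimulated) sessions.
    """

    traces: Mapping[str, SignalTrace]
    animal_id: str = ""
    group: str = "DBS-Pilo"
    day_index: int = 1
    schedule: "object | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("session needs at least one trace")
        fss = {tr.fs for tr in self.traces.values()}
        ns = {tr.n_samples for tr in self.traces.values()}
        if len(fss) != 1 or len(ns) != 1:
            raise ValueError("all traces must share sampling rate and length")
        if not 1 <= int(self.day_index) <= 10:
            raise ValueError(f"day_index must be in [1, 10], got {self.day_index}")

    @property
    def fs(self) -> float:
        return next(iter(self.traces.values())).fs

    @property
    def duration_s(self) -> float:
        return next(iter(self.traces.values())).duration_s

    def hippocampal(self) -> dict[str, SignalTrace]:
        return {c: self.traces[c] for c in HIPPOCAMPAL_CHANNELS if c in self.traces}


def _fir_taps(fs: float, f_low: float, f_high: float, n_max: int) -> np.ndarray:
    """Linear-phase band-pass FIR kernel (Hamming-windowed sinc).

    The transition width scales with the lower band edge so that narrow
    low-frequency bands (delta at 1 Hz) get adequately steep filters without
    making fast-band kernels needlessly long.
    """
    nyq = fs / 2.0
    if not (0 < f_low < f_high):
        raise ValueError(f"invalid band [{f_low}, {f_high}) Hz")
    if f_high > nyq:
        raise ValueError(f"band edge {f_high} Hz exceeds Nyquist {nyq} Hz")
    trans = max(0.5, 0.25 * f_low)
    numtaps = int(3.3 * fs / trans)
    # keep the kernel shorter than the signal; odd length for exact zero phase
    numtaps = min(numtaps, max(33, (n_max // 3) | 1))
    numtaps |= 1
    f_hi = min(f_high, nyq * 0.999)
    return sps.firwin(numtaps, [f_low, f_hi], pass_zero=False, fs=fs)


def bandpass(x: np.ndarray, fs: float, f_low: float, f_high: float) -> np.ndarray:
    """Zero-phase FIR band-pass via FFT convolution of a symmetric kernel."""
    x = np.asarray(x, dtype=float)
    taps = _fir_taps(fs, f_low, f_high, x.size)
    return sps.fftconvolve(x, taps, mode="same")


def analytic_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic (Hilbert) signal."""
    return np.abs(sps.hilbert(np.asarray(x, dtype=float)))


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Phase of the analytic signal, radians in (−π, π]."""
    return np.angle(sps.hilbert(np.asarray(x, dtype=float)))
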