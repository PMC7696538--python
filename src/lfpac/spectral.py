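"""Windowed spectral estimation and band-power partitioning.

Power spectral density is estimated with the averaged-periodogram (Welch)
method on 10-s Hann-tapered windows with 50% overlap, giving 0.1-Hz
resolution. Band powers integrate the PSD over half-open intervals
[f_low, f_high); the named bands are delta (1–4 Hz), theta (4–12 Hz), beta
(15–30 Hz) and gamma–fast-ripple (30–600 Hz). Relative power divides by the
total over [1, 600) Hz — the union support of the named bands — so relative
powers are invariant under global amplitude scaling and the four bands sum
to ≤ 1 (12–15 Hz is deliberately uncovered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import SignalTrace


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ValueError(f"invalid band {self.name}: [{self.f_low}, {self.f_high})")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 12.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("gamma_fast_ripple", 30.0, 600.0),
)
TOTAL_RANGE = (1.0, 600.0)


@dataclass
class PSD:
    freqs: np.ndarray
    power: np.ndarray  # µV²/Hz

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 0.0


@dataclass
class RelativePowerResult:
    absolute_power: dict[str, float]
    relative_power: dict[str, float]
    total_power: float
    window_s: float = 10.0
    overlap: float = 0.5


def compute_psd(
    trace: SignalTrace, window_s: float = 10.0, overlap: float = 0.5
) -> PSD:
    """Welch PSD on Hann-tapered sliding windows (default 10 s, 50% overlap)."""
    nperseg = int(round(window_s * trace.fs))
    if trace.n_samples < nperseg:
        raise ValueError(
            f"trace ({trace.duration_s:.1f} s) shorter than one {window_s}-s window"
        )
    freqs, power = sps.welch(
        trace.samples,
        fs=trace.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend="constant",
        average="mean",
        scaling="density",
    )
    return PSD(freqs=freqs, power=power)


def band_powers(
    psd: PSD,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    total_range: tuple[float, float] = TOTAL_RANGE,
    window_s: float = 10.0,
    overlap: float = 0.5,
) -> RelativePowerResult:
    """Integrate the PSD over each band; relative = band / total range."""
    for a in bands:
        for b in bands:
            if a.name < b.name and a.f_low < b.f_high and b.f_low < a.f_high:
                raise ValueError(f"bands {a.name} and {b.name} overlap")
    df = psd.df
    f = psd.freqs

    def integrate(lo: float, hi: float) -> float:
        sel = (f >= lo) & (f < hi)
        return float(np.sum(psd.power[sel]) * df)

    absolute = {b.name: integrate(b.f_low, b.f_high) for b in bands}
    total = integrate(*total_range)
    relative = {
        name: (p / total if total > 0 else 0.0) for name, p in absolute.items()
    }
    return RelativePowerResult(
        absolute_power=absolute,
        relative_power=relative,
        total_power=total,
        window_s=window_s,
        overlap=overlap,
    )


def relative_band_power(
    trace: SignalTrace,
    band: str = "theta",
    window_s: float = 10.0,
    overlap: float = 0.5,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> float:
    """Convenience: one band's relative power for one trace."""
    res = band_powers(compute_psd(trace, window_s, overlap), bands,
                      window_s=window_s, overlap=overlap)
    return res.relative_power[band]


@dataclass
class ThetaChangeResult:
    """Pre→post relative-theta comparison.

    ``overall_percent`` uses the left/right-averaged relative theta:
    100 × (post − pre) / pre. Per-side values and percent changes are kept
    for the lateralized comparison.
    """

    per_side: dict[str, tuple[float, float, float]]  # channel -> (pre, post, %)
    mean_pre: float
    mean_post: float
    overall_percent: float


def theta_change(
    pre30: "SignalTrace | dict[str, SignalTrace]",
    post30: "SignalTrace | dict[str, SignalTrace]",
    window_s: float = 10.0,
    overlap: float = 0.5,
) -> ThetaChangeResult:
    """Percent change in relative theta between two (30-s) epochs.

    Accepts single traces or ``{channel: trace}`` maps (both sides); the
    overall figure compares the side-averaged relative theta values.
    """
    if isinstance(pre30, SignalTrace):
        pre30 = {pre30.channel or "chan": pre30}
    if isinstance(post30, SignalTrace):
        post30 = {post30.channel or "chan": post30}
    if set(pre30) != set(post30):
        raise ValueError("pre and post epochs must cover the same channels")
    per_side = {}
    for ch in pre30:
        p = relative_band_power(pre30[ch], "theta", window_s, overlap)
        q = relative_band_power(post30[ch], "theta", window_s, overlap)
        if p == 0:
            raise ZeroDivisionError(f"zero pre-epoch theta power on {ch}")
        per_side[ch] = (p, q, 100.0 * (q - p) / p)
    mean_pre = float(np.mean([v[0] for v in per_side.values()]))
    mean_post = float(np.mean([v[1] for v in per_side.values()]))
    if mean_pre == 0:
        raise ZeroDivisionError("zero pre-epoch theta power")
    return ThetaChangeResult(
        per_side=per_side,
        mean_pre=mean_pre,
        mean_post=mean_post,
        overall_percent=100.0 * (mean_post - mean_pre) / mean_pre,
    )
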