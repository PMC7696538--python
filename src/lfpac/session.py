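"""Recording I/O, stimulation-schedule model, and analysis-epoch extraction.

The daily stimulation protocol is four 50-s trains of 4-Hz biphasic pulses
with 5-min pauses between trains; recording starts 5 min before the first
train and ends 5 min after the last, giving a 1700-s session with the
default parameters. The analysis epochs are the 5-min windows immediately
before the first train and after the last train (``pre5``/``post5``) and the
30-s windows flanking the same boundaries (``pre30``/``post30``). Sham
sessions without a schedule contribute their first and last 5 minutes.

EDF (European Data Format, 16-bit) is the canonical on-disk format; a raw
NumPy ``.npz`` + JSON-header container is provided as a lossless fallback.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .signals import SignalTrace, RecordingSession, HIPPOCAMPAL_CHANNELS


class ChannelMissingError(KeyError):
    """A required channel is absent from a recording."""


@dataclass
class StimTrain:
    """One stimulation train: 4-Hz biphasic square pulses, 100 µs wide."""

    onset_s: float
    duration_s: float = 50.0
    pulse_rate: float = 4.0
    pulse_width_us: float = 100.0
    amplitude_uA: float = 500.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.pulse_rate <= 0:
            raise ValueError("train duration and pulse rate must be positive")
        if not 100.0 <= self.amplitude_uA <= 500.0:
            raise ValueError(
                f"amplitude {self.amplitude_uA} µA outside titration range [100, 500]"
            )

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class StimulationSchedule:
    """A day's stimulation package plus the flanking recording windows."""

    trains: list[StimTrain]
    inter_train_pause_s: float = 300.0
    pre_window_s: float = 300.0
    post_window_s: float = 300.0

    def __post_init__(self) -> None:
        onsets = [t.onset_s for t in self.trains]
        if onsets != sorted(onsets):
            raise ValueError("trains must be sorted by onset")
        for a, b in zip(self.trains, self.trains[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError("trains overlap")

    @property
    def first_onset_s(self) -> float:
        return self.trains[0].onset_s

    @property
    def last_offset_s(self) -> float:
        return self.trains[-1].offset_s

    @property
    def total_duration_s(self) -> float:
        return self.last_offset_s + self.post_window_s

    def to_json(self, path: str | Path) -> None:
        payload = {
            "trains": [asdict(t) for t in self.trains],
            "inter_train_pause_s": self.inter_train_pause_s,
            "pre_window_s": self.pre_window_s,
            "post_window_s": self.post_window_s,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StimulationSchedule":
        payload = json.loads(Path(path).read_text())
        trains = [StimTrain(**t) for t in payload.pop("trains")]
        return cls(trains=trains, **payload)


@dataclass
class Epoch:
    """A half-open analysis interval ``[start_s, end_s)`` on one channel."""

    label: str
    start_s: float
    end_s: float
    channel: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(f"invalid epoch [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def build_schedule(
    n_trains: int = 4,
    train_s: float = 50.0,
    pause_s: float = 300.0,
    pre_s: float = 300.0,
    post_s: float = 300.0,
    pulse_rate: float = 4.0,
    amplitude_uA: float = 500.0,
) -> StimulationSchedule:
    """Build the daily stimulation schedule.

    Train k (1-based) starts at ``pre_s + (k-1)*(train_s + pause_s)``; the
    total recording spans ``pre_s + n_trains*train_s +
    (n_trains-1)*pause_s + post_s`` seconds (1700 s with defaults).
    """
    if n_trains < 1 or min(train_s, pause_s, pre_s, post_s) <= 0:
        raise ValueError("schedule parameters must be positive")
    trains = [
        StimTrain(
            onset_s=pre_s + k * (train_s + pause_s),
            duration_s=train_s,
            pulse_rate=pulse_rate,
            amplitude_uA=amplitude_uA,
        )
        for k in range(n_trains)
    ]
    return StimulationSchedule(
        trains=trains,
        inter_train_pause_s=pause_s,
        pre_window_s=pre_s,
        post_window_s=post_s,
    )


def extract_epochs(
    session: RecordingSession,
    short_window_s: float = 30.0,
    channels: tuple[str, ...] | None = None,
) -> list[Epoch]:
    """Extract the pre/post stimulation epochs for each hippocampal channel.

    With a schedule: ``pre5`` is the ``pre_window_s`` ending at the first
    train onset, ``post5`` the ``post_window_s`` starting at the last train
    offset; ``pre30``/``post30`` are ``short_window_s``-long windows at the
    same boundaries. Sham sessions (no schedule) yield the first and last
    ``pre5``-length windows of the recording. Epochs never overlap a train.
    """
    channels = channels or tuple(
        c for c in HIPPOCAMPAL_CHANNELS if c in session.traces
    )
    dur = session.duration_s
    sched = session.schedule
    epochs: list[Epoch] = []
    if sched is None:
        w = 300.0
        w = min(w, dur / 2)
        bounds = {
            "pre5": (0.0, w),
            "post5": (dur - w, dur),
            "pre30": (max(0.0, w - short_window_s), w),
            "post30": (dur - w, dur - w + short_window_s),
        }
    else:
        on, off = sched.first_onset_s, sched.last_offset_s
        if off + sched.post_window_s > dur + 1e-9:
            raise ValueError(
                f"schedule extends to {off + sched.post_window_s:.1f} s but the "
                f"recording is only {dur:.1f} s long"
            )
        bounds = {
            "pre5": (on - sched.pre_window_s, on),
            "post5": (off, off + sched.post_window_s),
            "pre30": (on - short_window_s, on),
            "post30": (off, off + short_window_s),
        }
    for ch in channels:
        for label, (a, b) in bounds.items():
            epochs.append(Epoch(label=label, start_s=a, end_s=b, channel=ch))
    return epochs


def epoch_trace(session: RecordingSession, epoch: Epoch) -> SignalTrace:
    """Slice the epoch's channel out of the session."""
    if epoch.channel not in session.traces:
        raise ChannelMissingError(epoch.channel)
    return session.traces[epoch.channel].slice(epoch.start_s, epoch.end_s)


# --------------------------------------------------------------------------
# On-disk formats
# --------------------------------------------------------------------------

_EDF_HEADER = struct.Struct("<8s80s80s8s8s8s44s8s8s4s")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_session_edf(session: RecordingSession, path: str | Path) -> None:
    """Write a session as 16-bit EDF with physical dimension µV.

    One data record per second; each channel's physical range is its observed
    min/max so quantization error is at most (max−min)/2¹⁶.
    """
    path = Path(path)
    labels = list(session.traces)
    fs = session.fs
    spr = int(round(fs))  # samples per 1-s record
    n = next(iter(session.traces.values())).n_samples
    n_rec = n // spr
    ns = len(labels)
    header = bytearray()
    header += _edf_field("0", 8)
    header += _edf_field(f"animal {session.animal_id} group {session.group}", 80)
    header += _edf_field(f"day {session.day_index}", 80)
    header += _edf_field("01.01.20", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 + ns * 256, 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)  # record duration, seconds
    header += _edf_field(ns, 4)

    phys_min, phys_max, dig = [], [], []
    for lab in labels:
        x = session.traces[lab].samples[: n_rec * spr]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0)
        dig.append(scaled.astype("<i2"))

    for lab in labels:
        header += _edf_field(lab, 16)
    for _ in labels:
        header += _edf_field("", 80)  # transducer
    for _ in labels:
        header += _edf_field("uV", 8)
    for v in phys_min:
        header += _edf_field(f"{v:.6g}"[:8], 8)
    for v in phys_max:
        header += _edf_field(f"{v:.6g}"[:8], 8)
    for _ in labels:
        header += _edf_field(-32768, 8)
    for _ in labels:
        header += _edf_field(32767, 8)
    for _ in labels:
        header += _edf_field("", 80)  # prefiltering (acquisition metadata)
    for _ in labels:
        header += _edf_field(spr, 8)
    for _ in labels:
        header += _edf_field("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            for d in dig:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


def read_session_edf(path: str | Path) -> RecordingSession:
    """Read an EDF recording via MNE, mapping channels by label."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    traces = {}
    for name in raw.ch_names:
        data = raw.get_data(picks=[name])[0]
        # MNE converts EDF voltages to SI units (V); analysis units are µV.
        traces[name] = SignalTrace(samples=data * 1e6, fs=fs, channel=name)
    return RecordingSession(traces=traces)


def write_session(session: RecordingSession, path: str | Path) -> None:
    """Write a session; ``.edf`` → EDF, anything else → npz+JSON fallback."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_session_edf(session, path)
        return
    meta = {
        "animal_id": session.animal_id,
        "group": session.group,
        "day_index": session.day_index,
        "fs": session.fs,
        "channels": list(session.traces),
        "meta": session.meta,
    }
    arrays = {c: tr.samples for c, tr in session.traces.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def read_session(
    path: str | Path,
    require_channels: tuple[str, ...] = HIPPOCAMPAL_CHANNELS,
    schedule: StimulationSchedule | None = None,
) -> RecordingSession:
    """Read a session from EDF or the npz fallback.

    Raises :class:`ChannelMissingError` naming the first absent required
    channel (both hippocampal channels by default).
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        sess = read_session_edf(path)
    else:
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            traces = {
                c: SignalTrace(samples=z[c], fs=meta["fs"], channel=c)
                for c in meta["channels"]
            }
        sess = RecordingSession(
            traces=traces,
            animal_id=meta["animal_id"],
            group=meta["group"],
            day_index=meta["day_index"],
            meta=meta.get("meta", {}),
        )
    for ch in require_channels:
        if ch not in sess.traces:
            raise ChannelMissingError(
                f"required channel '{ch}' missing from {path.name}"
            )
    sess.schedule = schedule
    return sess
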