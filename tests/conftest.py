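"""Shared fixtures: scaled-down synthetic sessions and schedules.

Tests run at reduced sampling rates and durations (the analysis is
rate-independent); fast-ripple-band tests use fs = 1500 Hz so the 250–600 Hz
band stays below Nyquist.
"""

import numpy as np
import pytest

from lfpac import (
    SyntheticSpec,
    build_schedule,
    generate_session,
    generate_background,
    add_coupled_oscillations,
)


@pytest.fixture(scope="session")
def short_schedule():
    """Two 10-s trains, 30-s pauses, 60-s flanking windows (160 s total)."""
    return build_schedule(n_trains=2, train_s=10, pause_s=30, pre_s=60, post_s=60)


@pytest.fixture(scope="session")
def coupled_trace():
    """120-s trace with delta(2.5 Hz)→80 Hz coupling at κ = 0.8, jittered."""
    bg = generate_background(120, 1000, 1.0, 5.0, seed=2)
    return add_coupled_oscillations(
        bg, 2.5, 20.0, [(80.0, 10.0, 0.8)],
        freq_jitter=0.3, rng=np.random.default_rng(7),
    )


@pytest.fixture(scope="session")
def ied_session():
    """300-s session with 8×SD injected discharges (detector ground truth)."""
    spec = SyntheticSpec(duration_s=300, fs=1500, ied_amp_sd_multiple=8, seed=0)
    return generate_session(spec)


@pytest.fixture(scope="session")
def dbs_session(short_schedule):
    """Scaled DBS session: theta ×1.3 and κ ×0.5 after the last train."""
    spec = SyntheticSpec(
        duration_s=short_schedule.total_duration_s,
        fs=1500,
        noise_scale=20.0,
        delta_amp=60.0,
        theta_amp=25.0,
        coupling=[(80.0, 15.0, 0.8)],
        ied_rates={"spike": 2.0, "polyspike": 0.4, "sharp_wave": 0.6},
        ied_amp_sd_multiple=8.0,
        post_theta_multiplier=1.3,
        post_kappa_multiplier=0.5,
        seed=42,
    )
    return generate_session(spec, short_schedule)


def match_events(ground_truth, detected, tol_s=0.05):
    """Greedy 1:1 matching of ground-truth times to detections within ±tol."""
    used, matched = set(), 0
    for t_ev, *_ in ground_truth:
        for i, e in enumerate(detected):
            if i not in used and abs(e.peak_time_s - t_ev) < tol_s:
                matched += 1
                used.add(i)
                break
    return matched
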