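"""Study-level statistics: percent changes, group tests, correlations.

Conventions follow the study design: seizure-rate change is
``before − during`` (positive = improvement), unpaired tests use the Welch
correction by default (group sizes are unequal), and per-band tests are
reported raw, without multiple-testing correction (a Holm option exists but
is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


def percent_change(before: float, after: float, mode: str = "reduction") -> float:
    """Percent change relative to the 'before' value.

    ``reduction`` = 100·(before − after)/before;
    ``increase`` = 100·(after − before)/before. The two are exact negatives.
    """
    if before <= 0:
        raise ValueError(f"'before' must be positive, got {before}")
    if mode == "reduction":
        return 100.0 * (before - after) / before
    if mode == "increase":
        return 100.0 * (after - before) / before
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    design: str
    n: tuple[int, ...]


def compare_groups(
    values_a,
    values_b,
    design: str = "paired",
    equal_var: bool = False,
) -> TestResult:
    """Two-sided group comparison: paired t, unpaired (Welch) t, or ANOVA.

    Identical paired samples return (t=0, p=1) rather than the 0/0 NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if design == "paired":
        if a.size != b.size:
            raise ValueError("paired design requires equal lengths")
        d = a - b
        if np.allclose(d, 0.0):
            return TestResult(0.0, 1.0, design, (a.size, b.size))
        t, p = sst.ttest_rel(a, b)
    elif design == "unpaired":
        t, p = sst.ttest_ind(a, b, equal_var=equal_var)
    elif design == "anova":
        t, p = sst.f_oneway(a, b)
    else:
        raise ValueError(f"unknown design {design!r}")
    return TestResult(float(t), float(p), design, (a.size, b.size))


def correlate_outcome(outcome, predictor) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p value.

    Pairs with a missing value in either column are dropped; fewer than 3
    complete pairs or zero variance raise.
    """
    x = np.asarray(outcome, dtype=float)
    y = np.asarray(predictor, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def summarize_outcomes(
    seizure_logs,
    ied_table: pd.DataFrame | None = None,
    pac_table: pd.DataFrame | None = None,
    n_days: int = 10,
) -> pd.DataFrame:
    """One row per animal joining outcome and predictor columns.

    Columns: seizure rates before/during DBS and their change
    (before − during, positive = improvement), mean seizure durations, then
    any per-animal IED rates and per (epoch, channel, band) MaxPAC means.
    Animals missing from a predictor table get explicit NaNs; animals in a
    predictor table but not in the logs raise a join error.
    """
    rows = []
    for log in seizure_logs:
        df = log.to_frame()
        before = df[df.phase == "before"]
        dbs = df[df.phase == "dbs"]
        rb = len(before) / n_days
        rd = len(dbs) / n_days
        rows.append(
            {
                "animal_id": log.animal_id,
                "rate_before": rb,
                "rate_dbs": rd,
                "rate_change": rb - rd,
                "mean_duration_before_s": before.duration_s.mean(),
                "mean_duration_dbs_s": dbs.duration_s.mean(),
                "pac_level": getattr(log, "pac_level", np.nan),
            }
        )
    out = pd.DataFrame(rows).set_index("animal_id")

    for table, what in ((ied_table, "IED"), (pac_table, "PAC")):
        if table is None or table.empty:
            continue
        extra = set(table["animal_id"]) - set(out.index)
        if extra:
            raise KeyError(f"{what} table has unmatched animals: {sorted(extra)}")

    if ied_table is not None and not ied_table.empty:
        g = ied_table.groupby("animal_id")["bilateral_mean_rate"].mean()
        out["mean_ied_rate"] = g
        if "subtype" in ied_table.columns:
            for sub in ("spike", "polyspike", "sharp_wave"):
                sel = ied_table[ied_table.subtype == sub]
                out[f"mean_{sub}_rate"] = sel.groupby("animal_id")["rate"].mean()

    if pac_table is not None and not pac_table.empty:
        piv = pac_table.pivot_table(
            index="animal_id",
            columns=["epoch", "channel", "fa_band"],
            values="max_pac",
            aggfunc="mean",
        )
        piv.columns = [f"max_pac_{e}_{c}_{b}" for e, c, b in piv.columns]
        out = out.join(piv)
    return out.reset_index()


def cohort_percent_rate_change(outcomes: pd.DataFrame) -> float:
    """Cohort-level percent seizure-rate reduction: computed from the group
    mean rates (a ratio of means, not a mean of per-animal ratios)."""
    return percent_change(
        float(outcomes["rate_before"].mean()), float(outcomes["rate_dbs"].mean())
    )


def correlation_table(
    outcomes: pd.DataFrame,
    outcome_col: str = "rate_change",
    epochs: tuple[str, ...] = ("pre5", "post5"),
    channels: tuple[str, ...] = ("left_hipp", "right_hipp"),
    bands: tuple[str, ...] = ("gamma", "hfo", "ripple", "fast_ripple"),
) -> pd.DataFrame:
    """Seizure-outcome vs MaxPAC correlation grid (epoch × side × band)."""
    rows = []
    for ep in epochs:
        for ch in channels:
            for band in bands:
                col = f"max_pac_{ep}_{ch}_{band}"
                if col not in outcomes.columns:
                    continue
                r, p = correlate_outcome(outcomes[outcome_col], outcomes[col])
                rows.append(
                    {"epoch": ep, "channel": ch, "fa_band": band, "r": r, "p": p}
                )
    return pd.DataFrame(rows)


def day_course(ied_tables: pd.DataFrame) -> tuple[pd.DataFrame, TestResult | None]:
    """Mean IED rate per (group, day), plus the day-1 vs day-10 paired test.

    Expects columns ``group, animal_id, day_index, rate``. The paired test
    uses animals present on both day 1 and day 10.
    """
    if ied_tables.empty:
        return pd.DataFrame(columns=["group", "day_index", "mean_rate"]), None
    means = (
        ied_tables.groupby(["group", "day_index"])["rate"]
        .mean()
        .reset_index()
        .rename(columns={"rate": "mean_rate"})
    )
    last_day = int(ied_tables["day_index"].max())
    piv = ied_tables.pivot_table(index="animal_id", columns="day_index", values="rate")
    test = None
    if 1 in piv.columns and last_day in piv.columns and last_day > 1:
        both = piv[[1, last_day]].dropna()
        if len(both) >= 2:
            test = compare_groups(both[1], both[last_day], design="paired")
    return means, test
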