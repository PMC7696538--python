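"""Study statistics: percent-change arithmetic, tests, correlations,
outcome assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lfpac import (
    CohortSpec,
    generate_seizure_log,
    percent_change,
    compare_groups,
    correlate_outcome,
    summarize_outcomes,
    cohort_percent_rate_change,
    day_course,
)
from lfpac.stats import holm_correction
from lfpac.synth import SeizureLog


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(5.17, 3.37, 34.82), (60.84, 44.67, 26.58), (1.18, 0.83, 29.66)],
    )
    def test_reduction_arithmetic(self, before, after, expected):
        assert percent_change(before, after) == pytest.approx(expected, abs=0.01)

    def test_increase_arithmetic(self):
        assert percent_change(25.9, 30.3, "increase") == pytest.approx(16.99, abs=0.01)

    def test_no_change_is_zero(self):
        assert percent_change(4.2, 4.2) == 0.0
        assert percent_change(4.2, 4.2, "increase") == 0.0

    def test_nonpositive_before_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @given(
        before=st.floats(0.01, 1e4),
        after=st.floats(0.0, 1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_reduction_increase_antisymmetry(self, before, after):
        assert percent_change(before, after, "reduction") == -percent_change(
            before, after, "increase"
        )


class TestCompareGroups:
    def test_identical_paired_samples(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "paired")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_paired_detects_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 20)
        res = compare_groups(a, a + 1.0, "paired")
        assert res.p_value < 1e-6

    def test_unpaired_uses_welch(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(0, 1, 9), rng.normal(0, 5, 7), "unpaired")
        assert np.isfinite(res.statistic)

    def test_anova_two_groups_matches_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        f = compare_groups(a, b, "anova")
        t = compare_groups(a, b, "unpaired", equal_var=True)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-9)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        n_rej = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 1, 10)
            if compare_groups(a, b, "unpaired").p_value < 0.05:
                n_rej += 1
        assert 0.03 <= n_rej / reps <= 0.07

    def test_paired_power_on_kappa_halving_effect(self):
        # pre/post MaxPAC of 10 animals with the generated effect size:
        # halving κ roughly halves coupling; detectable by a paired t test
        rng = np.random.default_rng(4)
        pre = rng.normal(0.025, 0.005, 10)
        rejections = 0
        for _ in range(200):
            pre = rng.normal(0.025, 0.005, 10)
            post = pre * 0.55 + rng.normal(0, 0.003, 10)
            if compare_groups(pre, post, "paired").p_value < 0.05:
                rejections += 1
        assert rejections / 200 >= 0.8


class TestCorrelation:
    def test_perfect_negative(self):
        r, _ = correlate_outcome([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_outcome([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_outcome([1, 2], [3, 4])

    def test_nan_pairs_dropped(self):
        r, _ = correlate_outcome([1, 2, 3, np.nan], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_null_critical_value_at_n9(self):
        # |r| > 0.666 (the α=0.05 two-sided critical value at n=9) should
        # occur in about 5% of independent draws
        rng = np.random.default_rng(5)
        n_exceed = 0
        reps = 1000
        for _ in range(reps):
            r, _ = correlate_outcome(rng.normal(0, 1, 9), rng.normal(0, 1, 9))
            if abs(r) > 0.666:
                n_exceed += 1
        assert 0.03 <= n_exceed / reps <= 0.07

    def test_synthetic_cohort_reproduces_negative_sign(self):
        logs = generate_seizure_log(
            CohortSpec(n_animals=9, pac_outcome_slope=-0.01, seed=12)
        )
        out = summarize_outcomes(logs)
        r, _ = correlate_outcome(out["rate_change"], out["pac_level"])
        assert r < 0


class TestOutcomes:
    def test_one_row_per_animal(self):
        logs = generate_seizure_log(CohortSpec(n_animals=10, seed=1))
        out = summarize_outcomes(logs)
        assert len(out) == 10
        assert out.animal_id.nunique() == 10

    def test_zero_seizure_animal_zero_change(self):
        silent = SeizureLog(animal_id="quiet", entries=[], pac_level=0.02)
        out = summarize_outcomes([silent, SeizureLog("other", [], 0.02)])
        assert out.loc[out.animal_id == "quiet", "rate_change"].item() == 0.0

    def test_cohort_level_percent_reduction_near_design(self):
        logs = generate_seizure_log(
            CohortSpec(n_animals=200, dbs_rate_multiplier=0.77, seed=1)
        )
        pct = cohort_percent_rate_change(summarize_outcomes(logs))
        assert pct == pytest.approx(23.0, abs=3.0)

    def test_unmatched_predictor_animals_raise(self):
        logs = generate_seizure_log(CohortSpec(n_animals=3, seed=2))
        bad = pd.DataFrame(
            {"animal_id": ["ghost"], "bilateral_mean_rate": [1.0]}
        )
        with pytest.raises(KeyError, match="ghost"):
            summarize_outcomes(logs, ied_table=bad)

    def test_missing_pac_columns_are_nulls_not_drops(self):
        logs = generate_seizure_log(CohortSpec(n_animals=4, seed=3))
        pac = pd.DataFrame(
            {
                "animal_id": ["rat01", "rat02"],
                "epoch": ["pre5", "pre5"],
                "channel": ["left_hipp", "left_hipp"],
                "fa_band": ["gamma", "gamma"],
                "max_pac": [0.02, 0.03],
            }
        )
        out = summarize_outcomes(logs, pac_table=pac)
        col = "max_pac_pre5_left_hipp_gamma"
        assert len(out) == 4
        assert out[col].notna().sum() == 2


class TestDayCourse:
    def _table(self, trend=0.0, n_animals=9, n_days=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in range(n_animals):
            base = rng.uniform(3, 6)
            for d in range(1, n_days + 1):
                rows.append(
                    {
                        "group": "DBS-Pilo",
                        "animal_id": f"rat{a}",
                        "day_index": d,
                        "rate": max(base + trend * (d - 1) + rng.normal(0, 0.1), 0),
                    }
                )
        return pd.DataFrame(rows)

    def test_cell_counts(self):
        means, test = day_course(self._table())
        assert len(means) == 10

    def test_flat_rates_flat_course(self):
        means, test = day_course(self._table(trend=0.0))
        assert means.mean_rate.max() - means.mean_rate.min() < 0.5
        assert test.p_value > 0.05

    def test_decaying_rates_detected(self):
        means, test = day_course(self._table(trend=-0.2, seed=1))
        fit = np.polyfit(means.day_index, means.mean_rate, 1)[0]
        assert fit < 0
        assert test.p_value < 0.05

    def test_empty_input(self):
        means, test = day_course(pd.DataFrame())
        assert means.empty and test is None


def test_holm_correction_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.5]
    adj = holm_correction(p)
    assert np.all(adj >= np.asarray(p))
    assert np.all(adj <= 1.0)
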