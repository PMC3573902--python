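"""Day/night partitioning, period means, shares and replicate S.E."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielgrow.diel_analysis import (
    LightSchedule,
    diel_summary,
    normalize_daily,
    partition_periods,
    period_mean,
    replicate_sem,
    summarize_replicates,
    treatment_effect,
)
from dielgrow.errors import ValidationError

SCHED = LightSchedule(light_on=8.0, light_off=20.0)


def make_series(clock_hours, start_t=0.0):
    """Timestamps advancing 1 h per sample alongside the given clocks."""
    t = start_t + 3600.0 * np.arange(len(clock_hours))
    return t, np.asarray(clock_hours, dtype=float)


class TestPartition:
    def test_half_open_boundaries(self):
        # 07:59 nocturnal; 08:00 diurnal (light-on inclusive); 20:00 nocturnal
        t = np.array([0.0, 60.0, 43260.0])
        clock = np.array([7.0 + 59.0 / 60.0, 8.0, 20.0])
        part = partition_periods(t, clock, SCHED)
        assert list(part["period"]) == ["nocturnal", "diurnal", "nocturnal"]

    def test_day_increments_at_light_on(self):
        # hourly samples from 06:00 over 30 h: day rolls over at each 08:00
        clock0 = 6.0
        t = 3600.0 * np.arange(30)
        clock = (clock0 + t / 3600.0) % 24.0
        part = partition_periods(t, clock, SCHED)
        days = part["day"].to_numpy()
        assert days[0] == 1  # 06:00, before first light-on
        assert days[2] == 2  # 08:00 starts the next experimental day
        assert days[25] == 2  # 07:00 next morning still day 2
        assert days[26] == 3  # 08:00 next morning
        assert set(np.diff(days)) <= {0, 1}

    def test_zero_photoperiod_rejected(self):
        with pytest.raises(ValidationError):
            LightSchedule(light_on=8.0, light_off=8.0)

    def test_partition_exhaustive_exclusive(self):
        rng = np.random.default_rng(0)
        clock = rng.uniform(0, 24, 500)
        t = np.sort(rng.uniform(0, 1e5, 500))
        for sched in (SCHED, LightSchedule(light_on=20.0, light_off=6.0)):
            part = partition_periods(t, clock, sched)
            assert set(part["period"]) <= {"diurnal", "nocturnal"}
            assert len(part) == 500


class TestPeriodMean:
    def test_piecewise_constant(self):
        t, clock = make_series([9, 10, 11, 21, 22, 23])
        part = partition_periods(t, clock, SCHED)
        means = period_mean([0.1, 0.1, 0.1, 0.3, 0.3, 0.3], part)
        by = {r["period"]: r["mean"] for _, r in means.iterrows()}
        assert by["diurnal"] == pytest.approx(0.1)
        assert by["nocturnal"] == pytest.approx(0.3)

    def test_missing_windows_ignored_with_count(self):
        t, clock = make_series([9, 10, 21, 22])
        part = partition_periods(t, clock, SCHED)
        means = period_mean([0.1, np.nan, 0.3, 0.5], part)
        by = {r["period"]: r for _, r in means.iterrows()}
        assert by["diurnal"]["n"] == 1
        assert by["nocturnal"]["mean"] == pytest.approx(0.4)

    def test_empty_cell_absent_not_zero(self):
        t, clock = make_series([9, 10, 11])  # no night samples
        part = partition_periods(t, clock, SCHED)
        means = period_mean([1.0, 1.0, 1.0], part)
        assert set(means["period"]) == {"diurnal"}


class TestNormalise:
    @pytest.mark.parametrize(
        "d,n,expected",
        [
            (0.5, 0.5, (50.0, 50.0)),
            (0.1, 0.3, (25.0, 75.0)),  # nocturnal 3× diurnal → 75:25
            (0.3, 0.7, (30.0, 70.0)),  # the roughly 70:30 night:day split
        ],
    )
    def test_shares(self, d, n, expected):
        got = normalize_daily(d, n)
        assert got[0] == pytest.approx(expected[0])
        assert got[1] == pytest.approx(expected[1])
        assert got[0] + got[1] == 100.0  # exact, not approximate

    def test_both_zero_undefined(self):
        d, n = normalize_daily(0.0, 0.0)
        assert np.isnan(d) and np.isnan(n)


class TestReplicateSEM:
    def test_hand_computed_values(self):
        assert replicate_sem([1.0, 1.0, 1.0]) == 0.0
        assert replicate_sem([0.0, 2.0]) == pytest.approx(1.0, abs=1e-12)
        # sd([0.5, 0.6, 0.7]) = 0.1, / √3
        assert replicate_sem([0.5, 0.6, 0.7]) == pytest.approx(0.1 / np.sqrt(3), abs=1e-12)

    def test_single_value_undefined(self):
        assert np.isnan(replicate_sem([0.7]))


class TestTreatmentEffect:
    def test_percent_change(self):
        c = pd.DataFrame({"day": [1, 1], "period": ["diurnal", "nocturnal"], "mean": [0.6, 0.6]})
        t50 = c.assign(mean=[0.3, 0.3])
        t33 = c.assign(mean=[0.4, 0.4])
        assert treatment_effect(c, t50)["percent_change"].to_numpy() == pytest.approx([-50.0, -50.0])
        assert treatment_effect(c, t33)["percent_change"].to_numpy() == pytest.approx(
            [-100.0 / 3.0] * 2
        )
        assert treatment_effect(c, c)["percent_change"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_zero_control_undefined(self):
        c = pd.DataFrame({"day": [1], "period": ["diurnal"], "mean": [0.0]})
        t = c.assign(mean=[0.5])
        assert np.isnan(treatment_effect(c, t)["percent_change"].iloc[0])


class TestClosedFormPipeline:
    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.floats(min_value=1e-3, max_value=10.0),
        b=st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_piecewise_series_shares_machine_precision(self, a, b):
        """night=a, day=b on 12/12 → shares exactly 100a/(a+b) : 100b/(a+b)."""
        t = 1800.0 * np.arange(48)  # half-hourly over one full day from 08:00
        clock = (8.0 + t / 3600.0) % 24.0
        values = np.where(SCHED.is_diurnal(clock), b, a)
        summary = diel_summary(values, t, clock, SCHED)
        row = summary.iloc[0]
        assert row["nocturnal_share"] == pytest.approx(100.0 * a / (a + b), abs=1e-9)
        assert row["diurnal_share"] == pytest.approx(100.0 * b / (a + b), abs=1e-9)
        assert row["nocturnal_share"] + row["diurnal_share"] == 100.0

    def test_three_to_one_gives_75_25(self):
        t = 1800.0 * np.arange(48)
        clock = (8.0 + t / 3600.0) % 24.0
        b = 0.012
        values = np.where(SCHED.is_diurnal(clock), b, 3 * b)
        row = diel_summary(values, t, clock, SCHED).iloc[0]
        assert row["nocturnal_share"] == pytest.approx(75.0, abs=1e-12)
        assert row["diurnal_share"] == pytest.approx(25.0, abs=1e-12)


class TestReplicateSummary:
    def make_replicate(self, night, day, jitter=0.0):
        t = 1800.0 * np.arange(48)
        clock = (8.0 + t / 3600.0) % 24.0
        values = np.where(SCHED.is_diurnal(clock), day, night) + jitter
        return pd.DataFrame(
            {
                "window_start_s": t,
                "window_end_s": t + 1800.0,
                "window_start_clock": clock,
                "velocity_mm_h": values,
            }
        )

    def test_across_plants(self):
        reps = [self.make_replicate(0.58, 0.56), self.make_replicate(0.62, 0.60),
                self.make_replicate(0.60, 0.58)]
        out = summarize_replicates(reps, SCHED, treatment="control")
        assert set(out["n"]) == {3}
        noct = out[out["period"] == "nocturnal"].iloc[0]
        assert noct["mean"] == pytest.approx(0.6, abs=1e-12)
        assert noct["sem"] == pytest.approx(np.std([0.58, 0.62, 0.60], ddof=1) / np.sqrt(3))
        day_rows = out[out["day"] == 1]
        assert day_rows["share_pct"].sum() == pytest.approx(100.0)

    def test_single_replicate_sem_undefined(self):
        out = summarize_replicates([self.make_replicate(0.6, 0.6)], SCHED)
        assert out["sem"].isna().all()
        assert set(out["n"]) == {1}
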