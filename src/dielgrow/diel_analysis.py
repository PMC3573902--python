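"""Day/night (diel) aggregation of growth time series.

Samples are partitioned into diurnal and nocturnal periods against a light
schedule (study default 12 h : 12 h), averaged per experimental day, and
normalised so nocturnal + diurnal = 100% per day. A "day" starts at
light-on: one light period plus the following dark period, so each diurnal
mean is paired with the night that follows it. Standard errors are taken
across replicate plants (after averaging time windows within a period per
plant), never across time windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "LightSchedule",
    "partition_periods",
    "period_mean",
    "normalize_daily",
    "replicate_sem",
    "treatment_effect",
    "diel_summary",
    "summarize_replicates",
]

DIURNAL = "diurnal"
NOCTURNAL = "nocturnal"


@dataclass(frozen=True)
class LightSchedule:
    """Light-on/light-off clock times (hours, 0–24)."""

    light_on: float = 8.0
    light_off: float = 20.0

    def __post_init__(self):
        if not (0.0 <= self.light_on < 24.0 and 0.0 <= self.light_off < 24.0):
            raise ValidationError("light_on/light_off must be clock hours in [0, 24)")
        if self.photoperiod <= 0.0 or self.photoperiod >= 24.0:
            raise ValidationError(
                f"photoperiod must be in (0, 24) h, got {self.photoperiod} "
                "(light_on == light_off gives no partition)"
            )

    @property
    def photoperiod(self) -> float:
        return (self.light_off - self.light_on) % 24.0

    def is_diurnal(self, clock_h) -> np.ndarray:
        """Half-open convention: light-on inclusive, light-off exclusive."""
        c = np.asarray(clock_h, dtype=float) % 24.0
        if self.light_on < self.light_off:
            return (c >= self.light_on) & (c < self.light_off)
        return (c >= self.light_on) | (c < self.light_off)


def partition_periods(
    timestamps_s: Sequence[float],
    clock_times_h: Sequence[float],
    schedule: LightSchedule,
) -> pd.DataFrame:
    """Label each sample diurnal/nocturnal and assign a 1-based day index.

    A sample is diurnal iff its clock time lies in ``[light_on, light_off)``
    (window centres should be passed for windowed series, which assigns a
    straddling window by its centre — unbiased for symmetric windows). The
    day index increments at every light-on: day n = n-th light period plus
    the following dark period.
    """
    t = np.asarray(timestamps_s, dtype=float)
    c = np.asarray(clock_times_h, dtype=float) % 24.0
    if t.shape != c.shape:
        raise ValidationError("timestamps and clock times must align")
    labels = np.where(schedule.is_diurnal(c), DIURNAL, NOCTURNAL)
    # continuous hours axis anchored at the first sample's clock time
    hours = c[0] + (t - t[0]) / 3600.0
    day = np.floor((hours - schedule.light_on) / 24.0)
    day_index = (day - day.min() + 1).astype(int)
    return pd.DataFrame({"t_s": t, "clock_h": c, "period": labels, "day": day_index})


def period_mean(values: Sequence[float], partition: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean per (day, period) cell; empty cells are absent rows.

    NaN values (missing windows) are ignored; ``n`` reports the samples
    actually used in each cell.
    """
    v = np.asarray(values, dtype=float)
    if len(v) != len(partition):
        raise ValidationError("values must align with the partition table")
    df = partition.copy()
    df["value"] = v
    df = df.dropna(subset=["value"])
    out = (
        df.groupby(["day", "period"], sort=True)["value"]
        .agg(mean="mean", n="count")
        .reset_index()
    )
    return out


def normalize_daily(diurnal_mean: float, nocturnal_mean: float) -> tuple:
    """Shares (%) of the daily total; returns (diurnal_share, nocturnal_share).

    Shares sum to 100 exactly; both-zero input yields (nan, nan) as the
    undefined marker.
    """
    if diurnal_mean < 0 or nocturnal_mean < 0:
        raise ValidationError("period means must be non-negative for normalisation")
    total = diurnal_mean + nocturnal_mean
    if total == 0:
        return (float("nan"), float("nan"))
    nocturnal_share = 100.0 * nocturnal_mean / total
    return (100.0 - nocturnal_share, nocturnal_share)


def replicate_sem(values: Iterable[float]) -> float:
    """S.E. across replicate plants: sample s.d. (n−1) over √n; NaN for n<2."""
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


def treatment_effect(summary_control: pd.DataFrame, summary_treatment: pd.DataFrame) -> pd.DataFrame:
    """Percent change per matched (day, period) cell: 100·(T − C)/C.

    A zero control mean marks the cell undefined (NaN) rather than raising.
    """
    merged = summary_control.merge(
        summary_treatment, on=["day", "period"], suffixes=("_control", "_treatment")
    )
    if merged.empty:
        raise ValidationError("no matched (day, period) cells between the summaries")
    ctrl = merged["mean_control"].to_numpy(dtype=float)
    trt = merged["mean_treatment"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(ctrl != 0, 100.0 * (trt - ctrl) / ctrl, np.nan)
    out = merged[["day", "period"]].copy()
    out["percent_change"] = pct
    return out


def diel_summary(
    values: Sequence[float],
    timestamps_s: Sequence[float],
    clock_times_h: Sequence[float],
    schedule: LightSchedule,
) -> pd.DataFrame:
    """Per-day diurnal/nocturnal means and daily shares for one series."""
    part = partition_periods(timestamps_s, clock_times_h, schedule)
    means = period_mean(values, part)
    rows = []
    for day, g in means.groupby("day"):
        cells = {r["period"]: r for _, r in g.iterrows()}
        d = cells.get(DIURNAL)
        n = cells.get(NOCTURNAL)
        d_mean = d["mean"] if d is not None else float("nan")
        n_mean = n["mean"] if n is not None else float("nan")
        if d is not None and n is not None and d_mean >= 0 and n_mean >= 0:
            d_share, n_share = normalize_daily(d_mean, n_mean)
        else:
            d_share = n_share = float("nan")
        rows.append(
            {
                "day": int(day),
                "diurnal_mean": d_mean,
                "nocturnal_mean": n_mean,
                "diurnal_share": d_share,
                "nocturnal_share": n_share,
                "n_diurnal_windows": int(d["n"]) if d is not None else 0,
                "n_nocturnal_windows": int(n["n"]) if n is not None else 0,
            }
        )
    return pd.DataFrame(rows)


def summarize_replicates(
    replicate_series: Sequence[pd.DataFrame],
    schedule: LightSchedule,
    value_column: Optional[str] = None,
    treatment: str = "",
) -> pd.DataFrame:
    """Across-plant summary: per (day, period) mean, share, S.E., n.

    Each element of ``replicate_series`` is one plant's windowed series with
    columns ``window_start_s``/``window_end_s``, ``window_start_clock`` (or
    ``clock_h``) and a value column (auto-detected: ``velocity_mm_h`` or
    ``rgr_div_h``). Time windows are first averaged per plant within each
    (day, period) cell; the mean, share and S.E. are then taken across
    plants, matching a replicated-plant experimental design.
    """
    per_plant = []
    for i, df in enumerate(replicate_series):
        col = value_column
        if col is None:
            for cand in ("velocity_mm_h", "rgr_div_h", "rgr_area_h", "value"):
                if cand in df.columns:
                    col = cand
                    break
        if col is None or col not in df.columns:
            raise ValidationError(f"replicate {i}: no value column found")
        if "window_start_s" in df.columns:
            t = 0.5 * (df["window_start_s"] + df["window_end_s"]).to_numpy()
            if "window_start_clock" in df.columns:
                c0 = df["window_start_clock"].iloc[0] - df["window_start_s"].iloc[0] / 3600.0
            else:
                c0 = 0.0
            clock = (c0 + t / 3600.0) % 24.0
        else:
            t = df["t_s"].to_numpy()
            clock = df["clock_h"].to_numpy()
        means = period_mean(df[col].to_numpy(), partition_periods(t, clock, schedule))
        means["plant"] = i
        per_plant.append(means)
    allm = pd.concat(per_plant, ignore_index=True)

    rows = []
    for (day, period), g in allm.groupby(["day", "period"], sort=True):
        vals = g["mean"].to_numpy(dtype=float)
        rows.append(
            {
                "treatment": treatment,
                "day": int(day),
                "period": period,
                "mean": float(np.mean(vals)),
                "sem": replicate_sem(vals),
                "n": int(len(vals)),
            }
        )
    out = pd.DataFrame(rows)
    # daily shares from the across-plant period means
    shares = []
    for day, g in out.groupby("day"):
        cells = {r["period"]: r["mean"] for _, r in g.iterrows()}
        if DIURNAL in cells and NOCTURNAL in cells:
            d_share, n_share = normalize_daily(cells[DIURNAL], cells[NOCTURNAL])
        else:
            d_share = n_share = float("nan")
        for _, r in g.iterrows():
            shares.append(d_share if r["period"] == DIURNAL else n_share)
    out["share_pct"] = shares
    return out
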