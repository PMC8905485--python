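"""Duration-sufficiency machinery: rolling SD, cumulative SD, stabilization.

The central question is how many nights of self-tracker data are needed
before an individual's summary statistics settle.  Three instruments:

* :func:`rolling_sd` — sample SD over a trailing 7-calendar-day window moved
  one day at a time, describing short-horizon variability.
* :func:`cumulative_sd` — SD over an expanding calendar window (3 days, then
  4, ... up to 3+80), whose flattening defines sufficiency.
* :func:`stabilization_day` — an explicit criterion for that flattening: the
  smallest window length from which all successive relative SD changes stay
  below a tolerance for a holding period.

All windows are *calendar* windows: missing nights reduce the number of
observations (available-case SDs with a minimum-observation floor) rather
than stretching the window.  Sample SDs use the n-1 denominator; the sleep
midtime is routed to the circular SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ALL_VARIABLES, CIRCULAR_VARIABLES, CohortPanel
from .night_metrics import circular_mean_sd

__all__ = [
    "VariabilityProfile",
    "WeeklySummary",
    "rolling_sd",
    "cumulative_sd",
    "stabilization_day",
    "weekly_summary",
    "daily_cohort_stats",
    "variability_profile",
    "profiles_frame",
]

STABILIZATION_EPS = 1e-9


def _sd(values: np.ndarray, circular: bool) -> float:
    if values.size < 2:
        return np.nan
    if circular:
        return circular_mean_sd(values)[1]
    return float(np.std(values, ddof=1))


def _circ_mean(values: np.ndarray) -> float:
    return circular_mean_sd(values)[0] if values.size else np.nan


@dataclass
class VariabilityProfile:
    """Rolling/cumulative SD sequences and stabilization day for one series."""

    participant_id: str
    variable: str
    rolling: pd.Series  # date -> SD over the trailing window
    cumulative: pd.Series  # window length (days) -> SD
    stabilization: int | None
    rel_tol: float
    hold_days: int


@dataclass
class WeeklySummary:
    """Per-calendar-week (Mon-Sun) mean/SD, optionally max-normalized."""

    participant_id: str
    variable: str
    week_start: pd.Timestamp
    n_obs: int
    mean: float
    sd: float
    norm_mean: float
    norm_sd: float
    complete: bool


def rolling_sd(
    series: pd.Series,
    window_days: int = 7,
    step_days: int = 1,
    *,
    circular: bool = False,
    min_obs: int = 5,
) -> pd.Series:
    """Trailing-window sample SD over calendar days.

    For each window end date (every ``step_days`` starting once a full
    window has elapsed), the SD of the available values in the trailing
    ``window_days`` calendar days; windows with fewer than ``min_obs``
    values yield NaN.
    """
    if window_days < 2:
        raise ValueError("window_days must be >= 2")
    if step_days < 1:
        raise ValueError("step_days must be >= 1")
    s = series.dropna().sort_index()
    if s.empty:
        return pd.Series(dtype=float, name="rolling_sd")
    s.index = pd.DatetimeIndex(s.index)
    first, last = s.index.min(), s.index.max()
    start = first + pd.Timedelta(days=window_days - 1)
    ends = pd.date_range(start, last, freq=f"{step_days}D")
    values = np.full(len(ends), np.nan)
    for i, end in enumerate(ends):
        window = s[(s.index > end - pd.Timedelta(days=window_days)) & (s.index <= end)]
        if len(window) >= max(min_obs, 2):
            values[i] = _sd(window.to_numpy(), circular)
    return pd.Series(values, index=ends, name="rolling_sd")


def cumulative_sd(
    series: pd.Series,
    start_days: int = 3,
    max_extra: int = 80,
    *,
    circular: bool = False,
    min_obs: int = 2,
) -> pd.Series:
    """SD over expanding calendar windows anchored at the series start.

    Window lengths run ``start_days, start_days+1, ..., start_days+max_extra``
    (truncated at the series end).  Each entry is the from-scratch sample SD
    of the values observed within that many calendar days of the first
    observation; entries with fewer than ``min_obs`` values are NaN.
    """
    s = series.dropna().sort_index()
    if s.empty:
        raise ValueError("cumulative_sd: empty series")
    s.index = pd.DatetimeIndex(s.index)
    t0 = s.index.min()
    span = (s.index.max() - t0).days + 1
    if span < start_days:
        raise ValueError(
            f"cumulative_sd: series spans {span} days < start_days={start_days}"
        )
    lengths = [L for L in range(start_days, start_days + max_extra + 1) if L <= span]
    out = np.full(len(lengths), np.nan)
    arr = s.to_numpy()
    offsets = (s.index - t0).days.to_numpy()
    for i, L in enumerate(lengths):
        vals = arr[offsets < L]
        if vals.size >= max(min_obs, 2):
            out[i] = _sd(vals, circular)
    return pd.Series(out, index=pd.Index(lengths, name="window_days"), name="cumulative_sd")


def stabilization_day(
    cum: pd.Series,
    rel_tol: float = 0.05,
    hold_days: int = 14,
    eps: float = STABILIZATION_EPS,
) -> int | None:
    """First window length from which the cumulative SD has flattened.

    Returns the smallest window length ``L`` such that for every pair of
    consecutive window lengths within ``[L, L + hold_days]`` the relative SD
    change ``|SD_{n+1} - SD_n| / max(SD_n, eps)`` stays below ``rel_tol``;
    ``None`` if the criterion never holds (including when the sequence is
    too short to verify a full holding period).
    """
    if cum.empty:
        raise ValueError("stabilization_day: empty sequence")
    if rel_tol <= 0:
        raise ValueError("rel_tol must be > 0")
    if hold_days < 1:
        raise ValueError("hold_days must be >= 1")
    lengths = np.asarray(cum.index, dtype=int)
    sds = cum.to_numpy(dtype=float)
    last = lengths[-1]
    for i, L in enumerate(lengths):
        hi = L + hold_days
        if hi > last:
            break
        in_hold = (lengths >= L) & (lengths <= hi)
        seg = sds[in_hold]
        seg_len = lengths[in_hold]
        # consecutive pairs only (gapless integer lengths)
        step_ok = np.diff(seg_len) == 1
        if np.isnan(seg).any():
            continue
        rel = np.abs(np.diff(seg)) / np.maximum(seg[:-1], eps)
        if np.all(rel[step_ok] < rel_tol) and step_ok.all():
            return int(L)
    return None


def weekly_summary(
    panel: CohortPanel,
    variable: str,
    *,
    normalize: bool = True,
    min_days: int = 4,
    participants: list[str] | None = None,
) -> list[WeeklySummary]:
    """Per-participant calendar-week (Mon-Sun) means and SDs.

    Normalization divides by the participant's largest observed value over
    the whole collection period, putting nonnegative variables on [0, 1].
    The circular sleep midtime gets a circular weekly mean/SD and no
    normalized values (a max over clock times is not meaningful).
    """
    if variable not in ALL_VARIABLES:
        raise KeyError(f"unknown variable {variable!r}")
    circular = variable in CIRCULAR_VARIABLES
    out: list[WeeklySummary] = []
    for pid in participants or panel.participants:
        s = panel.get_series(pid, variable)
        if s.empty:
            continue
        vmax = float(s.max()) if not circular else np.nan
        week_start = s.index - pd.to_timedelta(s.index.dayofweek, unit="D")
        for wk, grp in s.groupby(week_start):
            vals = grp.to_numpy()
            complete = len(vals) >= min_days
            if not complete:
                mean = sd = np.nan
            elif circular:
                sd = _sd(vals, True)
                mean = _circ_mean(vals)
            else:
                mean = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            if normalize and not circular and vmax > 0 and complete:
                nm, ns = mean / vmax, sd / vmax
            else:
                nm = ns = np.nan
            out.append(
                WeeklySummary(pid, variable, pd.Timestamp(wk), len(vals), mean, sd, nm, ns, complete)
            )
    return out


def daily_cohort_stats(
    panel: CohortPanel,
    variable: str,
    smooth_days: int = 14,
    *,
    participants: list[str] | None = None,
) -> pd.DataFrame:
    """Per-date cross-participant mean/SD plus a smoothed mean.

    The smoothed column is a centered moving average of width
    ``smooth_days`` over the daily means — a visual trend aid only, never
    used in statistics.  SD is NaN where only one participant contributes.
    """
    if variable not in ALL_VARIABLES:
        raise KeyError(f"unknown variable {variable!r}")
    circular = variable in CIRCULAR_VARIABLES
    cols = {}
    for pid in participants or panel.participants:
        s = panel.get_series(pid, variable)
        if not s.empty:
            cols[pid] = s
    if not cols:
        raise ValueError("daily_cohort_stats: no participant has data")
    wide = pd.DataFrame(cols).sort_index()
    if circular:
        mean = wide.apply(lambda row: _circ_mean(row.dropna().to_numpy()), axis=1)
        sd = wide.apply(lambda row: _sd(row.dropna().to_numpy(), True), axis=1)
    else:
        mean = wide.mean(axis=1)
        sd = wide.std(axis=1, ddof=1)
    smoothed = mean.rolling(smooth_days, center=True, min_periods=1).mean()
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "smoothed_mean": smoothed, "n": wide.notna().sum(axis=1)}
    )


def variability_profile(
    panel: CohortPanel,
    participant_id: str,
    variable: str,
    *,
    window_days: int = 7,
    min_obs: int = 5,
    start_days: int = 3,
    max_extra: int = 80,
    rel_tol: float = 0.05,
    hold_days: int = 14,
    anchor: pd.Timestamp | None = None,
) -> VariabilityProfile:
    """Rolling SD, cumulative SD and stabilization day for one series.

    ``anchor``, when given, restricts the series to dates >= anchor (the
    reference analysis anchors both sequences at the first days of October).
    """
    if variable not in ALL_VARIABLES:
        raise KeyError(f"unknown variable {variable!r}")
    circular = variable in CIRCULAR_VARIABLES
    s = panel.get_series(participant_id, variable)
    if anchor is not None:
        s = s[s.index >= pd.Timestamp(anchor)]
    roll = rolling_sd(s, window_days, circular=circular, min_obs=min_obs)
    cum = cumulative_sd(s, start_days, max_extra, circular=circular)
    stab = stabilization_day(cum, rel_tol, hold_days)
    return VariabilityProfile(participant_id, variable, roll, cum, stab, rel_tol, hold_days)


def profiles_frame(profiles: list[VariabilityProfile]) -> pd.DataFrame:
    """Long-format frame (participant, variable, kind, index, sd) for CSV export."""
    rows = []
    for p in profiles:
        for ts, sd in p.rolling.items():
            rows.append((p.participant_id, p.variable, "rolling", ts.date().isoformat(), sd))
        for L, sd in p.cumulative.items():
            rows.append((p.participant_id, p.variable, "cumulative", int(L), sd))
    return pd.DataFrame(rows, columns=["participant_id", "variable", "kind", "index", "sd"])
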