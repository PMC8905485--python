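"""Before/after testing of sleep and activity variables around a DST change.

On October 29, 2017 European clocks were set back one hour.  For each
participant, variable and horizon (15, 30 or 60 days on each side) the
values observed before the change are compared with those after using a
two-sample two-tailed t test at alpha = .05, yielding a participant x
variable x horizon significance grid.

Conventions: windows are half-open and symmetric — before = [dst - h, dst),
after = [dst, dst + h) — so the DST day itself belongs to "after".  Nights
are the observations within a participant (serial correlation is ignored; a
documented limitation).  The circular sleep midtime is unfolded to minutes
after 18:00 before testing; means are reported back on the clock.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ALL_VARIABLES, CIRCULAR_VARIABLES, CohortPanel
from .night_metrics import delinearize_clock, linearize_clock
from .stats import two_sample_t

__all__ = ["DEFAULT_DST_DATE", "DEFAULT_HORIZONS", "DSTResult", "dst_windows", "dst_test", "dst_grid", "grid_frame"]

DEFAULT_DST_DATE = dt.date(2017, 10, 29)
DEFAULT_HORIZONS = (15, 30, 60)


@dataclass
class DSTResult:
    """Before/after comparison of one series at one horizon."""

    participant_id: str
    variable: str
    horizon_days: int
    n_before: int
    n_after: int
    mean_before: float
    mean_after: float
    t: float | None
    p: float | None
    significant: bool | None

    @property
    def computed(self) -> bool:
        return self.t is not None


def dst_windows(
    dst_date: dt.date, horizon_days: int
) -> tuple[tuple[dt.date, dt.date], tuple[dt.date, dt.date]]:
    """Half-open (start, end) date ranges on each side of the clock change.

    ``before = [dst - horizon, dst)`` and ``after = [dst, dst + horizon)``;
    both spans contain exactly ``horizon_days`` days regardless of month
    boundaries, and the DST day itself falls in "after".
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    h = dt.timedelta(days=horizon_days)
    return (dst_date - h, dst_date), (dst_date, dst_date + h)


def dst_test(
    series: pd.Series,
    dst_date: dt.date = DEFAULT_DST_DATE,
    horizon_days: int = 30,
    *,
    circular: bool = False,
    alpha: float = 0.05,
    participant_id: str = "",
    variable: str = "",
) -> DSTResult:
    """t test of before-vs-after values of one date-indexed series.

    With fewer than two observations on either side the means are still
    reported but the test fields stay ``None`` (reported, not computed).
    """
    (b0, b1), (a0, a1) = dst_windows(dst_date, horizon_days)
    s = series.dropna().sort_index()
    s.index = pd.DatetimeIndex(s.index)
    before = s[(s.index >= pd.Timestamp(b0)) & (s.index < pd.Timestamp(b1))].to_numpy()
    after = s[(s.index >= pd.Timestamp(a0)) & (s.index < pd.Timestamp(a1))].to_numpy()
    if circular:
        before_lin, after_lin = linearize_clock(before), linearize_clock(after)
    else:
        before_lin, after_lin = before, after

    def _mean(lin: np.ndarray) -> float:
        if lin.size == 0:
            return np.nan
        m = float(np.mean(lin))
        return float(delinearize_clock(m)) if circular else m

    mean_b, mean_a = _mean(before_lin), _mean(after_lin)
    if before.size < 2 or after.size < 2:
        return DSTResult(
            participant_id, variable, horizon_days,
            int(before.size), int(after.size), mean_b, mean_a, None, None, None,
        )
    t, p = two_sample_t(before_lin, after_lin, equal_var=True)
    return DSTResult(
        participant_id, variable, horizon_days,
        int(before.size), int(after.size), mean_b, mean_a, t, p, bool(p < alpha),
    )


def dst_grid(
    panel: CohortPanel,
    dst_date: dt.date = DEFAULT_DST_DATE,
    horizons=DEFAULT_HORIZONS,
    *,
    participants: list[str] | None = None,
    variables: list[str] | None = None,
    alpha: float = 0.05,
) -> list[DSTResult]:
    """One :class:`DSTResult` per participant x variable x horizon."""
    variables = variables or ALL_VARIABLES
    participants = participants or panel.participants
    if not participants:
        raise ValueError("dst_grid: empty panel")
    out: list[DSTResult] = []
    for pid in participants:
        for var in variables:
            s = panel.get_series(pid, var)
            for h in horizons:
                out.append(
                    dst_test(
                        s, dst_date, int(h),
                        circular=var in CIRCULAR_VARIABLES,
                        alpha=alpha, participant_id=pid, variable=var,
                    )
                )
    return out


def grid_frame(results: list[DSTResult]) -> pd.DataFrame:
    """Tidy frame of a DST grid, serializable as a checkmark table."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "variable": r.variable,
                "horizon": r.horizon_days,
                "n_before": r.n_before,
                "n_after": r.n_after,
                "mean_before": r.mean_before,
                "mean_after": r.mean_after,
                "t": r.t,
                "p": r.p,
                "significant": r.significant,
            }
            for r in results
        ]
    )
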