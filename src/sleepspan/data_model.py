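"""Domain types and CSV I/O for longitudinal sleep/activity panels.

A *panel* is the long-format union of per-night sleep records (one scored
night per participant per date, produced by an under-mattress sleep sensor)
and per-day activity records (steps and daytime heart rate from a wrist
wearable).  Nights are keyed by the calendar date of the evening of sleep
onset, so the night spanning a clock change belongs unambiguously to one
date.  Gaps are allowed: a missing night is an absent row, never a sentinel.

All validation is *total*: every input row is either accepted or yields a
row-level :class:`Diagnostic`; rows are never silently dropped.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NIGHT_COLUMNS",
    "DAY_COLUMNS",
    "NIGHT_VARIABLES",
    "DAY_VARIABLES",
    "ALL_VARIABLES",
    "CIRCULAR_VARIABLES",
    "STAGE_SUM_TOL_H",
    "Diagnostic",
    "PanelSchemaError",
    "PanelIntegrityError",
    "PanelValidationError",
    "NightRecord",
    "DayRecord",
    "Hypnogram",
    "CohortPanel",
    "read_panel",
    "write_panel",
    "read_hypnograms",
    "write_hypnograms",
]

NIGHT_COLUMNS = [
    "participant_id",
    "night_date",
    "total_in_bed_h",
    "tst_h",
    "sol_min",
    "n_awake",
    "deep_h",
    "rem_h",
    "light_h",
    "sleep_midtime_min",
    "nocturnal_hr_bpm",
]
DAY_COLUMNS = ["participant_id", "day_date", "steps", "diurnal_hr_bpm"]

#: The 11 analysis variables, in the order they are conventionally tabulated.
NIGHT_VARIABLES = [
    "nocturnal_hr_bpm",
    "total_in_bed_h",
    "tst_h",
    "sol_min",
    "n_awake",
    "deep_h",
    "rem_h",
    "light_h",
    "sleep_midtime_min",
]
DAY_VARIABLES = ["steps", "diurnal_hr_bpm"]
ALL_VARIABLES = ["steps", "diurnal_hr_bpm"] + NIGHT_VARIABLES

#: Variables that live on the 24-hour clock and need circular treatment.
CIRCULAR_VARIABLES = frozenset({"sleep_midtime_min"})

#: Stage totals may exceed TST by up to one minute (rounding of per-minute
#: stage counts); TST itself spans onset to final wake and may include
#: intra-sleep wake, so ``deep+rem+light <= tst + tolerance``.
STAGE_SUM_TOL_H = 1.0 / 60.0

_FLOAT_TOL = 1e-9

STAGES = ("WAKE", "LIGHT", "DEEP", "REM")


@dataclass(frozen=True)
class Diagnostic:
    """A located validation message for one input row."""

    source: str  # "nights" | "days" | "hypnogram"
    row: int  # 0-based data-row index within the file
    participant_id: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.source}[row {self.row}] ({self.participant_id}): {self.message}"


class PanelSchemaError(ValueError):
    """A required column is missing or the file cannot be parsed at all."""


class PanelIntegrityError(ValueError):
    """Duplicate (participant, date) keys."""


class PanelValidationError(ValueError):
    """One or more rows violated a hard invariant.

    The offending rows are listed in :attr:`diagnostics`.
    """

    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        preview = "; ".join(str(d) for d in diagnostics[:5])
        more = "" if len(diagnostics) <= 5 else f" (+{len(diagnostics) - 5} more)"
        super().__init__(f"{len(diagnostics)} invalid row(s): {preview}{more}")


@dataclass
class NightRecord:
    """One scored night of sleep variables for one participant."""

    participant_id: str
    night_date: dt.date
    total_in_bed_h: float
    tst_h: float
    sol_min: float
    n_awake: int
    deep_h: float
    rem_h: float
    light_h: float
    sleep_midtime_min: float
    nocturnal_hr_bpm: float | None = None

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        out: list[str] = []
        if self.tst_h < -_FLOAT_TOL or self.tst_h > self.total_in_bed_h + _FLOAT_TOL:
            out.append(
                f"tst_h={self.tst_h} outside [0, total_in_bed_h={self.total_in_bed_h}]"
            )
        stage_sum = self.deep_h + self.rem_h + self.light_h
        if stage_sum > self.tst_h + STAGE_SUM_TOL_H + _FLOAT_TOL:
            out.append(
                f"stage sum {stage_sum:.4f} h exceeds tst_h={self.tst_h} + 1 min tolerance"
            )
        if self.sol_min < -_FLOAT_TOL:
            out.append(f"sol_min={self.sol_min} < 0")
        if self.n_awake < 0 or float(self.n_awake) != int(self.n_awake):
            out.append(f"n_awake={self.n_awake} not a nonnegative integer")
        if min(self.deep_h, self.rem_h, self.light_h) < -_FLOAT_TOL:
            out.append("negative stage duration")
        if not (0.0 <= self.sleep_midtime_min < 1440.0):
            out.append(f"sleep_midtime_min={self.sleep_midtime_min} outside [0, 1440)")
        return out


@dataclass
class DayRecord:
    """One day of activity for one participant."""

    participant_id: str
    day_date: dt.date
    steps: int
    diurnal_hr_bpm: float | None = None

    def violations(self) -> list[str]:
        out: list[str] = []
        if self.steps < 0:
            out.append(f"steps={self.steps} < 0")
        return out


@dataclass
class Hypnogram:
    """Per-minute stage sequence for one in-bed interval.

    ``stages[0]`` is the first in-bed minute; the sequence length equals the
    whole minutes between bed entry and bed exit.
    """

    participant_id: str
    night_date: dt.date
    bed_entry: dt.datetime
    stages: list[str]

    def violations(self) -> list[str]:
        out: list[str] = []
        if len(self.stages) < 1:
            out.append("empty stage sequence")
        bad = sorted({s for s in self.stages} - set(STAGES))
        if bad:
            out.append(f"unknown stage label(s): {bad}")
        return out

    @property
    def bed_entry_clock_min(self) -> float:
        t = self.bed_entry.time()
        return t.hour * 60 + t.minute + t.second / 60.0


@dataclass
class CohortPanel:
    """Date-indexed nights and days for many participants; gaps allowed.

    Backed by two tidy :class:`pandas.DataFrame` objects with the CSV column
    schema.  At most one night and one day row exist per (participant, date).
    """

    nights: pd.DataFrame
    days: pd.DataFrame

    def __post_init__(self) -> None:
        self.nights = _coerce_frame(self.nights, NIGHT_COLUMNS, "night_date")
        self.days = _coerce_frame(self.days, DAY_COLUMNS, "day_date")
        for df, key, label in (
            (self.nights, "night_date", "nights"),
            (self.days, "day_date", "days"),
        ):
            dup = df.duplicated(subset=["participant_id", key])
            if dup.any():
                pairs = df.loc[dup, ["participant_id", key]].head(5).values.tolist()
                raise PanelIntegrityError(
                    f"duplicate (participant, date) in {label}: {pairs}"
                )

    # -- queries -----------------------------------------------------------
    @property
    def participants(self) -> list[str]:
        ids = set(self.nights["participant_id"]) | set(self.days["participant_id"])
        return sorted(ids)

    def date_range(self, participant_id: str) -> tuple[dt.date, dt.date] | None:
        dates = pd.concat(
            [
                self.nights.loc[
                    self.nights["participant_id"] == participant_id, "night_date"
                ],
                self.days.loc[
                    self.days["participant_id"] == participant_id, "day_date"
                ],
            ]
        )
        if dates.empty:
            return None
        return dates.min().date(), dates.max().date()

    def get_series(self, participant_id: str, variable: str) -> pd.Series:
        """Date-indexed series of one variable for one participant.

        Missing nights/days are simply absent from the index.
        """
        if variable in DAY_VARIABLES:
            df, key = self.days, "day_date"
        elif variable in NIGHT_VARIABLES:
            df, key = self.nights, "night_date"
        else:
            raise KeyError(f"unknown variable {variable!r}; expected one of {ALL_VARIABLES}")
        sub = df[df["participant_id"] == participant_id]
        s = pd.Series(
            sub[variable].to_numpy(dtype=float),
            index=pd.DatetimeIndex(sub[key]),
            name=variable,
        ).sort_index()
        return s.dropna()

    @classmethod
    def empty(cls) -> "CohortPanel":
        return cls(
            nights=pd.DataFrame(columns=NIGHT_COLUMNS),
            days=pd.DataFrame(columns=DAY_COLUMNS),
        )


def _coerce_frame(df: pd.DataFrame, columns: list[str], datecol: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing column(s): {missing}")
    df = df[columns].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df[datecol] = pd.to_datetime(df[datecol])
    return df.sort_values(["participant_id", datecol], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# Row validation
# ---------------------------------------------------------------------------

_NIGHT_REQUIRED = [c for c in NIGHT_COLUMNS if c != "nocturnal_hr_bpm"]
_DAY_REQUIRED = [c for c in DAY_COLUMNS if c != "diurnal_hr_bpm"]


def _validate_rows(
    df: pd.DataFrame, source: str, datecol: str, required: list[str]
) -> list[Diagnostic]:
    diags: list[Diagnostic] = []
    record_cls = NightRecord if source == "nights" else DayRecord
    for i, row in df.iterrows():
        pid = None if pd.isna(row.get("participant_id")) else str(row["participant_id"])
        missing = [c for c in required if pd.isna(row[c])]
        if missing:
            diags.append(Diagnostic(source, int(i), pid, f"missing required value(s): {missing}"))
            continue
        kwargs = {c: row[c] for c in df.columns if c not in ("participant_id", datecol)}
        kwargs = {k: (None if pd.isna(v) else v) for k, v in kwargs.items()}
        if source == "nights":
            kwargs["n_awake"] = float(kwargs["n_awake"])
        rec = record_cls(
            participant_id=pid,
            **{datecol if source != "nights" else "night_date": row[datecol].date()},
            **kwargs,
        )
        for msg in rec.violations():
            diags.append(Diagnostic(source, int(i), pid, msg))
    return diags


def _read_csv(path: str | Path, columns: list[str], datecol: str, source: str):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError as exc:
        raise PanelSchemaError(f"{path} has no header row") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path}: missing column(s) {missing}")
    diags: list[Diagnostic] = []
    parsed = pd.to_datetime(df[datecol], errors="coerce")
    for i in np.flatnonzero(parsed.isna() & df[datecol].notna()):
        diags.append(
            Diagnostic(source, int(i), str(df.loc[i, "participant_id"]),
                       f"unparseable date {df.loc[i, datecol]!r}")
        )
    for i in np.flatnonzero(df[datecol].isna()):
        diags.append(Diagnostic(source, int(i), str(df.loc[i, "participant_id"]), "missing date"))
    df[datecol] = parsed
    return df, diags


def read_panel(nights_path: str | Path, days_path: str | Path) -> CohortPanel:
    """Read and validate a panel from ``nights.csv`` and ``days.csv``.

    Raises
    ------
    PanelSchemaError
        A required column is absent.
    PanelIntegrityError
        Duplicate (participant, date) keys.
    PanelValidationError
        One or more rows violate a hard invariant; every offending row is
        reported in ``.diagnostics``.
    """
    nights, diags_n = _read_csv(nights_path, NIGHT_COLUMNS, "night_date", "nights")
    days, diags_d = _read_csv(days_path, DAY_COLUMNS, "day_date", "days")
    diags = diags_n + diags_d
    ok_n = nights[nights["night_date"].notna()]
    ok_d = days[days["day_date"].notna()]
    diags += _validate_rows(ok_n, "nights", "night_date", _NIGHT_REQUIRED)
    diags += _validate_rows(ok_d, "days", "day_date", _DAY_REQUIRED)
    if diags:
        raise PanelValidationError(diags)
    return CohortPanel(nights=nights, days=days)


def write_panel(panel: CohortPanel, out_dir: str | Path) -> dict[str, Path]:
    """Write ``nights.csv`` and ``days.csv``; round-trips losslessly.

    Floats are written with ``repr`` precision so ``read_panel`` reproduces
    every field bit-for-bit; missing values become empty cells.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nights": out_dir / "nights.csv",
        "days": out_dir / "days.csv",
    }
    for key, df, datecol in (
        ("nights", panel.nights, "night_date"),
        ("days", panel.days, "day_date"),
    ):
        out = df.copy()
        out[datecol] = out[datecol].dt.strftime("%Y-%m-%d")
        out.to_csv(paths[key], index=False)
    return paths


# ---------------------------------------------------------------------------
# Hypnogram I/O: one row per minute (participant_id, night_date, minute_index, stage)
# ---------------------------------------------------------------------------

def write_hypnograms(hypnograms: list[Hypnogram], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for h in hypnograms:
        for i, stage in enumerate(h.stages):
            rows.append(
                {
                    "participant_id": h.participant_id,
                    "night_date": h.night_date.isoformat(),
                    "bed_entry": h.bed_entry.isoformat(),
                    "minute_index": i,
                    "stage": stage,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_hypnograms(path: str | Path) -> list[Hypnogram]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "night_date", "bed_entry", "minute_index", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise PanelSchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out: list[Hypnogram] = []
    for (pid, date, entry), grp in df.groupby(
        ["participant_id", "night_date", "bed_entry"], sort=True
    ):
        grp = grp.sort_values("minute_index")
        idx = grp["minute_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise PanelValidationError(
                [Diagnostic("hypnogram", int(idx[0]), pid, "non-contiguous minute_index")]
            )
        h = Hypnogram(
            participant_id=pid,
            night_date=dt.date.fromisoformat(str(date)),
            bed_entry=dt.datetime.fromisoformat(str(entry)),
            stages=list(grp["stage"]),
        )
        bad = h.violations()
        if bad:
            raise PanelValidationError(
                [Diagnostic("hypnogram", 0, pid, m) for m in bad]
            )
        out.append(h)
    return out
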