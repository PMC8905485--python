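"""Scoring of per-minute hypnograms and circular statistics for sleep midtime.

The sleep-sensor variables are derived from a per-minute stage sequence
(WAKE/LIGHT/DEEP/REM) over one in-bed interval:

* sleep onset          = first non-WAKE minute (minute 0 is bed entry)
* final wake           = minute after the last non-WAKE minute
* total sleep time     = onset -> final wake, *including* intra-sleep wake
* number of awakenings = maximal WAKE runs strictly inside the sleep period
* sleep midtime        = clock time halfway along the onset->wake arc,
                         a circular quantity on the 1440-minute day

Sleep onset uses the simplest consistent rule (first non-WAKE minute, no
"N consecutive minutes" requirement) and an awakening is any interior WAKE
run of >= 1 minute; both are configurable at scoring time.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import Hypnogram, NightRecord

__all__ = [
    "NoSleepError",
    "UndefinedCircularMeanError",
    "ScoredNight",
    "score_hypnogram",
    "sleep_midtime",
    "circular_mean_sd",
    "linearize_clock",
    "delinearize_clock",
    "LINEAR_REFERENCE_MIN",
]

MINUTES_PER_DAY = 1440.0

#: Reference clock time (18:00) used to unfold sleep midtimes onto a line.
#: Midtimes cluster in the night, far from the 18:00 cut, so ordinary means,
#: SDs and t tests are safe on the unfolded scale.
LINEAR_REFERENCE_MIN = 1080.0


class NoSleepError(ValueError):
    """The hypnogram contains no non-WAKE minute; the night is unscorable."""


class UndefinedCircularMeanError(ValueError):
    """Zero resultant vector: the circular mean is undefined."""


@dataclass
class ScoredNight:
    """A scored in-bed interval: onset/final-wake indices plus the derived record."""

    onset_index: int
    final_wake_index: int
    record: NightRecord


def score_hypnogram(
    h: Hypnogram,
    *,
    onset_run_min: int = 1,
    min_awakening_min: int = 1,
) -> ScoredNight:
    """Derive the per-night sleep variables from a per-minute hypnogram.

    Parameters
    ----------
    h
        Per-minute stage sequence with its bed-entry timestamp.
    onset_run_min
        Number of consecutive non-WAKE minutes required to declare sleep
        onset.  Default 1: onset is the first non-WAKE minute.
    min_awakening_min
        Minimum length of an interior WAKE run to count as an awakening.
        Default 1 (the device's own threshold is unknown).

    Raises
    ------
    NoSleepError
        If no qualifying sleep onset exists.
    """
    stages = np.asarray(h.stages, dtype=object)
    n = stages.size
    asleep = stages != "WAKE"
    if not asleep.any():
        raise NoSleepError(f"{h.participant_id} {h.night_date}: all-WAKE hypnogram")

    if onset_run_min <= 1:
        onset = int(np.argmax(asleep))
    else:
        run = 0
        onset = None
        for i, a in enumerate(asleep):
            run = run + 1 if a else 0
            if run >= onset_run_min:
                onset = i - onset_run_min + 1
                break
        if onset is None:
            raise NoSleepError(
                f"{h.participant_id} {h.night_date}: no {onset_run_min}-minute sleep run"
            )
    final_wake = int(n - np.argmax(asleep[::-1]))  # minute after last non-WAKE

    interior = stages[onset:final_wake]
    wake_runs = _run_lengths(interior == "WAKE")
    n_awake = int(sum(1 for L in wake_runs if L >= min_awakening_min))

    deep = int(np.sum(interior == "DEEP"))
    rem = int(np.sum(interior == "REM"))
    light = int(np.sum(interior == "LIGHT"))

    midtime = (h.bed_entry_clock_min + (onset + final_wake) / 2.0) % MINUTES_PER_DAY
    record = NightRecord(
        participant_id=h.participant_id,
        night_date=h.night_date,
        total_in_bed_h=n / 60.0,
        tst_h=(final_wake - onset) / 60.0,
        sol_min=float(onset),
        n_awake=n_awake,
        deep_h=deep / 60.0,
        rem_h=rem / 60.0,
        light_h=light / 60.0,
        sleep_midtime_min=midtime,
        nocturnal_hr_bpm=None,
    )
    return ScoredNight(onset_index=onset, final_wake_index=final_wake, record=record)


def _run_lengths(mask: np.ndarray) -> list[int]:
    """Lengths of maximal True runs in a boolean sequence."""
    out: list[int] = []
    run = 0
    for v in mask:
        if v:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def sleep_midtime(onset_clock_min: float, wake_clock_min: float) -> float:
    """Clock time halfway along the forward arc from onset to final wake.

    Both arguments are minutes after midnight in [0, 1440); the sleep
    interval runs forward from onset, wrapping midnight when wake < onset.
    """
    for name, v in (("onset", onset_clock_min), ("wake", wake_clock_min)):
        if not (0.0 <= v < MINUTES_PER_DAY):
            raise ValueError(f"{name} clock {v} outside [0, 1440)")
    duration = (wake_clock_min - onset_clock_min) % MINUTES_PER_DAY
    return (onset_clock_min + duration / 2.0) % MINUTES_PER_DAY


def circular_mean_sd(times_min) -> tuple[float, float]:
    """Circular mean and SD of clock times on the 1440-minute day.

    The mean is the argument of the mean resultant vector; the SD is
    ``sqrt(-2 ln R)`` rescaled from radians to minutes.  Rotation
    equivariant: shifting all inputs by ``c`` (mod 1440) shifts the mean by
    ``c`` and leaves the SD unchanged.

    Raises
    ------
    ValueError
        Empty input.
    UndefinedCircularMeanError
        Zero resultant vector (e.g. antipodal pairs): no mean direction.
    """
    x = np.asarray(times_min, dtype=float)
    if x.size == 0:
        raise ValueError("circular_mean_sd: empty input")
    theta = x * (2.0 * math.pi / MINUTES_PER_DAY)
    R = float(np.hypot(np.mean(np.sin(theta)), np.mean(np.cos(theta))))
    if R < 1e-12:
        raise UndefinedCircularMeanError(
            "zero mean resultant vector: circular mean undefined"
        )
    mean = float(stats.circmean(x, high=MINUTES_PER_DAY, low=0.0))
    sd = float(stats.circstd(x, high=MINUTES_PER_DAY, low=0.0))
    return mean % MINUTES_PER_DAY, sd


def linearize_clock(times_min, reference_min: float = LINEAR_REFERENCE_MIN):
    """Unfold clock times to minutes-after-``reference`` in [0, 1440).

    With the default 18:00 reference, a 23:30 midtime maps to 330 and an
    02:00 midtime to 480, so night-time values are contiguous and ordinary
    statistics apply.
    """
    return np.mod(np.asarray(times_min, dtype=float) - reference_min, MINUTES_PER_DAY)


def delinearize_clock(values, reference_min: float = LINEAR_REFERENCE_MIN):
    """Inverse of :func:`linearize_clock`."""
    return np.mod(np.asarray(values, dtype=float) + reference_min, MINUTES_PER_DAY)
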