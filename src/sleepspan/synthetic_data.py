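"""Synthetic longitudinal sleep/activity cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume for a free-living self-tracker study: ~54 adults observed between a
staggered enrollment (June-September 2017) and a common stop date (December
28, 2017), spanning the October 29 DST clock change.  For participant *i*,
variable *v* and date *t* the latent nightly value is

    y_ivt = mu_v + cluster_offset_v + b_iv + slope_v (t - t0)
            + delta_v 1[t >= dst_date] + eps_ivt

with participant random effects ``b_iv ~ N(0, sd_between_v)`` and nightly
noise ``eps ~ N(0, sd_within_v)``.  Default population means and
between-participant SDs follow the reference cohort summary (step counts
around 4.9k/day, TST near 6.9 h, roughly two awakenings per night, sleep
midtime a little after 3 AM); defaults plant a declining step trend, a
rising time-in-bed trend, a DST-linked jump in sleep-onset latency, a later
midtime and reduced REM after the clock change, and a second cluster offset
by about one awakening per night.

Distributional choices keep configured means exact under the hard record
invariants:

* counts (steps, awakenings) are floored-at-zero rounded Gaussians whose
  latent mean is analytically corrected so the post-floor mean equals the
  configured one;
* sleep-onset latency is log-normal (strictly positive, right-skewed) with
  its mean set exactly;
* TST is *derived* as deep + REM + light + a small intra-sleep wake term,
  so the stage-sum invariant holds by construction and stage/TST means stay
  exact; the configured TST SD is therefore implied rather than set;
* time in bed is TST + SOL + a nonnegative terminal-slack term whose mean
  is chosen so time in bed hits its configured mean;
* sleep midtime is generated on the 1440-minute circle.

Nights and days are deleted independently (MCAR) at the missingness rate.
Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import (
    ALL_VARIABLES,
    DAY_COLUMNS,
    NIGHT_COLUMNS,
    CohortPanel,
    Hypnogram,
)

__all__ = [
    "VariableSpec",
    "SyntheticConfig",
    "GroundTruth",
    "InfeasibleTargetsError",
    "default_variables",
    "null_variables",
    "planted_two_cluster_config",
    "generate_cohort",
    "generate_hypnogram",
]

MINUTES_PER_DAY = 1440.0

#: Mean intra-sleep wake in hours (TST minus stage sum).  The reference
#: cohort's stage durations sum to within a minute of its TST, so the
#: residual wake inside the sleep period is tiny.
WAKE_WITHIN_MEAN_H = 0.01
WAKE_WITHIN_SD_H = 0.05

_STAGE_FLOOR_H = 0.02
_SLACK_FLOOR_H = 0.005


class InfeasibleTargetsError(ValueError):
    """The requested night targets cannot be realized as a hypnogram."""


@dataclass(frozen=True)
class VariableSpec:
    """Population parameters for one variable.

    mu          population mean (units of the variable)
    sd_between  between-participant SD of the random effect
    sd_within   night-to-night (or day-to-day) noise SD
    slope_per_day   linear seasonal trend, units/day from study start
    dst_delta   step change applied from the DST date onward
    kind        sampling family: "continuous", "count", "lognormal",
                "circular"
    """

    mu: float
    sd_between: float
    sd_within: float
    slope_per_day: float = 0.0
    dst_delta: float = 0.0
    kind: str = "continuous"


def default_variables() -> dict[str, VariableSpec]:
    """Defaults reproducing the reference cohort's scale and trends."""
    return {
        "steps": VariableSpec(4895.97, 2772.25, 1500.0, slope_per_day=-6.0, kind="count"),
        "diurnal_hr_bpm": VariableSpec(58.89, 5.91, 3.0),
        "nocturnal_hr_bpm": VariableSpec(61.10, 6.02, 2.5),
        "total_in_bed_h": VariableSpec(7.81, 0.82, 0.30, slope_per_day=0.0015),
        "tst_h": VariableSpec(6.86, 0.99, 0.90),  # derived; SDs implied (see module docstring)
        "sol_min": VariableSpec(10.22, 5.25, 6.0, dst_delta=5.0, kind="lognormal"),
        "n_awake": VariableSpec(2.03, 0.93, 1.2, kind="count"),
        "deep_h": VariableSpec(2.18, 0.68, 0.40),
        "rem_h": VariableSpec(1.54, 0.34, 0.35, dst_delta=-0.20),
        "light_h": VariableSpec(3.13, 0.56, 0.50),
        "sleep_midtime_min": VariableSpec(11249.91 / 60.0, 2645.61 / 60.0, 40.0,
                                          dst_delta=20.0, kind="circular"),
    }


def null_variables() -> dict[str, VariableSpec]:
    """Defaults with all trends and DST effects zeroed (stationary cohort)."""
    return {
        name: replace(spec, slope_per_day=0.0, dst_delta=0.0)
        for name, spec in default_variables().items()
    }


@dataclass
class SyntheticConfig:
    """Full description of a synthetic cohort (see module docstring)."""

    n_participants: int = 54
    enrollment_start: dt.date = dt.date(2017, 6, 7)
    enrollment_end: dt.date = dt.date(2017, 9, 25)
    study_end: dt.date = dt.date(2017, 12, 28)
    dst_date: dt.date = dt.date(2017, 10, 29)
    variables: dict[str, VariableSpec] = field(default_factory=default_variables)
    #: fraction of participants in the offset (second) cluster
    cluster_frac: float = 0.5
    #: per-variable mean offsets applied to second-cluster members
    cluster_offsets: dict[str, float] = field(
        default_factory=lambda: {"n_awake": 1.03}
    )
    #: optional per-variable within-SD override for second-cluster members
    cluster_sd_within: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.10
    #: intra-sleep wake (TST minus stage sum), hours: mean and nightly SD
    wake_within_mean_h: float = WAKE_WITHIN_MEAN_H
    wake_within_sd_h: float = WAKE_WITHIN_SD_H
    #: if set, DST deltas decay linearly to zero over this many days
    #: (transient instead of step); off by default
    dst_decay_days: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.cluster_frac <= 1.0):
            raise ValueError("cluster_frac must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.enrollment_start > self.enrollment_end:
            raise ValueError("enrollment_start after enrollment_end")
        if self.enrollment_end >= self.study_end:
            raise ValueError("enrollment_end must precede study_end")
        unknown = set(self.variables) - set(ALL_VARIABLES)
        if unknown:
            raise ValueError(f"unknown variable spec(s): {sorted(unknown)}")
        for name, spec in self.variables.items():
            if spec.sd_between < 0 or spec.sd_within < 0:
                raise ValueError(f"{name}: negative SD")
        any_delta = any(s.dst_delta != 0 for s in self.variables.values())
        if any_delta and not (self.enrollment_start <= self.dst_date <= self.study_end):
            raise ValueError(
                "dst_date outside the study range while DST deltas are nonzero"
            )

    # -- (de)serialization for YAML configs --------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("enrollment_start", "enrollment_end", "study_end", "dst_date"):
            d[key] = d[key].isoformat()
        d["variables"] = {k: dataclasses.asdict(v) for k, v in self.variables.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("enrollment_start", "enrollment_end", "study_end", "dst_date"):
            if key in d and isinstance(d[key], str):
                d[key] = dt.date.fromisoformat(d[key])
        if "variables" in d:
            d["variables"] = {
                k: v if isinstance(v, VariableSpec) else VariableSpec(**v)
                for k, v in d["variables"].items()
            }
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator knows: labels, random effects, start dates."""

    cluster_labels: pd.Series  # participant -> 1 or 2
    random_effects: pd.DataFrame  # participant x variable
    start_dates: pd.Series  # participant -> first logging date
    config: SyntheticConfig
    seed: int

    def expected_mean(self, participant_id: str, variable: str, date: dt.date) -> float:
        """Noise-free expected value for one participant/variable/date."""
        cfg = self.config
        if variable == "tst_h":
            return (
                sum(self.expected_mean(participant_id, v, date)
                    for v in ("deep_h", "rem_h", "light_h"))
                + cfg.wake_within_mean_h
            )
        if variable == "total_in_bed_h":
            # population mean path plus the stage and SOL random effects it
            # inherits (see generate_cohort: slack targets the population path)
            stage_b = sum(
                self.random_effects.loc[participant_id, v]
                for v in ("deep_h", "rem_h", "light_h")
            )
            sol_b = self.random_effects.loc[participant_id, "sol_min"] / 60.0
            spec = cfg.variables[variable]
            t = (date - cfg.enrollment_start).days
            val = spec.mu + spec.slope_per_day * t + stage_b + sol_b
            if self.cluster_labels[participant_id] == 2:
                val += cfg.cluster_offsets.get(variable, 0.0)
            if date >= cfg.dst_date:
                val += _dst_factor(cfg, date) * spec.dst_delta
            return float(val)
        spec = cfg.variables[variable]
        t = (date - cfg.enrollment_start).days
        val = spec.mu + spec.slope_per_day * t
        val += self.random_effects.loc[participant_id, variable]
        if self.cluster_labels[participant_id] == 2:
            val += cfg.cluster_offsets.get(variable, 0.0)
        if date >= cfg.dst_date:
            val += _dst_factor(cfg, date) * spec.dst_delta
        return float(val)


def _dst_factor(cfg: SyntheticConfig, date: dt.date) -> float:
    if cfg.dst_decay_days is None:
        return 1.0
    age = (date - cfg.dst_date).days
    return max(0.0, 1.0 - age / cfg.dst_decay_days)


# ---------------------------------------------------------------------------
# Mean-exact samplers
# ---------------------------------------------------------------------------

_K = np.linspace(-8.0, 12.0, 4001)
_G = _K * norm.cdf(_K) + norm.pdf(_K)  # E[max(N(k,1),0)], monotone in k


def _floored_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """max(Normal, 0) with the latent mean corrected so E[result] == mean."""
    mean = np.broadcast_to(np.asarray(mean, float), size).copy()
    sd = np.broadcast_to(np.asarray(sd, float), size)
    out = np.empty(size)
    zero_sd = sd == 0.0
    out[zero_sd] = np.maximum(mean[zero_sd], 0.0)
    if (~zero_sd).any():
        k_target = mean[~zero_sd] / sd[~zero_sd]
        k_latent = np.interp(k_target, _G, _K)
        draw = rng.normal(k_latent * sd[~zero_sd], sd[~zero_sd])
        out[~zero_sd] = np.maximum(draw, 0.0)
    return out


def _lognormal_mean(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Log-normal draws with E[result] == mean exactly."""
    mean = np.maximum(np.broadcast_to(np.asarray(mean, float), size), 1e-6)
    sd = np.broadcast_to(np.asarray(sd, float), size)
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[CohortPanel, GroundTruth]:
    """Draw a full cohort panel plus its ground truth.

    Reproducible: the same (config, seed) yields an identical panel.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_participants
    pids = [f"p{i + 1:03d}" for i in range(n)]

    n_cluster2 = int(round(config.cluster_frac * n))
    labels = np.ones(n, dtype=int)
    labels[rng.permutation(n)[:n_cluster2]] = 2
    cluster_labels = pd.Series(labels, index=pids, name="cluster")

    effects = pd.DataFrame(
        {
            v: rng.normal(0.0, config.variables[v].sd_between, n)
            for v in ALL_VARIABLES
        },
        index=pids,
    )

    window = (config.enrollment_end - config.enrollment_start).days
    start_offsets = rng.integers(0, window + 1, n)
    start_dates = pd.Series(
        [config.enrollment_start + dt.timedelta(days=int(o)) for o in start_offsets],
        index=pids,
        name="start_date",
    )

    night_frames: list[pd.DataFrame] = []
    day_frames: list[pd.DataFrame] = []
    t0 = pd.Timestamp(config.enrollment_start)
    dst = pd.Timestamp(config.dst_date)
    for i, pid in enumerate(pids):
        dates = pd.date_range(start_dates[pid], config.study_end, freq="D")
        m = len(dates)
        t = np.asarray((dates - t0).days, dtype=float)
        after = np.asarray(dates >= dst, dtype=float)
        if config.dst_decay_days is not None:
            age = np.asarray((dates - dst).days, dtype=float)
            after *= np.clip(1.0 - age / config.dst_decay_days, 0.0, 1.0)

        def pop_mean_of(var: str) -> np.ndarray:
            spec = config.variables[var]
            val = spec.mu + spec.slope_per_day * t + spec.dst_delta * after
            if labels[i] == 2:
                val = val + config.cluster_offsets.get(var, 0.0)
            return val

        def mean_of(var: str) -> np.ndarray:
            return pop_mean_of(var) + effects.loc[pid, var]

        def sd_of(var: str) -> float:
            if labels[i] == 2 and var in config.cluster_sd_within:
                return config.cluster_sd_within[var]
            return config.variables[var].sd_within

        deep = _floor_cont(rng, mean_of("deep_h"), sd_of("deep_h"), m)
        rem = _floor_cont(rng, mean_of("rem_h"), sd_of("rem_h"), m)
        light = _floor_cont(rng, mean_of("light_h"), sd_of("light_h"), m)
        wake = _floored_normal(rng, config.wake_within_mean_h, config.wake_within_sd_h, m)
        tst = deep + rem + light + wake
        sol = _lognormal_mean(rng, mean_of("sol_min"), sd_of("sol_min"), m)

        # Terminal slack targets the *population* mean path of time in bed:
        # subtracting participant-level stage effects here would push many
        # slack targets below the zero floor and bias time in bed upward.
        # Between-participant variation in time in bed is therefore inherited
        # from TST and SOL rather than set independently.
        exp_tst = (
            pop_mean_of("deep_h") + pop_mean_of("rem_h") + pop_mean_of("light_h")
            + config.wake_within_mean_h
        )
        slack_mean = (
            pop_mean_of("total_in_bed_h") - exp_tst - pop_mean_of("sol_min") / 60.0
        )
        slack = _floored_normal(rng, slack_mean, sd_of("total_in_bed_h"), m)
        in_bed = tst + sol / 60.0 + np.maximum(slack, _SLACK_FLOOR_H)

        n_awake = np.round(
            _floored_normal(rng, mean_of("n_awake"), sd_of("n_awake"), m)
        )
        midtime = np.mod(
            rng.normal(mean_of("sleep_midtime_min"), sd_of("sleep_midtime_min")),
            MINUTES_PER_DAY,
        )
        noct_hr = rng.normal(mean_of("nocturnal_hr_bpm"), sd_of("nocturnal_hr_bpm"))
        steps = np.round(_floored_normal(rng, mean_of("steps"), sd_of("steps"), m))
        diur_hr = rng.normal(mean_of("diurnal_hr_bpm"), sd_of("diurnal_hr_bpm"))

        keep_nights = rng.random(m) >= config.missing_rate
        keep_days = rng.random(m) >= config.missing_rate
        night_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "night_date": dates,
                    "total_in_bed_h": in_bed,
                    "tst_h": tst,
                    "sol_min": sol,
                    "n_awake": n_awake,
                    "deep_h": deep,
                    "rem_h": rem,
                    "light_h": light,
                    "sleep_midtime_min": midtime,
                    "nocturnal_hr_bpm": noct_hr,
                }
            )[keep_nights]
        )
        day_frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "day_date": dates,
                    "steps": steps,
                    "diurnal_hr_bpm": diur_hr,
                }
            )[keep_days]
        )

    panel = CohortPanel(
        nights=pd.concat(night_frames, ignore_index=True)[NIGHT_COLUMNS],
        days=pd.concat(day_frames, ignore_index=True)[DAY_COLUMNS],
    )
    truth = GroundTruth(cluster_labels, effects, start_dates, config, seed)
    return panel, truth


def _floor_cont(rng, mean, sd, size) -> np.ndarray:
    """Continuous stage draw, floored at a small positive duration."""
    if np.ndim(sd) == 0 and sd == 0:
        return np.maximum(np.broadcast_to(np.asarray(mean, float), size), _STAGE_FLOOR_H).copy()
    return np.maximum(rng.normal(mean, sd, size), _STAGE_FLOOR_H)


# ---------------------------------------------------------------------------
# Convenience configurations
# ---------------------------------------------------------------------------

def planted_two_cluster_config(
    n_participants: int = 50,
    n_days: int = 30,
    *,
    mean_1: float = 2.03,
    sd_1: float = 0.93,
    mean_2: float = 3.06,
    sd_2: float = 1.27,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SyntheticConfig:
    """Two clusters separated only in the number of awakenings.

    All other variables are identical constants across participants (no
    between- or within-participant noise), so cluster structure lives
    entirely in the awakening count: nightly values N(mean_1, sd_1) in the
    first cluster versus N(mean_2, sd_2) in the second, with no additional
    between-participant heterogeneity.
    """
    base = null_variables()
    variables = {
        name: replace(spec, sd_between=0.0, sd_within=0.0)
        for name, spec in base.items()
    }
    variables["n_awake"] = VariableSpec(mean_1, 0.0, sd_1, kind="count")
    end = dt.date(2017, 12, 28)
    start = end - dt.timedelta(days=n_days - 1)
    return SyntheticConfig(
        n_participants=n_participants,
        enrollment_start=start,
        enrollment_end=start,  # everyone spans the full window
        study_end=end,
        variables=variables,
        cluster_frac=0.5,
        cluster_offsets={"n_awake": mean_2 - mean_1},
        cluster_sd_within={"n_awake": sd_2},
        missing_rate=missing_rate,
        wake_within_sd_h=0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hypnogram synthesis
# ---------------------------------------------------------------------------

def generate_hypnogram(
    sol_min: int,
    n_awake: int,
    deep_min: int,
    rem_min: int,
    light_min: int,
    bed_minutes: int,
    seed: int = 0,
    *,
    participant_id: str = "p001",
    night_date: dt.date = dt.date(2017, 10, 1),
    bed_entry: dt.datetime | None = None,
) -> Hypnogram:
    """Per-minute stage sequence realizing exact night targets.

    Scoring the result reproduces ``sol_min``, ``n_awake`` and the three
    stage totals exactly: the sequence starts with ``sol_min`` WAKE
    minutes, contains the shuffled stage minutes split into ``n_awake + 1``
    non-empty sleep blocks separated by single interior WAKE minutes, and
    ends with terminal WAKE filling the remaining bed time.

    Raises
    ------
    InfeasibleTargetsError
        If the targets cannot fit in ``bed_minutes`` or the stage minutes
        cannot host ``n_awake`` interior awakenings.
    """
    for name, v in (
        ("sol_min", sol_min), ("n_awake", n_awake), ("deep_min", deep_min),
        ("rem_min", rem_min), ("light_min", light_min), ("bed_minutes", bed_minutes),
    ):
        if v < 0 or int(v) != v:
            raise InfeasibleTargetsError(f"{name}={v} must be a nonnegative integer")
    sleep_total = deep_min + rem_min + light_min
    if sleep_total < 1:
        raise InfeasibleTargetsError("need at least one sleep minute")
    if sleep_total < n_awake + 1:
        raise InfeasibleTargetsError(
            f"{sleep_total} sleep minutes cannot host {n_awake} interior awakenings"
        )
    needed = sol_min + sleep_total + n_awake
    if needed > bed_minutes:
        raise InfeasibleTargetsError(
            f"targets need {needed} minutes but bed_minutes={bed_minutes}"
        )
    rng = np.random.default_rng(seed)
    stage_minutes = (
        ["DEEP"] * deep_min + ["REM"] * rem_min + ["LIGHT"] * light_min
    )
    stage_minutes = [stage_minutes[j] for j in rng.permutation(sleep_total)]
    # split into n_awake+1 non-empty contiguous blocks
    if n_awake > 0:
        cuts = np.sort(rng.choice(np.arange(1, sleep_total), n_awake, replace=False))
    else:
        cuts = np.array([], dtype=int)
    blocks = np.split(np.asarray(stage_minutes, dtype=object), cuts)
    seq: list[str] = ["WAKE"] * sol_min
    for j, block in enumerate(blocks):
        if j > 0:
            seq.append("WAKE")
        seq.extend(block.tolist())
    seq.extend(["WAKE"] * (bed_minutes - len(seq)))
    if bed_entry is None:
        bed_entry = dt.datetime.combine(night_date, dt.time(23, 0))
    return Hypnogram(
        participant_id=participant_id,
        night_date=night_date,
        bed_entry=bed_entry,
        stages=seq,
    )
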