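"""Repeatable validation experiments on the synthetic generator.

Each function runs one of the package's headline simulation checks —
planted-cluster recovery, DST test calibration and power, stabilization-day
behaviour — and returns raw per-replicate results so callers can summarize
at whatever level they need.  All randomness flows from a single integer
seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .clustering import build_features, cluster, contrast_tests
from .data_model import ALL_VARIABLES, CIRCULAR_VARIABLES
from .dst_effects import dst_grid, grid_frame
from .synthetic_data import (
    SyntheticConfig,
    generate_cohort,
    null_variables,
    planted_two_cluster_config,
)
from .variability import cumulative_sd, stabilization_day

__all__ = [
    "planted_cluster_recovery",
    "dst_null_calibration",
    "dst_power_by_horizon",
    "stabilization_days_on_stationary_series",
]

_MOD = 2**31


def planted_cluster_recovery(
    n_seeds: int = 100, base_seed: int = 0, *, min_size: int = 8
) -> pd.DataFrame:
    """Recover two clusters separated only in the awakening count.

    For each seed: generate the planted two-cluster cohort (n=50, 30
    complete nights), cluster the 30-day window means at K=2, and record
    the adjusted Rand index against the planted labels plus whether the
    contrast table flags the awakening count — and nothing else — as
    significant.
    """
    rows = []
    for i in range(n_seeds):
        seed = (base_seed * 100_003 + i) % _MOD
        cfg = planted_two_cluster_config(seed=seed)
        panel, truth = generate_cohort(cfg, seed=seed)
        feats = build_features(panel, weeks_back=5, min_days=5)
        run = cluster(feats, 2, min_size=min_size, seed=0)
        ari = adjusted_rand_score(
            truth.cluster_labels[run.assignments.index], run.assignments
        )
        table = contrast_tests(run)
        flagged = set(table.loc[table["significant"], "variable"])
        rows.append(
            {"seed": seed, "ari": float(ari), "only_n_awake": flagged == {"n_awake"}}
        )
    return pd.DataFrame(rows)


def _aligned_cohort(n_participants: int, variables, seed: int) -> SyntheticConfig:
    """All participants enrolled exactly 60 days before the clock change."""
    return SyntheticConfig(
        n_participants=n_participants,
        enrollment_start=dt.date(2017, 8, 30),
        enrollment_end=dt.date(2017, 8, 30),
        study_end=dt.date(2017, 12, 28),
        variables=variables,
        cluster_frac=0.0,
        cluster_offsets={},
        seed=seed,
    )


def dst_null_calibration(
    n_replicates: int = 1000, horizon: int = 30, seed: int = 0
) -> pd.Series:
    """Per-variable type-I rate of the before/after t test under the null.

    The null cohort is stationary (no trends, no DST effects, no clusters);
    each participant's series is an independent replicate, since the
    participant random effect shifts both windows equally.
    """
    cfg = _aligned_cohort(n_replicates, null_variables(), seed)
    panel, _ = generate_cohort(cfg, seed=seed)
    frame = grid_frame(dst_grid(panel, cfg.dst_date, horizons=(horizon,)))
    computed = frame[frame["significant"].notna()]
    return computed.groupby("variable")["significant"].mean()


def dst_power_by_horizon(
    n_seeds: int = 200,
    delta_in_sd: float = 2.0,
    horizons: tuple[int, ...] = (15, 60),
    seed: int = 0,
    variable: str = "sol_min",
) -> pd.DataFrame:
    """Per-replicate rejection of the DST test under a planted SOL jump.

    The jump equals ``delta_in_sd`` night-to-night SDs of the variable.
    Returns one row per replicate with a rejection flag per horizon.
    """
    variables = null_variables()
    spec = variables[variable]
    variables[variable] = replace(spec, dst_delta=delta_in_sd * spec.sd_within)
    cfg = _aligned_cohort(n_seeds, variables, seed)
    panel, _ = generate_cohort(cfg, seed=seed)
    frame = grid_frame(
        dst_grid(panel, cfg.dst_date, horizons=horizons, variables=[variable])
    )
    wide = frame.pivot(index="participant_id", columns="horizon", values="significant")
    return wide.astype(bool)


def stabilization_days_on_stationary_series(
    n_seeds: int = 200,
    variable: str = "tst_h",
    seed: int = 0,
    *,
    rel_tol: float = 0.05,
    hold_days: int = 14,
) -> list[int | None]:
    """Stabilization day of the cumulative SD on stationary synthetic series.

    Each replicate is one participant observed from October 1 onward under
    the stationary generator defaults (night-to-night noise and the default
    missingness, no trends or DST effects).  Returns one stabilization day
    (or None, meaning the criterion never held) per replicate.
    """
    cfg = SyntheticConfig(
        n_participants=n_seeds,
        enrollment_start=dt.date(2017, 10, 1),
        enrollment_end=dt.date(2017, 10, 1),
        study_end=dt.date(2017, 12, 28),
        variables=null_variables(),
        cluster_frac=0.0,
        cluster_offsets={},
        seed=seed,
    )
    panel, _ = generate_cohort(cfg, seed=seed)
    out: list[int | None] = []
    for pid in panel.participants:
        s = panel.get_series(pid, variable)
        cum = cumulative_sd(s, start_days=3, max_extra=80,
                            circular=variable in CIRCULAR_VARIABLES)
        out.append(stabilization_day(cum, rel_tol=rel_tol, hold_days=hold_days))
    return out
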