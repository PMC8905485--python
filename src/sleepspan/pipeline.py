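"""End-to-end orchestration: generate/load -> variability -> cluster -> DST.

A :class:`RunConfig` fixes every stage parameter (defaults match the
reference analysis: 7-day rolling window, 3+80 cumulative windows anchored
at October 1, horizons 15/30/60 around October 29 2017, alpha = .05) and
:func:`run` executes the enabled stages, writing CSV/JSON outputs plus a
manifest (config hash, seed, versions, row counts).  Runs are idempotent:
the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import ALL_VARIABLES, CohortPanel, read_panel, write_panel
from .clustering import build_features, cluster, contrast_tests, elbow_curve, select_k
from .dst_effects import DEFAULT_DST_DATE, DEFAULT_HORIZONS, dst_grid, grid_frame
from .synthetic_data import SyntheticConfig, generate_cohort
from .variability import profiles_frame, variability_profile

__all__ = ["RunConfig", "StageError", "run"]

log = logging.getLogger("sleepspan")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the cause."""


@dataclass
class RunConfig:
    """Inputs, stage toggles and stage parameters for one pipeline run."""

    # inputs: either CSV paths or a synthetic config
    nights_path: str | None = None
    days_path: str | None = None
    synthetic: SyntheticConfig | None = None

    # stage toggles
    do_variability: bool = True
    do_clustering: bool = True
    do_dst: bool = True

    # variability parameters
    rolling_window_days: int = 7
    rolling_min_obs: int = 5
    cumulative_start_days: int = 3
    cumulative_max_extra: int = 80
    stabilization_rel_tol: float = 0.05
    stabilization_hold_days: int = 14
    variability_anchor: dt.date | None = dt.date(2017, 10, 1)
    variability_variables: list[str] = field(default_factory=lambda: list(ALL_VARIABLES))

    # clustering parameters
    weeks_back: int = 6
    k_max: int = 8
    k_fixed: int | None = None  # None: pick by the elbow rule
    min_cluster_size: int = 8
    min_days_in_window: int = 5
    standardize: bool = True

    # DST parameters
    dst_date: dt.date = DEFAULT_DST_DATE
    horizons: tuple[int, ...] = DEFAULT_HORIZONS

    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "sleepspan_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        for key in ("dst_date", "variability_anchor"):
            if d[key] is not None:
                d[key] = d[key] if isinstance(d[key], str) else d[key].isoformat()
        d["horizons"] = list(self.horizons)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], SyntheticConfig):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        for key in ("dst_date", "variability_anchor"):
            if isinstance(d.get(key), str):
                d[key] = dt.date.fromisoformat(d[key])
        if "horizons" in d:
            d["horizons"] = tuple(int(h) for h in d["horizons"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _load_panel(config: RunConfig, out: Path) -> CohortPanel:
    if config.synthetic is not None:
        panel, truth = generate_cohort(config.synthetic, seed=config.seed)
        write_panel(panel, out)
        truth_obj = {
            "cluster_labels": truth.cluster_labels.to_dict(),
            "start_dates": {k: v.isoformat() for k, v in truth.start_dates.items()},
            "random_effects": {
                pid: {v: float(truth.random_effects.loc[pid, v]) for v in truth.random_effects.columns}
                for pid in truth.random_effects.index
            },
            "seed": truth.seed,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_obj, indent=1, sort_keys=True))
        return panel
    if config.nights_path is None or config.days_path is None:
        raise StageError("load: neither CSV paths nor a synthetic config given")
    return read_panel(config.nights_path, config.days_path)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the enabled stages; return the paths of everything written."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    try:
        panel = _load_panel(config, out)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc
    counts["nights"] = len(panel.nights)
    counts["days"] = len(panel.days)
    counts["participants"] = len(panel.participants)
    log.info("loaded panel: %s", counts)

    if config.do_variability:
        try:
            profiles = []
            stab_rows = []
            anchor = (
                pd.Timestamp(config.variability_anchor)
                if config.variability_anchor is not None
                else None
            )
            for pid in panel.participants:
                for var in config.variability_variables:
                    s = panel.get_series(pid, var)
                    if anchor is not None:
                        s = s[s.index >= anchor]
                    span = 0 if s.empty else (s.index.max() - s.index.min()).days + 1
                    if span < config.cumulative_start_days:
                        continue
                    prof = variability_profile(
                        panel, pid, var,
                        window_days=config.rolling_window_days,
                        min_obs=config.rolling_min_obs,
                        start_days=config.cumulative_start_days,
                        max_extra=config.cumulative_max_extra,
                        rel_tol=config.stabilization_rel_tol,
                        hold_days=config.stabilization_hold_days,
                        anchor=anchor,
                    )
                    profiles.append(prof)
                    stab_rows.append(
                        {
                            "participant_id": pid,
                            "variable": var,
                            "stabilization_day": prof.stabilization,
                            "rel_tol": prof.rel_tol,
                            "hold_days": prof.hold_days,
                        }
                    )
            artifacts["variability_profile"] = out / "variability_profile.csv"
            _write_csv(profiles_frame(profiles), artifacts["variability_profile"])
            artifacts["stabilization"] = out / "stabilization.csv"
            _write_csv(pd.DataFrame(stab_rows), artifacts["stabilization"])
            counts["variability_profiles"] = len(profiles)
            log.info("variability: %d profiles", len(profiles))
        except Exception as exc:
            raise StageError(f"variability: {exc}") from exc

    if config.do_clustering:
        try:
            feats = build_features(
                panel, config.weeks_back, config.min_days_in_window,
                standardize=config.standardize,
            )
            if feats.excluded:
                log.info("clustering: excluded %s", feats.excluded)
            k_hi = min(config.k_max, len(feats.participants))
            curve = elbow_curve(feats, range(1, k_hi + 1), seed=config.seed)
            k = config.k_fixed if config.k_fixed is not None else select_k(curve)
            k = max(k, 2)
            run_ = cluster(feats, k, config.min_cluster_size, seed=config.seed, elbow=curve)
            payload = {
                "weeks_back": run_.weeks_back,
                "k": run_.k,
                "seed": run_.seed,
                "elbow_curve": {str(i): float(v) for i, v in curve.items()},
                "sizes": run_.sizes,
                "retained": run_.retained,
                "assignments": {p: int(c) for p, c in run_.assignments.items()},
                "excluded": feats.excluded,
            }
            artifacts["cluster_run"] = out / "cluster_run.json"
            artifacts["cluster_run"].write_text(json.dumps(payload, indent=1, sort_keys=True))
            counts["clusters_retained"] = len(run_.retained)
            if len(run_.retained) == 2:
                contrasts = contrast_tests(run_, alpha=config.alpha)
                artifacts["contrasts"] = out / "contrasts.csv"
                _write_csv(contrasts, artifacts["contrasts"])
            else:
                log.info("clustering: %d retained clusters; skipping contrasts",
                         len(run_.retained))
        except Exception as exc:
            raise StageError(f"clustering: {exc}") from exc

    if config.do_dst:
        try:
            results = dst_grid(
                panel, config.dst_date, config.horizons, alpha=config.alpha
            )
            artifacts["dst_grid"] = out / "dst_grid.csv"
            _write_csv(grid_frame(results), artifacts["dst_grid"])
            counts["dst_cells"] = len(results)
        except Exception as exc:
            raise StageError(f"dst: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "sleepspan": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": counts,
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    artifacts["manifest"] = path
    return artifacts
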