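"""Expanding-window K-means cohort discovery with elbow selection.

Participants are summarized by their mean of each of the 11 variables over
a trailing window (the last week of the trial, the last two weeks, ...),
z-scored per column, and partitioned with Euclidean K-means.  K is chosen
by the elbow of the within/between distance-ratio curve; clusters below a
minimum size are excluded from downstream contrasts; a pooled-variance
Student t test compares the two retained clusters variable by variable.

Sleep midtime is linearized to minutes after 18:00 before averaging,
clustering and testing (midtimes cluster in the night, far from the cut).
Per-night values are first averaged per participant, so all tests compare
participants, not nights, avoiding pseudo-replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .data_model import ALL_VARIABLES, CIRCULAR_VARIABLES, DAY_VARIABLES, CohortPanel
from .night_metrics import delinearize_clock, linearize_clock
from .stats import two_sample_t

__all__ = [
    "FeatureMatrix",
    "ClusterRun",
    "build_features",
    "elbow_curve",
    "select_k",
    "cluster",
    "contrast_tests",
    "window_stability",
]

UNASSIGNED = -1


@dataclass
class FeatureMatrix:
    """Participant x variable means over a trailing window, standardized.

    ``frame`` holds per-participant means on the analysis scale (midtime
    already linearized); ``X`` is the z-scored matrix actually clustered.
    Degenerate (zero-variance) columns standardize to all-zeros.
    """

    frame: pd.DataFrame  # index: participant_id; columns: variables
    X: np.ndarray
    center: pd.Series
    scale: pd.Series
    excluded: list[tuple[str, str]]  # (participant_id, reason)
    weeks_back: int
    window: tuple[pd.Timestamp, pd.Timestamp]

    @property
    def participants(self) -> list[str]:
        return list(self.frame.index)


@dataclass
class ClusterRun:
    """One K-means solution over one trailing window."""

    weeks_back: int
    k: int
    seed: int
    assignments: pd.Series  # participant -> cluster label (UNASSIGNED if dropped)
    sizes: dict[int, int]  # all clusters, pre-exclusion
    retained: list[int]
    centers: pd.DataFrame  # retained clusters x variables, original units
    features: FeatureMatrix
    elbow: pd.Series | None = None


def build_features(
    panel: CohortPanel,
    weeks_back: int,
    min_days: int = 5,
    *,
    standardize: bool = True,
    end_date: pd.Timestamp | None = None,
    variables: list[str] | None = None,
) -> FeatureMatrix:
    """Per-participant variable means over the trailing ``weeks_back`` weeks.

    Participants with fewer than ``min_days`` observed nights (or days, for
    the daytime variables) in the window, or with a wholly missing
    variable, are excluded and listed with a reason.
    """
    if weeks_back < 1:
        raise ValueError("weeks_back must be >= 1")
    variables = variables or ALL_VARIABLES
    if end_date is None:
        stamps = [panel.nights["night_date"].max(), panel.days["day_date"].max()]
        end_date = max(t for t in stamps if pd.notna(t))
    end_date = pd.Timestamp(end_date)
    start = end_date - pd.Timedelta(days=7 * weeks_back - 1)

    rows: dict[str, dict[str, float]] = {}
    excluded: list[tuple[str, str]] = []
    for pid in panel.participants:
        feats: dict[str, float] = {}
        reason = None
        for var in variables:
            s = panel.get_series(pid, var)
            s = s[(s.index >= start) & (s.index <= end_date)]
            kind = "days" if var in DAY_VARIABLES else "nights"
            if len(s) < min_days:
                reason = f"only {len(s)} {kind} with {var} in window (min_days={min_days})"
                break
            vals = s.to_numpy()
            if var in CIRCULAR_VARIABLES:
                vals = linearize_clock(vals)
            feats[var] = float(np.mean(vals))
        if reason is None:
            rows[pid] = feats
        else:
            excluded.append((pid, reason))
    if not rows:
        raise ValueError("build_features: no eligible participants")
    frame = pd.DataFrame.from_dict(rows, orient="index")[variables].sort_index()
    center = frame.mean()
    scale = frame.std(ddof=0)
    # a column whose spread is at rounding level is degenerate: averaging the
    # same value over different day counts leaves last-ulp noise that must
    # not be inflated to unit variance
    tiny = 1e-9 * np.maximum(1.0, frame.abs().max())
    scale = scale.where(scale > tiny, 0.0)
    if standardize:
        safe = scale.replace(0.0, 1.0)
        X = ((frame - center) / safe).to_numpy()
        X[:, (scale == 0.0).to_numpy()] = 0.0
    else:
        X = frame.to_numpy()
        center = pd.Series(0.0, index=frame.columns)
        scale = pd.Series(1.0, index=frame.columns)
    return FeatureMatrix(frame, X, center, scale, excluded, weeks_back, (start, end_date))


def _fit_kmeans(X: np.ndarray, k: int, seed: int, restarts: int) -> KMeans:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    km.fit(X)
    return km


def _ratio(X: np.ndarray, km: KMeans) -> float:
    """Within-cluster to between-center mean distance ratio.

    Within: mean Euclidean distance of points to their assigned center.
    Between: mean pairwise distance among centers.  For K=1 the between
    term is absent and the within dispersion itself is returned (documented
    convention for the degenerate case).
    """
    centers = km.cluster_centers_
    d = np.linalg.norm(X - centers[km.labels_], axis=1)
    within = float(np.mean(d))
    if centers.shape[0] == 1:
        return within
    diffs = centers[:, None, :] - centers[None, :, :]
    pair = np.linalg.norm(diffs, axis=-1)
    iu = np.triu_indices(centers.shape[0], k=1)
    between = float(np.mean(pair[iu]))
    return within / between if between > 0 else np.inf


def elbow_curve(
    features: FeatureMatrix,
    k_range=range(1, 9),
    seed: int = 0,
    restarts: int = 10,
) -> pd.Series:
    """Within/between distance-ratio curve over candidate K (best of restarts)."""
    n = features.X.shape[0]
    ks = [int(k) for k in k_range]
    if any(k < 1 or k > n for k in ks):
        raise ValueError(f"k_range must lie within [1, {n}]")
    vals = []
    for k in ks:
        km = _fit_kmeans(features.X, k, seed, restarts)
        vals.append(_ratio(features.X, km))
    return pd.Series(vals, index=pd.Index(ks, name="k"), name="ratio")


def select_k(curve: pd.Series, *, flat_tol: float = 1e-9) -> int:
    """Elbow selection: K with the greatest curvature of the ratio curve.

    Curvature is the second difference of the *log* ratio, making the rule
    scale-free (multiplying the curve by a constant changes nothing) and
    robust to the degenerate K=1 entry, whose within-only dispersion is on
    a different scale from the within/between ratios.  Ties break toward
    smaller K.  A curve with no positive curvature anywhere (flat, linear
    or purely convex decay) has no elbow and returns the smallest K with a
    warning.
    """
    if len(curve) < 3:
        raise ValueError("select_k: need a curve over >= 3 K values")
    ks = np.asarray(curve.index, dtype=int)
    r = np.log(np.maximum(curve.to_numpy(dtype=float), 1e-300))
    d2 = r[:-2] - 2 * r[1:-1] + r[2:]
    if np.all(d2 <= flat_tol):
        warnings.warn("elbow curve has no elbow; returning smallest K", stacklevel=2)
        return int(ks[0])
    best = int(np.argmax(d2))  # argmax takes the first (= smallest K) on ties
    return int(ks[1 + best])


def cluster(
    features: FeatureMatrix,
    k: int,
    min_size: int = 8,
    seed: int = 0,
    restarts: int = 10,
    *,
    elbow: pd.Series | None = None,
) -> ClusterRun:
    """K-means partition with small-cluster exclusion.

    Clusters smaller than ``min_size`` are dropped from downstream
    contrasts; their members are flagged ``UNASSIGNED`` (-1).  Centers are
    reported in original units (inverse of the z-scoring; midtime back on
    the clock).
    """
    if k < 2:
        raise ValueError("cluster: K must be >= 2")
    km = _fit_kmeans(features.X, k, seed, restarts)
    labels = pd.Series(km.labels_, index=features.frame.index, name="cluster")
    sizes = labels.value_counts().to_dict()
    retained = sorted(c for c, n in sizes.items() if n >= min_size)
    if not retained:
        raise ValueError(
            f"all {k} clusters smaller than min_size={min_size}: sizes {sizes}"
        )
    assignments = labels.where(labels.isin(retained), UNASSIGNED)
    centers_scaled = pd.DataFrame(
        km.cluster_centers_, columns=features.frame.columns
    ).loc[retained]
    centers = centers_scaled * features.scale.replace(0.0, 1.0) + features.center
    for var in centers.columns:
        if var in CIRCULAR_VARIABLES:
            centers[var] = delinearize_clock(centers[var].to_numpy())
    return ClusterRun(
        weeks_back=features.weeks_back,
        k=k,
        seed=seed,
        assignments=assignments,
        sizes={int(c): int(n) for c, n in sizes.items()},
        retained=[int(c) for c in retained],
        centers=centers,
        features=features,
        elbow=elbow,
    )


def contrast_tests(run: ClusterRun, alpha: float = 0.05) -> pd.DataFrame:
    """Variable-by-variable comparison of the two retained clusters.

    One row per variable with each cluster's mean and SD (computed over the
    participant-level window means), the pooled-variance Student t
    statistic, the two-tailed p value and a significance flag at ``alpha``.
    Midtime means are reported back on the clock; its SD and test operate
    on the linearized scale.
    """
    if len(run.retained) != 2:
        raise ValueError(
            f"contrast_tests needs exactly 2 retained clusters, got {len(run.retained)}; "
            "compare pairs of clusters explicitly instead"
        )
    a, b = run.retained
    frame = run.features.frame
    in_a = run.assignments == a
    in_b = run.assignments == b
    rows = []
    for var in frame.columns:
        xa = frame.loc[in_a, var].to_numpy()
        xb = frame.loc[in_b, var].to_numpy()
        t, p = two_sample_t(xa, xb, equal_var=True)
        mean_a, mean_b = float(np.mean(xa)), float(np.mean(xb))
        if var in CIRCULAR_VARIABLES:
            mean_a = float(delinearize_clock(mean_a))
            mean_b = float(delinearize_clock(mean_b))
        rows.append(
            {
                "variable": var,
                "cluster_1": a,
                "mean_1": mean_a,
                "sd_1": float(np.std(xa, ddof=1)),
                "n_1": int(in_a.sum()),
                "cluster_2": b,
                "mean_2": mean_b,
                "sd_2": float(np.std(xb, ddof=1)),
                "n_2": int(in_b.sum()),
                "t": t,
                "p": p,
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def window_stability(
    panel: CohortPanel,
    weeks_list,
    k: int,
    seed: int = 0,
    *,
    min_days: int = 5,
    restarts: int = 10,
    ari_threshold: float = 0.8,
) -> tuple[pd.DataFrame, int | None]:
    """Assignment agreement (adjusted Rand index) across window lengths.

    Clusters the cohort for each window length in ``weeks_list`` and scores
    the ARI between consecutive windows' raw assignments on their common
    participants.  Returns the pairwise table and the first window length
    after which every subsequent consecutive ARI stays >= ``ari_threshold``
    (None if never).
    """
    weeks_list = sorted(int(w) for w in weeks_list)
    if len(weeks_list) < 2:
        raise ValueError("window_stability: need >= 2 window lengths")
    labelings: dict[int, pd.Series] = {}
    for w in weeks_list:
        feats = build_features(panel, w, min_days)
        km = _fit_kmeans(feats.X, k, seed, restarts)
        labelings[w] = pd.Series(km.labels_, index=feats.frame.index)
    rows = []
    for w1, w2 in zip(weeks_list[:-1], weeks_list[1:]):
        common = labelings[w1].index.intersection(labelings[w2].index)
        ari = adjusted_rand_score(labelings[w1][common], labelings[w2][common])
        rows.append({"weeks_a": w1, "weeks_b": w2, "n_common": len(common), "ari": float(ari)})
    table = pd.DataFrame(rows)
    stable_from: int | None = None
    for i in range(len(table)):
        if (table["ari"].iloc[i:] >= ari_threshold).all():
            stable_from = int(table["weeks_a"].iloc[i])
            break
    return table, stable_from
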