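"""Time-lapse migration-track metrics and nonparametric group comparison.

A track is the ordered 2D position of one cell across frames. Five summary
statistics are computed per track:

- total_distance (μm): summed Euclidean step lengths over the whole track
- velocity (μm/min): total_distance / total_time
- displacement (μm): straight-line distance from first to last position
- efficiency (dimensionless): displacement / total_distance, the straightness
  index (1 for straight motion, 0 for a closed loop)
- net_velocity (μm/min): displacement / total_time, the directed component

total_time is the frame span times the frame interval, so skipped frames do
not shorten the clock. Treatment groups (e.g. control vs MET-inhibitor
explants) are compared per metric with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Track",
    "TrackMetrics",
    "GroupComparison",
    "compute_track_metrics",
    "summarize_tracks",
    "compare_groups",
    "compare_conditions",
    "METRIC_NAMES",
]

METRIC_NAMES = ("total_distance", "velocity", "displacement", "efficiency", "net_velocity")

#: Default acquisition interval (minutes between frames).
DEFAULT_FRAME_INTERVAL_MIN = 15.0


@dataclass
class Track:
    """One cell's ordered, time-stamped 2D positions (μm)."""

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) < 2:
            raise ValueError(f"track {self.track_id!r} has fewer than 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id!r}: frame indices must strictly increase")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")

    @property
    def n_points(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class TrackMetrics:
    track_id: str
    total_distance: float
    velocity: float
    displacement: float
    efficiency: float
    net_velocity: float
    total_time: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney comparison of one metric between two groups."""

    metric: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    method: str


def compute_track_metrics(track: Track) -> TrackMetrics:
    """The five per-track statistics; see the module docstring for definitions."""
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    total_distance = float(steps.sum())
    displacement = float(np.hypot(track.x[-1] - track.x[0], track.y[-1] - track.y[0]))
    total_time = float((track.frames[-1] - track.frames[0]) * track.frame_interval_min)
    if total_time <= 0:
        raise ValueError(f"track {track.track_id!r} has zero total time")
    efficiency = displacement / total_distance if total_distance > 0 else 0.0
    return TrackMetrics(
        track_id=track.track_id,
        total_distance=total_distance,
        velocity=total_distance / total_time,
        displacement=displacement,
        efficiency=efficiency,
        net_velocity=displacement / total_time,
        total_time=total_time,
    )


def summarize_tracks(tracks: Iterable[Track]) -> pd.DataFrame:
    """Per-track metrics table, one row per track."""
    rows = [compute_track_metrics(t).__dict__ for t in tracks]
    if not rows:
        raise ValueError("no tracks to summarize")
    return pd.DataFrame(rows).set_index("track_id")


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    metric: str = "",
    exact_max_product: int = 400,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two samples of one metric.

    The exact null distribution is used when ``n_a * n_b <= exact_max_product``
    and there are no ties; otherwise the normal approximation with continuity
    and mid-rank tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size * b.size <= exact_max_product and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        metric=metric,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method=method,
    )


def compare_conditions(
    metrics: pd.DataFrame, groups: pd.Series, metric_names: Sequence[str] = METRIC_NAMES
) -> pd.DataFrame:
    """Mann-Whitney comparison of every metric between exactly two conditions.

    ``metrics`` is the output of :func:`summarize_tracks`; ``groups`` maps each
    track id to its condition label.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two conditions, got {labels}")
    ga = metrics.loc[groups[groups == labels[0]].index]
    gb = metrics.loc[groups[groups == labels[1]].index]
    rows = []
    for m in metric_names:
        cmp = compare_groups(ga[m].to_numpy(), gb[m].to_numpy(), metric=m)
        rows.append(
            {
                "metric": m,
                "group_a": labels[0],
                "group_b": labels[1],
                "U": cmp.u_statistic,
                "p_value": cmp.p_value,
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "median_a": cmp.median_a,
                "median_b": cmp.median_b,
                "method": cmp.method,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
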