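"""Novel-object-recognition behavioral scoring from tracking.

An exploration bout is a maximal run of tracking samples during which
the nose-object distance stays below 2.5 cm. Distance is measured to
the object's *surface* by default (center distance minus radius,
floored at 0): with 10 cm diameter objects a 2.5 cm center criterion
would be physically impossible to satisfy, so the proximity threshold
is read as nose-to-surface. A ``to_surface=False`` flag restores the
center reading for narrower objects.

The discrimination index is
DI = (time_novel - time_familiar) / (time_novel + time_familiar),
undefined (NaN) when the animal never explores either object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import ArenaObject, TrackingTrace

EXPLORATION_THRESHOLD_CM = 2.5


@dataclass
class ExplorationBout:
    """One contiguous exploration interval, bounded by the first and
    last sub-threshold samples."""

    object_label: str
    t_start: float
    t_end: float

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class BehaviorSummary:
    """Per-animal NOR summary: exploration times (s), DI, percent time
    at the novel object, bout counts and total traveled distance (cm)."""

    time_novel: float
    time_familiar: float
    di: float
    pct_novel: float
    n_bouts_novel: int
    n_bouts_familiar: int
    total_distance: float

    def to_dict(self) -> dict:
        return {
            "time_novel": self.time_novel, "time_familiar": self.time_familiar,
            "di": self.di, "pct_novel": self.pct_novel,
            "n_bouts_novel": self.n_bouts_novel,
            "n_bouts_familiar": self.n_bouts_familiar,
            "total_distance": self.total_distance,
        }


def nose_object_distance(trace: TrackingTrace, obj: ArenaObject,
                         to_surface: bool = True) -> np.ndarray:
    """Euclidean nose-object distance (cm), one value per sample.

    With ``to_surface`` the distance is to the nearest surface point of
    the (circular) object: center distance minus radius, floored at 0.
    """
    if trace.nose_xy.size == 0 or np.isnan(trace.nose_xy).all():
        raise ValueError("trace has no nose coordinates")
    d = np.hypot(trace.nose_xy[:, 0] - obj.center[0],
                 trace.nose_xy[:, 1] - obj.center[1])
    if to_surface:
        d = np.maximum(d - obj.radius, 0.0)
    return d


def detect_bouts(t: np.ndarray, distance: np.ndarray, label: str = "",
                 threshold_cm: float = EXPLORATION_THRESHOLD_CM,
                 min_dur_s: float = 0.0) -> list:
    """Find maximal runs with distance < threshold.

    Bout boundaries are the times of the first and last sub-threshold
    samples of each run; runs shorter than ``min_dur_s`` are dropped.
    """
    t = np.asarray(t, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if len(t) == 0:
        raise ValueError("empty distance series")
    below = distance < threshold_cm
    edges = np.diff(below.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if below[0]:
        starts = np.r_[0, starts]
    if below[-1]:
        ends = np.r_[ends, len(below) - 1]
    bouts = []
    for i0, i1 in zip(starts, ends):
        if t[i1] - t[i0] >= min_dur_s:
            bouts.append(ExplorationBout(label, float(t[i0]), float(t[i1])))
    return bouts


def detect_object_bouts(trace: TrackingTrace,
                        threshold_cm: float = EXPLORATION_THRESHOLD_CM,
                        min_dur_s: float = 0.0,
                        to_surface: bool = True) -> list:
    """Detect bouts for every object in the trace, sorted by onset."""
    bouts = []
    for obj in trace.objects:
        d = nose_object_distance(trace, obj, to_surface=to_surface)
        bouts.extend(detect_bouts(trace.t, d, obj.label, threshold_cm, min_dur_s))
    bouts.sort(key=lambda b: b.t_start)
    return bouts


def total_distance(trace: TrackingTrace, median_kernel: int = 5) -> float:
    """Total traveled distance (cm) of the body point.

    A short median filter (default 5 samples) suppresses tracking
    jitter before step-summing; raw step sums inflate the distance.
    """
    xy = trace.body_xy
    if len(xy) < 2:
        return 0.0
    k = median_kernel + (median_kernel + 1) % 2  # force odd
    if k > 1 and len(xy) >= k:
        xy = np.column_stack([sps.medfilt(xy[:, 0], k), sps.medfilt(xy[:, 1], k)])
    steps = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    return float(steps.sum())


def behavior_summary(trace: TrackingTrace, bouts: list) -> BehaviorSummary:
    """Aggregate bouts into the per-animal NOR summary.

    With zero total exploration DI and pct_novel are reported as NaN
    (missing), never as 0.
    """
    time = {"novel": 0.0, "familiar": 0.0}
    n = {"novel": 0, "familiar": 0}
    for b in bouts:
        if b.object_label not in time:
            raise ValueError(f"unknown object label {b.object_label!r}")
        time[b.object_label] += b.duration
        n[b.object_label] += 1
    denom = time["novel"] + time["familiar"]
    if denom > 0:
        di = (time["novel"] - time["familiar"]) / denom
        pct = 100.0 * time["novel"] / denom
    else:
        di = float("nan")
        pct = float("nan")
    return BehaviorSummary(time["novel"], time["familiar"], di, pct,
                           n["novel"], n["familiar"], total_distance(trace))


def novel_event_onsets(bouts: list, label: str = "novel") -> list:
    """Onset times of the labeled object's bouts, sorted (event markers
    for epoch extraction)."""
    return sorted(b.t_start for b in bouts if b.object_label == label)
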