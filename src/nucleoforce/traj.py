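"""Pause/translocation segmentation of sliding trajectories.

Manually tracked position-time trajectories of remodeler-driven histone
sliding consist of episodes of directed translocation interspersed with
pauses.  Following the assay's definition, samples whose local velocity
magnitude is below 3 nm/s are pauses; at or above 3 nm/s, active
translocation.  Local velocity is estimated by sliding-window linear
regression; runs of same-class samples are merged into segments whose
kind is finally set from the segment's own regression slope, so the
classification invariant (ACTIVE iff |v| >= threshold) holds for the
reported segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PAUSE = "PAUSE"
ACTIVE = "ACTIVE"
DEFAULT_V_THRESHOLD = 3.0  # nm/s
DEFAULT_MIN_ACTIVE_DURATION = 3.0  # s


@dataclass(frozen=True)
class MotionSegment:
    """A maximal run of one motion class within a trajectory."""

    start: float  # s
    end: float  # s
    mean_velocity: float  # nm/s, signed (regression slope over the segment)
    kind: str  # PAUSE or ACTIVE

    @property
    def duration(self) -> float:
        return self.end - self.start


def _slope(t: np.ndarray, x: np.ndarray) -> float:
    t = t - t.mean()
    denom = np.sum(t * t)
    if denom == 0:
        return 0.0
    return float(np.sum(t * (x - x.mean())) / denom)


def local_velocity(
    time: np.ndarray, position: np.ndarray, smoothing_window: float = 5.0
) -> np.ndarray:
    """Per-sample velocity by centered sliding-window linear regression."""
    time = np.asarray(time, dtype=float)
    position = np.asarray(position, dtype=float)
    n = time.size
    v = np.empty(n)
    half = smoothing_window / 2.0
    for i in range(n):
        mask = np.abs(time - time[i]) <= half
        v[i] = _slope(time[mask], position[mask])
    return v


def segment_trajectory(
    time: np.ndarray,
    position: np.ndarray,
    v_threshold: float = DEFAULT_V_THRESHOLD,
    smoothing_window: float = 5.0,
) -> list[MotionSegment]:
    """Partition a trajectory into PAUSE and ACTIVE segments.

    Samples are classified by local-velocity magnitude (>= threshold is
    ACTIVE, inclusive); consecutive same-class samples merge into
    segments; each segment's mean velocity is the regression slope over
    its samples, its kind is re-derived from that slope, and adjacent
    same-kind segments are merged again so the returned segments
    partition the track and satisfy the class definition.
    """
    time = np.asarray(time, dtype=float)
    position = np.asarray(position, dtype=float)
    if time.size < 2:
        raise ValueError("trajectory needs at least 2 points")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")

    v = local_velocity(time, position, smoothing_window)
    is_active = np.abs(v) >= v_threshold

    # run-length encode the per-sample classes
    bounds = [0] + list(np.flatnonzero(np.diff(is_active)) + 1) + [time.size]
    raw: list[tuple[int, int]] = list(zip(bounds[:-1], bounds[1:]))

    def make_segment(a: int, b: int) -> MotionSegment:
        sl = _slope(time[a:b], position[a:b]) if b - a >= 2 else 0.0
        kind = ACTIVE if abs(sl) >= v_threshold else PAUSE
        return MotionSegment(
            start=float(time[a]), end=float(time[b - 1]), mean_velocity=sl, kind=kind
        )

    segments = [make_segment(a, b) for a, b in raw]

    # merge adjacent same-kind segments (kind may flip after re-deriving)
    merged: list[tuple[int, int, str]] = []
    for (a, b), seg in zip(raw, segments):
        if merged and merged[-1][2] == seg.kind:
            merged[-1] = (merged[-1][0], b, seg.kind)
        else:
            merged.append((a, b, seg.kind))
    return [make_segment(a, b) for a, b, _ in merged]


def mean_active_velocity(
    segments: list[MotionSegment],
    min_duration: float = DEFAULT_MIN_ACTIVE_DURATION,
) -> tuple[float, float, int]:
    """Mean +/- SEM of |velocity| over qualifying ACTIVE segments.

    Only active-translocation segments lasting at least ``min_duration``
    seconds enter the average.  With a single qualifying segment the
    SEM is reported as 0 (n = 1 is flagged by the returned count).
    """
    speeds = [
        abs(s.mean_velocity)
        for s in segments
        if s.kind == ACTIVE and s.duration >= min_duration
    ]
    if not speeds:
        raise ValueError("no qualifying active segments")
    n = len(speeds)
    mean = float(np.mean(speeds))
    sem = float(np.std(speeds, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def associate_oligomer_velocity(
    tracks: list[tuple[int, list[MotionSegment]]],
    min_duration: float = DEFAULT_MIN_ACTIVE_DURATION,
) -> dict[int, dict]:
    """Velocity summaries per apparent-oligomer class.

    ``tracks`` pairs an oligomer label with a track's segments.  Classes
    with no qualifying active segment are omitted.  When exactly two
    classes are present, each summary also reports the between-class
    difference +/- pooled SE (no significance claim).
    """
    per_class: dict[int, list[float]] = {}
    for label, segments in tracks:
        speeds = [
            abs(s.mean_velocity)
            for s in segments
            if s.kind == ACTIVE and s.duration >= min_duration
        ]
        per_class.setdefault(int(label), []).extend(speeds)

    out: dict[int, dict] = {}
    for label, speeds in sorted(per_class.items()):
        if not speeds:
            continue
        n = len(speeds)
        out[label] = {
            "mean": float(np.mean(speeds)),
            "sem": float(np.std(speeds, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "n": n,
        }
    labels = list(out)
    if len(labels) == 2:
        a, b = labels
        diff = out[b]["mean"] - out[a]["mean"]
        pooled = float(np.hypot(out[a]["sem"], out[b]["sem"]))
        out[a]["difference_vs_other"] = -diff
        out[b]["difference_vs_other"] = diff
        for lab in labels:
            out[lab]["difference_se"] = pooled
    return out
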