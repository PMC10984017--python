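"""Social-contact detection from two-animal pose keypoints.

A frame counts as social interaction when the resident's head is within 60
pixels of the intruder's body centroid AND the approach angle — the angle
between the resident's heading (body centroid -> head) and the vector from
the resident's head to the intruder's body — is at most 135 degrees, i.e.
the resident is not facing directly away.  Thresholds are inclusive; runs
shorter than a minimum duration are dropped and short gaps merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PoseSession",
    "EventSeries",
    "head_body_distance",
    "approach_angle",
    "detect_interaction",
    "interaction_time",
    "DIST_THRESH_PX",
    "ANGLE_THRESH_DEG",
]

# contact rule thresholds (pixels, degrees)
DIST_THRESH_PX = 60.0
ANGLE_THRESH_DEG = 135.0


@dataclass
class PoseSession:
    """Per-frame keypoints for a resident-intruder session.

    Arrays are (n_frames, 2) pixel coordinates; ``valid`` marks frames where
    tracking succeeded (invalid frames yield missing distance/angle).
    """

    fps: float
    resident_head_xy: np.ndarray
    resident_body_xy: np.ndarray
    intruder_body_xy: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        arrs = []
        for name in ("resident_head_xy", "resident_body_xy", "intruder_body_xy"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 2 or a.shape[1] != 2:
                raise ValueError(f"{name} must have shape (n_frames, 2)")
            setattr(self, name, a)
            arrs.append(a)
        n = {a.shape[0] for a in arrs}
        if len(n) != 1:
            raise ValueError("keypoint arrays must have equal lengths")
        if self.valid is None:
            self.valid = np.ones(arrs[0].shape[0], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape[0] != arrs[0].shape[0]:
                raise ValueError("valid mask length mismatch")
        for a in arrs:
            if not np.isfinite(a[self.valid]).all():
                raise ValueError("keypoints must be finite on valid frames")

    @property
    def n_frames(self) -> int:
        return int(self.resident_head_xy.shape[0])


@dataclass
class EventSeries:
    """Sorted, non-overlapping (start_s, end_s) intervals with a label."""

    intervals: np.ndarray  # (n, 2)
    label: str = "interaction"

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if (iv[:, 1] <= iv[:, 0]).any():
                raise ValueError("interval durations must be positive")
            if (iv[1:, 0] < iv[:-1, 1]).any():
                raise ValueError("intervals must be sorted and non-overlapping")
        self.intervals = iv

    def __len__(self) -> int:
        return int(self.intervals.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s"]).assign(
            label=self.label
        )


def head_body_distance(session: PoseSession) -> np.ndarray:
    """Euclidean resident-head -> intruder-body distance per frame (px).

    Invalid frames are NaN.
    """
    d = np.linalg.norm(session.intruder_body_xy - session.resident_head_xy, axis=1)
    d = d.astype(float)
    d[~session.valid] = np.nan
    return d


def approach_angle(session: PoseSession) -> np.ndarray:
    """Angle (degrees, [0, 180]) between resident heading and head->intruder.

    Heading is resident body -> head.  Frames with a degenerate heading
    (head coincident with body) or a coincident head/intruder are NaN, as
    are invalid frames.
    """
    heading = session.resident_head_xy - session.resident_body_xy
    to_intruder = session.intruder_body_xy - session.resident_head_xy
    hn = np.linalg.norm(heading, axis=1)
    tn = np.linalg.norm(to_intruder, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", heading, to_intruder) / (hn * tn)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(hn == 0) | (tn == 0) | ~session.valid] = np.nan
    return ang


def interaction_mask(
    distance_px: np.ndarray,
    angle_deg: np.ndarray,
    dist_thresh_px: float = DIST_THRESH_PX,
    angle_thresh_deg: float = ANGLE_THRESH_DEG,
) -> np.ndarray:
    """Per-frame boolean contact rule: distance <= and angle <= thresholds.

    NaN (missing) frames are False — tracking dropouts never fabricate
    contact.
    """
    if dist_thresh_px < 0 or angle_thresh_deg < 0:
        raise ValueError("thresholds must be non-negative")
    d = np.asarray(distance_px, dtype=float)
    a = np.asarray(angle_deg, dtype=float)
    if d.shape != a.shape:
        raise ValueError("distance and angle must be aligned per frame")
    with np.errstate(invalid="ignore"):
        return (d <= dist_thresh_px) & (a <= angle_thresh_deg)


def _mask_to_intervals(mask: np.ndarray, fps: float) -> np.ndarray:
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return np.column_stack([starts / fps, ends / fps])


def detect_interaction(
    distance_px: np.ndarray,
    angle_deg: np.ndarray,
    fps: float,
    dist_thresh_px: float = DIST_THRESH_PX,
    angle_thresh_deg: float = ANGLE_THRESH_DEG,
    min_dur_s: float = 0.5,
    merge_gap_s: float = 0.2,
) -> EventSeries:
    """Detect social-interaction intervals from per-frame distance and angle.

    A frame interacts iff distance <= ``dist_thresh_px`` AND angle <=
    ``angle_thresh_deg`` (both inclusive).  Gaps shorter than
    ``merge_gap_s`` are merged first, then runs shorter than ``min_dur_s``
    are dropped.  Interval times are frame-edge based: a run of frames
    [i, j] spans [i/fps, (j+1)/fps).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    mask = interaction_mask(distance_px, angle_deg, dist_thresh_px, angle_thresh_deg)
    iv = _mask_to_intervals(mask, fps)
    if merge_gap_s > 0 and len(iv) > 1:
        merged = [iv[0]]
        for s, e in iv[1:]:
            if s - merged[-1][1] < merge_gap_s:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        iv = np.array(merged)
    if len(iv):
        iv = iv[(iv[:, 1] - iv[:, 0]) >= min_dur_s]
    return EventSeries(iv.reshape(-1, 2), label="interaction")


def interaction_time(series: EventSeries) -> float:
    """Total time in seconds spent in interaction intervals."""
    if len(series) == 0:
        return 0.0
    return float(np.sum(series.intervals[:, 1] - series.intervals[:, 0]))
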