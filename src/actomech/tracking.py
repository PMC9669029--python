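"""Detection and linking of thick-filament-like fluorescent objects.

Detection segments bright objects above threshold and describes each
one by its intensity-weighted centroid plus the angle and long-axis
length of its minimum-area rotated bounding box (the filament axis has
no polarity, so angles live in [-pi/2, pi/2)).  Linking is greedy
nearest-neighbour assignment with global conflict resolution; an
object may go undetected for up to ``max_gap`` frames (default 3) and
keep its identity, after which a new id is assigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .types import TrajectorySet, wrap_nematic

__all__ = ["Detection", "detect", "link"]


@dataclass
class Detection:
    frame: int
    x: float  # um
    y: float  # um
    theta: float  # rad, nematic
    length: float  # um, bounding-box long axis
    intensity: float


def _bbox_axis(coords_rc: np.ndarray, pixel_size: float):
    """Angle and long-side length of the minimum-area rotated bounding
    box of a pixel coordinate set (row, col)."""
    import shapely
    from shapely.geometry import MultiPoint

    if len(coords_rc) == 1:
        return 0.0, pixel_size
    pts = MultiPoint([(c, r) for r, c in coords_rc])  # (x, y) = (col, row)
    rect = pts.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # degenerate (collinear) -> line
        (x0, y0), (x1, y1) = rect.coords[0], rect.coords[-1]
        ang = np.arctan2(y1 - y0, x1 - x0)
        ln = np.hypot(x1 - x0, y1 - y0)
        return float(wrap_nematic(ang)), max(ln, 1.0) * pixel_size
    xy = np.asarray(rect.exterior.coords)[:4]
    sides = np.diff(np.vstack([xy, xy[:1]]), axis=0)[:2]
    lens = np.linalg.norm(sides, axis=1)
    k = int(np.argmax(lens))
    ang = np.arctan2(sides[k, 1], sides[k, 0])
    return float(wrap_nematic(ang)), max(float(lens[k]), 1.0) * pixel_size


def detect(
    frame: np.ndarray,
    pixel_size: float,
    min_area: int = 4,
    threshold_mode: str = "otsu",
    threshold_value: Optional[float] = None,
    frame_index: int = 0,
) -> List[Detection]:
    """Threshold-and-label segmentation of one (preprocessed) frame.

    ``threshold_mode``: 'otsu', 'mean', or 'absolute' (requires
    ``threshold_value``).  Objects smaller than ``min_area`` px are
    discarded.
    """
    frame = np.asarray(frame, dtype=float)
    if threshold_mode == "otsu":
        if np.ptp(frame) == 0:
            return []
        thr = threshold_otsu(frame)
    elif threshold_mode == "mean":
        thr = frame.mean()
    elif threshold_mode == "absolute":
        if threshold_value is None:
            raise ValueError("absolute threshold requires threshold_value")
        thr = threshold_value
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    mask = frame > thr
    labels = measure.label(mask, connectivity=2)
    out: List[Detection] = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < min_area:
            continue
        cy, cx = region.centroid_weighted
        theta, length = _bbox_axis(region.coords, pixel_size)
        out.append(
            Detection(
                frame=frame_index,
                x=float(cx * pixel_size),
                y=float(cy * pixel_size),
                theta=theta,
                length=length,
                intensity=float(region.image_intensity.sum()),
            )
        )
    return out


def link(
    detections: Sequence[Sequence[Detection]],
    max_disp: float,
    max_gap: int = 3,
    frame_interval: float = 1.0,
    pixel_size: float = 1.0,
) -> TrajectorySet:
    """Link per-frame detections into trajectories.

    Assignment is greedy by squared displacement with global conflict
    resolution (candidate pairs sorted by cost; each track and each
    detection used once).  A track missing for up to ``max_gap``
    frames may be resumed within ``max_disp`` um of its last position;
    beyond that a new id starts.  When two tracks claim one detection
    (objects merging/aggregating), only the cheaper keeps it; the
    other is terminated rather than guessed.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    rows = []
    next_id = 0
    # active tracks: id -> (last_frame, x, y)
    active: dict = {}

    def add_row(tid: int, det: Detection):
        rows.append(
            {
                "id": tid,
                "frame": det.frame,
                "t": det.frame * frame_interval,
                "x": det.x,
                "y": det.y,
                "theta": det.theta,
                "length": det.length,
            }
        )

    for frame_dets in detections:
        frame_dets = list(frame_dets)
        if not frame_dets:
            continue
        f = frame_dets[0].frame
        # retire tracks that exceeded the gap tolerance
        active = {
            tid: rec for tid, rec in active.items() if f - rec[0] <= max_gap + 1
        }
        candidates = []
        for tid, (lf, lx, ly) in active.items():
            for di, det in enumerate(frame_dets):
                cost = (det.x - lx) ** 2 + (det.y - ly) ** 2
                if cost <= max_disp**2:
                    candidates.append((cost, tid, di))
        candidates.sort(key=lambda c: c[0])
        used_tracks: set = set()
        used_dets: set = set()
        for cost, tid, di in candidates:
            if tid in used_tracks or di in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(di)
            det = frame_dets[di]
            add_row(tid, det)
            active[tid] = (f, det.x, det.y)
        for di, det in enumerate(frame_dets):
            if di in used_dets:
                continue
            add_row(next_id, det)
            active[next_id] = (f, det.x, det.y)
            next_id += 1
    df = pd.DataFrame(
        rows, columns=["id", "frame", "t", "x", "y", "theta", "length"]
    )
    return TrajectorySet(df, frame_interval=frame_interval, pixel_size=pixel_size)
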