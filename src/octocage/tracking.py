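"""Per-frame mouse segmentation and centroid/head tracking.

Re-implements the timelapse tracking stage: each frame's red channel is
thresholded (the mouse is a dark blob on a bright white or red
background), the largest connected component inside the cage becomes
the mouse, and per-frame centroid, area, elongation and head position
are extracted.  Frames with no acceptable blob are *missing*; sustained
missing runs are attributed to the mouse being inside the hut.

Also provides stretch-attend-posture (SAP) detection — elongated and
near-stationary frames — and quadrant assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .geometry import QUADRANT_LABELS, CageGeometry
from .schedule import AssaySchedule

#: default dark threshold on the red channel (0..255)
RED_THRESHOLD = 90
#: smallest acceptable blob area, px^2
MIN_BLOB_AREA = 40
#: SAP operational thresholds: elongation >= 2 and displacement <= 2 px/s
SAP_ELONGATION = 2.0
SAP_SPEED = 2.0


@dataclass
class Track:
    """Per-frame tracking output for one mouse.

    centroid/head are (n, 2) arrays with NaN where the mouse was not
    segmented; ``in_hut`` marks sustained missing runs attributed to the
    hut.  ``quadrant`` holds indices into
    :data:`octocage.geometry.QUADRANT_LABELS` (-1 = unknown).
    """

    time_s: np.ndarray
    centroid: np.ndarray
    head: np.ndarray
    area: np.ndarray
    elongation: np.ndarray
    in_hut: np.ndarray
    quadrant: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("centroid", "head", "area", "elongation", "in_hut", "quadrant"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"track field {name} has wrong length")
        if n > 1:
            dt = np.diff(self.time_s)
            if not (dt > 0).all() or not np.allclose(dt, dt[0]):
                raise ValueError("timestamps must increase with constant spacing")
        elong = self.elongation[np.isfinite(self.elongation)]
        if (elong < 1.0 - 1e-9).any():
            raise ValueError("elongation must be >= 1 where defined")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.centroid[:, 0])

    def speed(self) -> np.ndarray:
        """Per-frame centroid speed (px/s); NaN across missing frames and
        at the final frame."""
        out = np.full(len(self), np.nan)
        if len(self) > 1:
            dt = np.diff(self.time_s)
            disp = np.linalg.norm(np.diff(self.centroid, axis=0), axis=1)
            out[:-1] = disp / dt
        return out

    def to_frame(self) -> pd.DataFrame:
        quad = np.array(
            [QUADRANT_LABELS[q] if q >= 0 else "" for q in self.quadrant], dtype=object
        )
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "centroid_x": self.centroid[:, 0],
                "centroid_y": self.centroid[:, 1],
                "head_x": self.head[:, 0],
                "head_y": self.head[:, 1],
                "area": self.area,
                "elongation": self.elongation,
                "in_hut": self.in_hut.astype(int),
                "quadrant": quad,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Track":
        quad = np.array(
            [
                QUADRANT_LABELS.index(q) if q in QUADRANT_LABELS else -1
                for q in df["quadrant"].fillna("")
            ],
            dtype=np.int8,
        )
        return cls(
            time_s=df["time_s"].to_numpy(float),
            centroid=df[["centroid_x", "centroid_y"]].to_numpy(float),
            head=df[["head_x", "head_y"]].to_numpy(float),
            area=df["area"].to_numpy(float),
            elongation=df["elongation"].to_numpy(float),
            in_hut=df["in_hut"].to_numpy(bool),
            quadrant=quad,
        )


def segment_mouse(
    frame: np.ndarray,
    geometry: CageGeometry,
    phase: str = "day",
    threshold: float | None = RED_THRESHOLD,
    min_area: float = MIN_BLOB_AREA,
) -> dict | None:
    """Segment the mouse blob in one frame.

    The red channel is thresholded (dark mouse on a bright background;
    with ``threshold=None`` an Otsu threshold is computed per frame) and
    the largest connected component above ``min_area`` inside the cage
    bounds is returned as a record with centroid, area, orientation,
    elongation and the blob pixel coordinates.  Returns None when no
    component qualifies (e.g. mouse inside the hut).
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] < 3 or frame.size == 0:
        raise ValueError("frame must be a non-empty (H, W, 3) color image")
    if frame.shape[0] != geometry.height or frame.shape[1] != geometry.width:
        raise ValueError(
            f"frame shape {frame.shape[:2]} does not match geometry "
            f"({geometry.height}, {geometry.width})"
        )
    red = frame[:, :, 0].astype(float)
    if threshold is None:
        threshold = threshold_otsu(red)
    mask = red < threshold
    if not mask.any():
        return None
    labels = cc_label(mask)
    best = None
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        cy, cx = prop.centroid
        if not geometry.contains(cx, cy):
            continue
        if best is None or prop.area > best.area:
            best = prop
    if best is None:
        return None
    cy, cx = best.centroid
    minor = max(best.axis_minor_length, 1.0)
    coords = best.coords  # (row, col) pixel coordinates
    return {
        "centroid": np.array([cx, cy]),
        "area": float(best.area),
        "orientation": float(best.orientation),
        "elongation": float(best.axis_major_length / minor),
        "coords": coords,
    }


def track_video(
    frames,
    geometry: CageGeometry,
    schedule: AssaySchedule,
    threshold: float | None = RED_THRESHOLD,
    min_area: float = MIN_BLOB_AREA,
    hut_dwell: int = 2,
) -> Track:
    """Apply :func:`segment_mouse` to a frame sequence.

    The head is estimated as the blob-boundary pixel farthest along the
    motion-direction axis (falling back to the blob's major axis while
    stationary).  Runs of at least ``hut_dwell`` consecutive missing
    frames are attributed to the hut.
    """
    n = schedule.n_frames
    time_s = schedule.frame_times()
    centroid = np.full((n, 2), np.nan)
    head = np.full((n, 2), np.nan)
    area = np.full(n, np.nan)
    elong = np.full(n, np.nan)

    count = 0
    prev_c = None
    prev_dir = np.array([1.0, 0.0])
    for i, frame in enumerate(frames):
        if i >= n:
            count = i + 1
            continue
        phase = schedule.phase_at(min(time_s[i], schedule.total_duration - 1e-9))
        rec = segment_mouse(frame, geometry, phase, threshold, min_area)
        count = i + 1
        if rec is None:
            prev_c = None
            continue
        c = rec["centroid"]
        centroid[i] = c
        area[i] = rec["area"]
        elong[i] = rec["elongation"]
        if prev_c is not None and np.linalg.norm(c - prev_c) > 1e-6:
            direction = c - prev_c
        else:
            # stationary: use the blob's major axis, keeping the previous
            # travel sense to disambiguate the sign
            ori = rec["orientation"]  # regionprops: angle from the row axis
            direction = np.array([np.sin(ori), np.cos(ori)])
            if direction @ prev_dir < 0:
                direction = -direction
        prev_dir = direction / max(np.linalg.norm(direction), 1e-12)
        pix = rec["coords"][:, ::-1].astype(float)  # -> (x, y)
        head[i] = pix[np.argmax((pix - c) @ prev_dir)]
        prev_c = c
    if count != n:
        raise ValueError(f"frame count {count} does not match schedule ({n})")

    missing = ~np.isfinite(centroid[:, 0])
    in_hut = _fill_hut(missing, hut_dwell)
    quadrant = np.full(n, -1, dtype=np.int8)
    ok = ~missing
    if ok.any():
        quadrant[ok] = geometry.quadrant_codes(centroid[ok])
    quadrant[in_hut] = QUADRANT_LABELS.index("home")
    return Track(time_s, centroid, head, area, elong, in_hut, quadrant)


def _fill_hut(missing: np.ndarray, dwell: int) -> np.ndarray:
    """Mark missing runs of length >= dwell as in-hut."""
    in_hut = np.zeros(len(missing), bool)
    i = 0
    n = len(missing)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            if j - i >= dwell:
                in_hut[i:j] = True
            i = j
        else:
            i += 1
    return in_hut


def detect_sap(
    track: Track,
    elongation_threshold: float = SAP_ELONGATION,
    speed_threshold: float = SAP_SPEED,
) -> np.ndarray:
    """Stretch-attend-posture frames: elongated and near-stationary.

    True where elongation >= ``elongation_threshold`` and the
    frame-to-frame centroid displacement is <= ``speed_threshold``
    (px/s).  Missing frames are False.
    """
    speed = track.speed()
    elong = track.elongation
    with np.errstate(invalid="ignore"):
        out = (elong >= elongation_threshold) & (speed <= speed_threshold)
    return np.where(np.isfinite(elong) & np.isfinite(speed), out, False)


def assign_quadrant(point, geometry: CageGeometry) -> str:
    """Quadrant (home/wall/food/window) containing a pixel point.

    Boundary points resolve to the quadrant with the nearest centroid;
    points outside the cage raise ValueError.
    """
    x, y = float(point[0]), float(point[1])
    return geometry.quadrant_of(x, y)


def occupancy_percentages(track: Track) -> dict[str, float]:
    """Quadrant occupancy as % of frames with known location.

    In-hut frames count as home-quadrant time; frames that are missing
    for other reasons are excluded from the denominator.
    """
    known = track.quadrant >= 0
    total = int(known.sum())
    out = {}
    for qi, labl in enumerate(QUADRANT_LABELS):
        out[labl] = 100.0 * int((track.quadrant == qi).sum()) / total if total else np.nan
    return out
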