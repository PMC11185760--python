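"""Tracking- and pose-derived behavioral parameters.

Computes the 15 tracking-derived parameters (movement, acclimation,
habituation and quadrant occupancy from the centroid track) and the 52
pose-derived parameters (motion classes, speed, acclimation,
habituation, and location/sociability measures from the filtered
keypoint track) over the 22-h assay schedule.

Conventions
-----------
* Percent measures are 100 x qualifying / valid frames in the window;
  frames removed by the likelihood filter (or missing from tracking)
  are excluded from both numerator and denominator.  The one exception
  is Home, where in-hut time counts as home-quadrant time.
* Empty denominators yield the NaN sentinel, never 0.
* Acclimation is the value in the last 10-min bin of hour 1 minus the
  value in the first bin (negative = settling down).
* Habituation is the absolute level in the 10-min window following a
  stimulus onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import CageGeometry
from .pose import LIKELIHOOD_THRESHOLD, PoseTrack
from .schedule import AssaySchedule
from .tracking import Track, detect_sap, occupancy_percentages

#: speed-class thresholds t1..t4 (px/s): still < t1 <= scoot < t2 <= move
#: < t3 <= burst < t4 <= escape
MOTION_THRESHOLDS = (2.0, 10.0, 40.0, 80.0)
MOTION_CLASSES = ("still", "scoot", "move", "burst", "escape")

#: tracking-derived parameter ids, in table order
TRACK_PARAM_IDS = (
    "M1", "MD", "M7", "MN", "N-D", "AM", "AS", "HMM", "HL1M", "HL2M",
    "Home", "Wall", "Food", "Window", "Out",
)

#: pose-derived parameter ids, in table order
POSE_PARAM_IDS = (
    "M1", "MD", "M7", "MN", "MN-D",
    "Scl", "ScD", "Sc7", "ScN", "ScN-D",
    "Bl", "BD", "B7", "BN", "BN-D",
    "El", "ED", "E7", "EN", "EN-D",
    "Spl", "SpD", "Sp7", "SpN", "SpN-D",
    "AM", "ASc", "AB", "AE", "ASp",
    "HMM", "HL1M", "HL2M", "HMSc", "HL1Sc", "HL2Sc",
    "HMB", "HL1B", "HL2B", "HME", "HL1E", "HL2E",
    "HMSp", "HL1Sp", "HL2Sp",
    "Home", "Peek", "Window", "Wall", "Food", "DWindow", "Window Partner",
)

TRACK_PREFIX = "trk"
POSE_PREFIX = "pose"


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def filter_pose(pose: PoseTrack, threshold: float = LIKELIHOOD_THRESHOLD) -> PoseTrack:
    """Mark keypoint samples with likelihood < threshold invalid.

    The comparison is strict: a sample exactly at the threshold is kept.
    Coordinates are never modified.
    """
    return pose.filtered(threshold)


def speed_series(xy: np.ndarray, time_s: np.ndarray) -> np.ndarray:
    """Per-frame speed (px/s) from a possibly-NaN (n, 2) position series.

    speed[t] is the Euclidean displacement from frame t to t+1 divided
    by the time gap; it is NaN when either endpoint is invalid and at
    the final frame.
    """
    xy = np.asarray(xy, float)
    time_s = np.asarray(time_s, float)
    n = len(xy)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    out[:-1] = disp / np.diff(time_s)
    return out


def classify_motion(
    speed: np.ndarray, thresholds: tuple[float, ...] = MOTION_THRESHOLDS
) -> np.ndarray:
    """Speed-bin class codes: 0 still, 1 scoot, 2 move, 3 burst, 4 escape.

    Invalid (NaN) speeds get code -1.  "% movement" counts any class
    above still.
    """
    t = np.asarray(thresholds, float)
    if len(t) != 4 or not (np.diff(t) > 0).all() or t[0] <= 0:
        raise ValueError("thresholds must be four increasing positive values")
    speed = np.asarray(speed, float)
    codes = np.digitize(speed, t).astype(np.int8)
    codes[~np.isfinite(speed)] = -1
    return codes


def _window_mask(time_s: np.ndarray, intervals) -> np.ndarray:
    if isinstance(intervals, tuple) and np.isscalar(intervals[0]):
        intervals = [intervals]
    mask = np.zeros(len(time_s), bool)
    for lo, hi in intervals:
        mask |= (time_s >= lo) & (time_s < hi)
    return mask


def interval_percent(
    qualifying: np.ndarray,
    valid: np.ndarray,
    time_s: np.ndarray,
    interval,
) -> float:
    """100 x qualifying / valid frames within a half-open time window
    (or list of windows).  NaN when no valid frame falls inside."""
    w = _window_mask(time_s, interval)
    denom = int((valid & w).sum())
    if denom == 0:
        return np.nan
    return 100.0 * int((qualifying & valid & w).sum()) / denom


def interval_mean(
    values: np.ndarray, time_s: np.ndarray, interval
) -> float:
    """Mean of a per-frame series over a window, ignoring NaN."""
    w = _window_mask(time_s, interval)
    vals = np.asarray(values, float)[w]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if len(vals) else np.nan


def _hour1_bins(schedule: AssaySchedule):
    bin_len = schedule.hour_length / 6.0
    first = (0.0, bin_len)
    last = (5.0 * bin_len, 6.0 * bin_len)
    return first, last


def acclimation(
    qualifying: np.ndarray,
    valid: np.ndarray,
    time_s: np.ndarray,
    schedule: AssaySchedule,
) -> float:
    """Last minus first 10-min bin of hour 1, in percentage points."""
    first, last = _hour1_bins(schedule)
    return interval_percent(qualifying, valid, time_s, last) - interval_percent(
        qualifying, valid, time_s, first
    )


def acclimation_mean(
    values: np.ndarray, time_s: np.ndarray, schedule: AssaySchedule
) -> float:
    """Acclimation of a magnitude series (e.g. speed): last minus first
    10-min bin mean of hour 1."""
    first, last = _hour1_bins(schedule)
    return interval_mean(values, time_s, last) - interval_mean(values, time_s, first)


def habituation(
    qualifying: np.ndarray,
    valid: np.ndarray,
    time_s: np.ndarray,
    schedule: AssaySchedule,
    stimulus: str,
) -> float:
    """% qualifying in the 10-min window after a stimulus onset."""
    onset = schedule.onset_of(stimulus)
    return interval_percent(
        qualifying, valid, time_s, (onset, onset + schedule.period_length)
    )


def habituation_mean(
    values: np.ndarray, time_s: np.ndarray, schedule: AssaySchedule, stimulus: str
) -> float:
    onset = schedule.onset_of(stimulus)
    return interval_mean(values, time_s, (onset, onset + schedule.period_length))


# ---------------------------------------------------------------------------
# location and sociability
# ---------------------------------------------------------------------------


def location_params(
    pose: PoseTrack, geometry: CageGeometry
) -> dict[str, float]:
    """Pose-derived occupancy/distance measures.

    Home: % valid frames with the center inside the hut; Peek: % with
    the center inside and the nose outside; Window: % within the window
    radius; Wall/Food: mean over frames of the minimum distance to any
    wall segment / food point; DWindow: mean distance to the window.
    Both the mean and the minimum over time of the wall/food distances
    are returned (ids Wall/Food are the means).
    """
    center = pose.xy_valid("center")
    nose = pose.xy_valid("nose")
    cvalid = np.isfinite(center[:, 0])
    n_valid = int(cvalid.sum())
    if n_valid == 0:
        keys = ("Home", "Peek", "Window", "Wall", "Food", "DWindow",
                "Wall_min", "Food_min")
        return dict.fromkeys(keys, np.nan)
    c = center[cvalid]
    in_hut = geometry.in_hut_mask(c)
    home = 100.0 * in_hut.sum() / n_valid

    both = cvalid & np.isfinite(nose[:, 0])
    if both.any():
        c2 = center[both]
        n2 = nose[both]
        hut_c = geometry.in_hut_mask(c2)
        hut_n = geometry.in_hut_mask(n2)
        peek = 100.0 * (hut_c & ~hut_n).sum() / both.sum()
    else:
        peek = np.nan

    wdist = geometry.window_distance(c)
    window = 100.0 * (wdist <= geometry.window_radius).sum() / n_valid
    wall = geometry.wall_distance(c)
    food = geometry.food_distance(c)
    return {
        "Home": float(home),
        "Peek": float(peek),
        "Window": float(window),
        "Wall": float(np.mean(wall)),
        "Food": float(np.nanmean(food)) if np.isfinite(food).any() else np.nan,
        "DWindow": float(np.mean(wdist)),
        "Wall_min": float(np.min(wall)),
        "Food_min": float(np.nanmin(food)) if np.isfinite(food).any() else np.nan,
    }


def window_partner(
    pose_a: PoseTrack,
    pose_b: PoseTrack,
    geometry_a: CageGeometry,
    geometry_b: CageGeometry | None = None,
) -> dict[str, float]:
    """% of mouse-a window time during which the partner is also near
    its own window.

    Returns the a-conditional form (id "Window Partner") and, as a
    variant, the same co-occurrence normalized by total valid time.
    """
    geometry_b = geometry_b or geometry_a
    if len(pose_a) != len(pose_b) or not np.allclose(pose_a.time_s, pose_b.time_s):
        raise ValueError("partner tracks must share the same time grid")
    ca = pose_a.xy_valid("center")
    cb = pose_b.xy_valid("center")
    valid = np.isfinite(ca[:, 0]) & np.isfinite(cb[:, 0])
    if not valid.any():
        return {"Window Partner": np.nan, "Window Partner_total": np.nan}
    da = geometry_a.window_distance(ca[valid])
    db = geometry_b.window_distance(cb[valid])
    a_win = da <= geometry_a.window_radius
    b_win = db <= geometry_b.window_radius
    n_a = int(a_win.sum())
    cond = 100.0 * int((a_win & b_win).sum()) / n_a if n_a else np.nan
    total = 100.0 * int((a_win & b_win).sum()) / int(valid.sum())
    return {"Window Partner": cond, "Window Partner_total": total}


# ---------------------------------------------------------------------------
# parameter families
# ---------------------------------------------------------------------------


def _family_windows(schedule: AssaySchedule):
    return {
        "1": [schedule.hour_window(1)],
        "D": schedule.daytime,
        "7": [schedule.hour_window(7)],
        "N": schedule.nighttime,
    }


def compute_track_params(
    track: Track,
    geometry: CageGeometry,
    schedule: AssaySchedule,
    sap_elongation: float | None = None,
    sap_speed: float | None = None,
) -> pd.Series:
    """The 15 tracking-derived parameters from a centroid track."""
    time_s = track.time_s
    speed = track.speed()
    valid = np.isfinite(speed)
    moving = valid & (speed >= MOTION_THRESHOLDS[0])
    sap_kw = {}
    if sap_elongation is not None:
        sap_kw["elongation_threshold"] = sap_elongation
    if sap_speed is not None:
        sap_kw["speed_threshold"] = sap_speed
    sap = detect_sap(track, **sap_kw)
    sap_valid = valid & np.isfinite(track.elongation)

    win = _family_windows(schedule)
    out = {}
    out["M1"] = interval_percent(moving, valid, time_s, win["1"])
    out["MD"] = interval_percent(moving, valid, time_s, win["D"])
    out["M7"] = interval_percent(moving, valid, time_s, win["7"])
    out["MN"] = interval_percent(moving, valid, time_s, win["N"])
    out["N-D"] = out["MN"] - out["MD"]
    out["AM"] = acclimation(moving, valid, time_s, schedule)
    out["AS"] = acclimation(sap, sap_valid, time_s, schedule)
    out["HMM"] = habituation(moving, valid, time_s, schedule, "moth")
    out["HL1M"] = habituation(moving, valid, time_s, schedule, "lines1")
    out["HL2M"] = habituation(moving, valid, time_s, schedule, "lines2")
    occ = occupancy_percentages(track)
    out["Home"] = occ["home"]
    out["Wall"] = occ["wall"]
    out["Food"] = occ["food"]
    out["Window"] = occ["window"]
    out["Out"] = occ["wall"] + occ["window"]
    return pd.Series(out).reindex(list(TRACK_PARAM_IDS))


def compute_pose_params(
    pose: PoseTrack,
    partner_pose: PoseTrack | None,
    geometry: CageGeometry,
    schedule: AssaySchedule,
    thresholds: tuple[float, ...] = MOTION_THRESHOLDS,
    include_variants: bool = False,
) -> pd.Series:
    """The 52 pose-derived parameters from a likelihood-filtered track.

    ``include_variants`` appends the documented alternative definitions
    (min-over-time wall/food distance; total-time-normalized partner
    measure) under ``_min``/``_total`` suffixed ids.
    """
    if pose.valid is None:
        pose = filter_pose(pose)
    if partner_pose is not None and partner_pose.valid is None:
        partner_pose = filter_pose(partner_pose)
    time_s = pose.time_s
    center = pose.xy_valid("center")
    speed = speed_series(center, time_s)
    codes = classify_motion(speed, thresholds)
    valid = codes >= 0

    masks = {
        "M": valid & (codes >= 1),
        "Sc": codes == 1,
        "B": codes == 3,
        "E": codes == 4,
    }
    win = _family_windows(schedule)
    out = {}
    for prefix, fam_ids in (("M", ("M1", "MD", "M7", "MN", "MN-D")),
                            ("Sc", ("Scl", "ScD", "Sc7", "ScN", "ScN-D")),
                            ("B", ("Bl", "BD", "B7", "BN", "BN-D")),
                            ("E", ("El", "ED", "E7", "EN", "EN-D"))):
        q = masks[prefix]
        vals = {
            "1": interval_percent(q, valid, time_s, win["1"]),
            "D": interval_percent(q, valid, time_s, win["D"]),
            "7": interval_percent(q, valid, time_s, win["7"]),
            "N": interval_percent(q, valid, time_s, win["N"]),
        }
        out[fam_ids[0]] = vals["1"]
        out[fam_ids[1]] = vals["D"]
        out[fam_ids[2]] = vals["7"]
        out[fam_ids[3]] = vals["N"]
        out[fam_ids[4]] = vals["N"] - vals["D"]
    out["Spl"] = interval_mean(speed, time_s, win["1"])
    out["SpD"] = interval_mean(speed, time_s, win["D"])
    out["Sp7"] = interval_mean(speed, time_s, win["7"])
    out["SpN"] = interval_mean(speed, time_s, win["N"])
    out["SpN-D"] = out["SpN"] - out["SpD"]

    out["AM"] = acclimation(masks["M"], valid, time_s, schedule)
    out["ASc"] = acclimation(masks["Sc"], valid, time_s, schedule)
    out["AB"] = acclimation(masks["B"], valid, time_s, schedule)
    out["AE"] = acclimation(masks["E"], valid, time_s, schedule)
    out["ASp"] = acclimation_mean(speed, time_s, schedule)

    for stim, tag in (("moth", "M"), ("lines1", "L1"), ("lines2", "L2")):
        key = {"M": "HMM", "L1": "HL1M", "L2": "HL2M"}[tag]
        out[key] = habituation(masks["M"], valid, time_s, schedule, stim)
    for stim, tag in (("moth", "HMSc"), ("lines1", "HL1Sc"), ("lines2", "HL2Sc")):
        out[tag] = habituation(masks["Sc"], valid, time_s, schedule, stim)
    for stim, tag in (("moth", "HMB"), ("lines1", "HL1B"), ("lines2", "HL2B")):
        out[tag] = habituation(masks["B"], valid, time_s, schedule, stim)
    for stim, tag in (("moth", "HME"), ("lines1", "HL1E"), ("lines2", "HL2E")):
        out[tag] = habituation(masks["E"], valid, time_s, schedule, stim)
    for stim, tag in (("moth", "HMSp"), ("lines1", "HL1Sp"), ("lines2", "HL2Sp")):
        out[tag] = habituation_mean(speed, time_s, schedule, stim)

    loc = location_params(pose, geometry)
    out["Home"] = loc["Home"]
    out["Peek"] = loc["Peek"]
    out["Window"] = loc["Window"]
    out["Wall"] = loc["Wall"]
    out["Food"] = loc["Food"]
    out["DWindow"] = loc["DWindow"]
    if partner_pose is not None:
        wp = window_partner(pose, partner_pose, geometry)
        out["Window Partner"] = wp["Window Partner"]
    else:
        wp = {"Window Partner_total": np.nan}
        out["Window Partner"] = np.nan

    series = pd.Series(out).reindex(list(POSE_PARAM_IDS))
    if include_variants:
        series["Wall_min"] = loc["Wall_min"]
        series["Food_min"] = loc["Food_min"]
        series["Window Partner_total"] = wp["Window Partner_total"]
    return series


def compute_param_vector(
    track: Track,
    pose: PoseTrack,
    partner_pose: PoseTrack | None,
    geometry: CageGeometry,
    schedule: AssaySchedule,
) -> pd.Series:
    """All 67 behavioral parameters with namespaced ids.

    Tracking-derived ids are prefixed ``trk:``, pose-derived ids
    ``pose:`` (the two families share raw ids such as M1).
    """
    trk = compute_track_params(track, geometry, schedule)
    pos = compute_pose_params(pose, partner_pose, geometry, schedule)
    out = {}
    for k, v in trk.items():
        out[f"{TRACK_PREFIX}:{k}"] = v
    for k, v in pos.items():
        out[f"{POSE_PREFIX}:{k}"] = v
    return pd.Series(out)
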