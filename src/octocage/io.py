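"""Readers and writers for the pipeline's on-disk formats.

Everything is plain headered CSV, zero-padded numbered image files for
frame sequences, YAML for configuration, and Newick for dendrograms.
Pose tables use the DeepLabCut CSV dialect: three header rows
(scorer / bodyparts / coords) with x, y, likelihood columns per body
part and the frame index in the first column.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .gait import FootfallEvent, GaitRun
from .pose import BODY_PARTS, PoseTrack
from .syllables import SyllableSequence
from .tracking import Track

DEFAULT_SCORER = "octocage"


# ---------------------------------------------------------------------------
# pose tables (DeepLabCut CSV dialect)
# ---------------------------------------------------------------------------


def write_pose_table(pose: PoseTrack, path, scorer: str = DEFAULT_SCORER) -> None:
    """Write a pose track in the 3-header-row dialect."""
    parts = list(pose.data.columns.get_level_values(0).unique())
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [scorer] * (3 * len(parts)))
        w.writerow(["bodyparts"] + [p for p in parts for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * len(parts))
        arr = np.column_stack(
            [pose.data[(p, c)].to_numpy() for p in parts for c in ("x", "y", "likelihood")]
        )
        for i in range(len(pose)):
            w.writerow([i] + [repr(float(v)) for v in arr[i]])


def read_pose_table(path, frame_interval: float = 1.0) -> PoseTrack:
    """Read a 3-header-row pose table; extra (non-mouse) markers are
    tolerated and ignored.  A missing required body part is an error
    naming the part."""
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0,
                         float_precision="round_trip")
    except Exception as exc:  # malformed header / truncated file
        raise ValueError(f"malformed pose table {path}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise ValueError(f"malformed pose table {path}: expected 3 header rows")
    df.columns = df.columns.droplevel(0)  # drop the scorer level
    available = list(df.columns.get_level_values(0).unique())
    missing = [p for p in BODY_PARTS if p not in available]
    if missing:
        raise ValueError(f"pose table {path} is missing body part(s): {missing}")
    cols = {}
    for part in BODY_PARTS:
        for coord in ("x", "y", "likelihood"):
            if (part, coord) not in df.columns:
                raise ValueError(f"pose table {path}: part {part!r} lacks {coord}")
            cols[(part, coord)] = df[(part, coord)].to_numpy(float)
    data = pd.DataFrame(cols)
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["bodyparts", "coords"])
    time_s = df.index.to_numpy(float) * frame_interval
    return PoseTrack(time_s, data)


# ---------------------------------------------------------------------------
# tracks, syllables, footfalls, generic tables
# ---------------------------------------------------------------------------


def write_track(track: Track, path) -> None:
    track.to_frame().to_csv(path, index=False)


def read_track(path) -> Track:
    df = pd.read_csv(path)
    required = {"time_s", "centroid_x", "centroid_y", "in_hut", "quadrant"}
    if not required <= set(df.columns):
        raise ValueError(f"track file {path} lacks columns {required - set(df.columns)}")
    return Track.from_frame(df)


def write_syllables(seq: SyllableSequence, path) -> None:
    seq.to_frame().to_csv(path, index=False)


def read_syllables(path, alphabet=None) -> SyllableSequence:
    df = pd.read_csv(path)
    if not {"time_s", "label"} <= set(df.columns):
        raise ValueError(f"syllable file {path} must have time_s and label columns")
    kwargs = {} if alphabet is None else {"alphabet": tuple(alphabet)}
    return SyllableSequence(
        df["time_s"].to_numpy(float), df["label"].to_numpy(int), **kwargs
    )


def write_footfalls(run: GaitRun, path) -> None:
    df = run.to_frame()
    df.insert(0, "direction", run.direction)
    df.to_csv(path, index=False)


def read_footfalls(path) -> GaitRun:
    df = pd.read_csv(path)
    required = {"paw", "contact_start_s", "contact_end_s", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(
            f"footfall file {path} lacks columns {required - set(df.columns)}"
        )
    direction = int(df["direction"].iloc[0]) if "direction" in df else 1
    fields = [f for f in df.columns if f in FootfallEvent.__dataclass_fields__]
    events = [
        FootfallEvent(**{f: row[f] for f in fields}) for _, row in df.iterrows()
    ]
    return GaitRun(events=events, direction=direction)


# ---------------------------------------------------------------------------
# frame sequences
# ---------------------------------------------------------------------------


def write_frames(frames, directory, fmt: str = "png", pad: int = 6) -> list[Path]:
    """Write a frame sequence as zero-padded numbered images."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"frame_{i:0{pad}d}.{fmt}"
        iio.imwrite(p, np.asarray(frame))
        paths.append(p)
    return paths


def read_frames(directory, fmt: str = "png"):
    """Yield frames from a numbered image directory, in order."""
    import imageio.v3 as iio

    directory = Path(directory)
    for p in sorted(directory.glob(f"frame_*.{fmt}")):
        yield iio.imread(p)


def crop_composite(frames, rectangles) -> list[list[np.ndarray]]:
    """Split composite frames into per-cage sequences.

    ``rectangles`` is a list of (x, y, width, height) crops; crops must
    lie inside the composite, overlapping crops only warn.  Returns one
    frame list per rectangle, in input order.
    """
    rects = [tuple(int(v) for v in r) for r in rectangles]
    frames = list(frames)
    if not frames:
        return [[] for _ in rects]
    h, w = np.asarray(frames[0]).shape[:2]
    for x, y, cw, ch in rects:
        if x < 0 or y < 0 or x + cw > w or y + ch > h or cw <= 0 or ch <= 0:
            raise ValueError(f"crop rectangle {(x, y, cw, ch)} outside composite bounds")
    for i in range(len(rects)):
        for j in range(i + 1, len(rects)):
            if _rects_overlap(rects[i], rects[j]):
                warnings.warn(f"crop rectangles {i} and {j} overlap")
    out = [[] for _ in rects]
    for frame in frames:
        frame = np.asarray(frame)
        for k, (x, y, cw, ch) in enumerate(rects):
            out[k].append(frame[y : y + ch, x : x + cw].copy())
    return out


def grid_rectangles(
    width: int = 960, height: int = 640, rows: int = 2, cols: int = 4
) -> list[tuple[int, int, int, int]]:
    """The default 8-cage crop layout: a rows x cols grid of the
    composite (2 x 4 of 640 x 960 -> per-cage 320 x 240)."""
    cw, ch = width // cols, height // rows
    return [(c * cw, r * ch, cw, ch) for r in range(rows) for c in range(cols)]


def _rects_overlap(a, b) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return ax < bx + bw and bx < ax + aw and ay < by + bh and by < ay + ah


# ---------------------------------------------------------------------------
# profile tables
# ---------------------------------------------------------------------------


def write_profile_table(
    profiles: pd.DataFrame, path, supplementary_layout: bool = False
) -> None:
    """Write a profile table (one row per mouse).

    ``supplementary_layout`` reorders columns to the d*, f*, pose
    block, tracking block convention used by published per-mouse
    summary tables.
    """
    df = profiles
    if supplementary_layout:
        d = [c for c in df.columns if c.startswith("d")]
        f = [c for c in df.columns if c.startswith("f")]
        pose = [c for c in df.columns if c.startswith("pose:")]
        trk = [c for c in df.columns if c.startswith("trk:")]
        rest = [c for c in df.columns if c not in set(d + f + pose + trk)]
        df = df[d + f + pose + trk + rest]
    df.to_csv(path, index=True, index_label="mouse")


def read_profile_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="mouse")
    if df.empty:
        raise ValueError(f"profile table {path} is empty")
    return df


def read_supplementary_profiles(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a published per-mouse summary table (one row per mouse).

    Expects group-label columns (any of genotype/age/treatment/group,
    case-insensitive) alongside the numeric parameter columns (d*/f*
    syllable entries plus the pose- and tracking-derived blocks).
    Returns (parameters, labels).
    """
    df = pd.read_csv(path)
    label_cols = [c for c in df.columns
                  if c.strip().lower() in ("mouse", "id", "genotype", "age",
                                           "treatment", "group", "sex")]
    labels = df[label_cols].copy()
    labels.columns = [c.strip().lower() for c in label_cols]
    if "mouse" in labels.columns:
        labels = labels.set_index("mouse")
        df = df.set_index("mouse")
    params = df.drop(columns=label_cols, errors="ignore")
    params = params.apply(pd.to_numeric, errors="coerce")
    params = params.dropna(axis=1, how="all")
    if params.empty:
        raise ValueError(f"{path} contains no numeric parameter columns")
    return params, labels
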