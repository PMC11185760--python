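"""Pose-track container: per-frame keypoint coordinates with likelihoods.

A :class:`PoseTrack` holds the 8 labelled mouse body parts produced by
markerless pose estimation (nose, right ear, left ear, head, neck,
center, hip, tail base), each as per-frame (x, y, likelihood) triples on
the assay frame grid.  Likelihood filtering marks low-confidence samples
invalid; invalid samples are excluded from all downstream statistics but
their coordinates are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

BODY_PARTS = (
    "nose",
    "right ear",
    "left ear",
    "head",
    "neck",
    "center",
    "hip",
    "tail base",
)

#: default likelihood cutoff; samples strictly below are discarded
LIKELIHOOD_THRESHOLD = 0.90


@dataclass
class PoseTrack:
    """Keypoint trajectories for one mouse.

    Attributes
    ----------
    time_s : ndarray, shape (n_frames,)
        Strictly increasing timestamps on the schedule grid.
    data : DataFrame
        Columns are a (bodypart, coord) MultiIndex with coord in
        {x, y, likelihood}; one row per frame.
    valid : dict part -> bool ndarray, or None
        Set by :meth:`filtered`; True where the sample passed the
        likelihood filter.
    truth : dict or None
        Ground-truth per-frame state arrays when the track came from the
        simulator (in_hut, motion_state, sap, at_window, ...).
    """

    time_s: np.ndarray
    data: pd.DataFrame
    valid: dict[str, np.ndarray] | None = None
    truth: dict[str, Any] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        if len(self.time_s) != len(self.data):
            raise ValueError("time_s and data must have equal length")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if not (dt > 0).all():
                raise ValueError("timestamps must be strictly increasing")
        missing = [p for p in BODY_PARTS if p not in self.data.columns.get_level_values(0)]
        if missing:
            raise ValueError(f"pose table is missing body part(s): {missing}")
        lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy()
        if np.nanmin(lik) < 0 or np.nanmax(lik) > 1:
            raise ValueError("likelihoods must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def parts(self) -> tuple[str, ...]:
        return BODY_PARTS

    def xy(self, part: str) -> np.ndarray:
        """(n, 2) raw coordinates of one body part."""
        return self.data[part][["x", "y"]].to_numpy(float)

    def likelihood(self, part: str) -> np.ndarray:
        return self.data[part]["likelihood"].to_numpy(float)

    def valid_mask(self, part: str) -> np.ndarray:
        """Validity mask of a part (all-True when unfiltered)."""
        if self.valid is None:
            return np.ones(self.n_frames, dtype=bool)
        return self.valid[part]

    def xy_valid(self, part: str) -> np.ndarray:
        """(n, 2) coordinates with invalid samples replaced by NaN."""
        out = self.xy(part).copy()
        out[~self.valid_mask(part)] = np.nan
        return out

    def filtered(self, threshold: float = LIKELIHOOD_THRESHOLD) -> "PoseTrack":
        """Return a copy with the likelihood filter applied.

        Samples with likelihood strictly below ``threshold`` are marked
        invalid (a likelihood exactly at the threshold is kept).
        """
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("likelihood threshold must lie in [0, 1]")
        valid = {p: self.likelihood(p) >= threshold for p in BODY_PARTS}
        return PoseTrack(self.time_s, self.data, valid=valid, truth=self.truth)

    def translated(self, dx: float, dy: float) -> "PoseTrack":
        """Rigidly shift all coordinates (used by invariance checks)."""
        data = self.data.copy()
        data.loc[:, (slice(None), "x")] += dx
        data.loc[:, (slice(None), "y")] += dy
        return PoseTrack(self.time_s, data, valid=self.valid, truth=self.truth)


def pose_from_arrays(
    time_s: np.ndarray,
    coords: dict[str, np.ndarray],
    likelihoods: dict[str, np.ndarray] | None = None,
    truth: dict[str, Any] | None = None,
) -> PoseTrack:
    """Build a :class:`PoseTrack` from (n, 2) coordinate arrays per part."""
    n = len(time_s)
    cols = {}
    for part in BODY_PARTS:
        xy = np.asarray(coords[part], float)
        lik = (
            np.ones(n) if likelihoods is None else np.asarray(likelihoods[part], float)
        )
        cols[(part, "x")] = xy[:, 0]
        cols[(part, "y")] = xy[:, 1]
        cols[(part, "likelihood")] = lik
    data = pd.DataFrame(cols)
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["bodyparts", "coords"])
    return PoseTrack(np.asarray(time_s, float), data, truth=truth)
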