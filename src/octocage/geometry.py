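"""Cage geometry: bounds, quadrants, hut, window, food and wall features.

Coordinates are pixels with the origin at the top-left of the per-cage
frame, x rightward and y downward.  Each cage is partitioned into four
quadrants (home, wall, food, window); the shelter hut sits inside the
home quadrant and the viewing window — a hole giving visual access to
the partner mouse in the neighbouring cage — sits in the window quadrant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

QUADRANT_LABELS = ("home", "wall", "food", "window")


@dataclass
class CageGeometry:
    """Pixel geometry of a single cage.

    Parameters
    ----------
    width, height : int
        Per-cage frame size in pixels.
    quadrants : dict mapping label -> Polygon
        A partition of the cage rectangle into home/wall/food/window.
    hut : Polygon
        Shelter region; must lie inside the home quadrant.
    window_center : (x, y)
    window_radius : float
        Radius of the "near the window" zone, 40 px by default.
    food_points : list of (x, y)
    wall_segments : list of ((x0, y0), (x1, y1))
        Cage walls used for the wall-distance parameter.
    """

    width: int
    height: int
    quadrants: dict[str, Polygon]
    hut: Polygon
    window_center: tuple[float, float]
    window_radius: float = 40.0
    food_points: list[tuple[float, float]] = field(default_factory=list)
    wall_segments: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("cage dimensions must be positive")
        if self.window_radius <= 0:
            raise ValueError("window radius must be positive")
        if set(self.quadrants) != set(QUADRANT_LABELS):
            raise ValueError(f"quadrants must be exactly {QUADRANT_LABELS}")
        if not self.hut.within(self.quadrants["home"].buffer(1e-6)):
            raise ValueError("hut must lie inside the home quadrant")
        self._prepared = {k: prep(v) for k, v in self.quadrants.items()}
        self._quad_centroids = {
            k: (v.centroid.x, v.centroid.y) for k, v in self.quadrants.items()
        }
        self._hut_prepared = prep(self.hut)

    # -- membership ---------------------------------------------------------

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height

    def in_hut(self, x: float, y: float) -> bool:
        return self._hut_prepared.intersects(Point(x, y))

    def in_hut_mask(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized hut membership for an (n, 2) array of points."""
        import shapely

        xy = np.asarray(xy, float)
        return shapely.intersects_xy(self.hut, xy[:, 0], xy[:, 1])

    def quadrant_codes(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized quadrant assignment; returns indices into
        :data:`QUADRANT_LABELS` (-1 for points outside the cage)."""
        import shapely

        xy = np.asarray(xy, float)
        codes = np.full(len(xy), -1, dtype=np.int8)
        inside = (
            (xy[:, 0] >= 0) & (xy[:, 0] < self.width)
            & (xy[:, 1] >= 0) & (xy[:, 1] < self.height)
        )
        claimed = np.zeros(len(xy), dtype=bool)
        for qi, label in enumerate(QUADRANT_LABELS):
            hit = shapely.contains_xy(self.quadrants[label], xy[:, 0], xy[:, 1])
            hit &= inside & ~claimed
            codes[hit] = qi
            claimed |= hit
        # boundary points: nearest quadrant centroid tie-break
        for i in np.flatnonzero(inside & ~claimed):
            codes[i] = QUADRANT_LABELS.index(self.quadrant_of(xy[i, 0], xy[i, 1]))
        return codes

    def quadrant_of(self, x: float, y: float) -> str:
        """Quadrant label containing (x, y); see :func:`tracking.assign_quadrant`."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside cage bounds")
        p = Point(x, y)
        hits = [k for k, q in self._prepared.items() if q.contains(p)]
        if len(hits) == 1:
            return hits[0]
        # boundary point: covered by >= 2 closed quadrants (or by none, for
        # interior-boundary float edge cases) -> nearest quadrant centroid
        touching = [k for k, q in self.quadrants.items() if q.distance(p) < 1e-9]
        candidates = touching or list(self.quadrants)
        return min(
            candidates,
            key=lambda k: (x - self._quad_centroids[k][0]) ** 2
            + (y - self._quad_centroids[k][1]) ** 2,
        )

    # -- distances ----------------------------------------------------------

    def wall_distance(self, xy: np.ndarray) -> np.ndarray:
        """Minimum distance from each point to any wall segment."""
        xy = np.asarray(xy, float)
        dists = np.full(len(xy), np.inf)
        for (x0, y0), (x1, y1) in self.wall_segments:
            dists = np.minimum(dists, _point_segment_distance(xy, (x0, y0), (x1, y1)))
        return dists

    def food_distance(self, xy: np.ndarray) -> np.ndarray:
        """Minimum distance from each point to any food point."""
        xy = np.asarray(xy, float)
        pts = np.asarray(self.food_points, float)
        if len(pts) == 0:
            return np.full(len(xy), np.nan)
        d = np.linalg.norm(xy[:, None, :] - pts[None, :, :], axis=2)
        return d.min(axis=1)

    def window_distance(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, float)
        wc = np.asarray(self.window_center, float)
        return np.linalg.norm(xy - wc, axis=1)


def _point_segment_distance(xy, a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(xy - a, axis=1)
    t = np.clip((xy - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab[None, :]
    return np.linalg.norm(xy - proj, axis=1)


def default_geometry(width: int = 240, height: int = 320) -> CageGeometry:
    """The reference single-cage layout.

    The cage is split into 2 x 2 rectangular quadrants: home (top-left,
    containing the hut), wall (top-right), food (bottom-right, containing
    the food points), and window (bottom-left, containing the window to
    the partner cage in the lower inside-facing corner).
    """
    w2, h2 = width / 2.0, height / 2.0
    quadrants = {
        "home": Polygon([(0, 0), (w2, 0), (w2, h2), (0, h2)]),
        "wall": Polygon([(w2, 0), (width, 0), (width, h2), (w2, h2)]),
        "food": Polygon([(w2, h2), (width, h2), (width, height), (w2, height)]),
        "window": Polygon([(0, h2), (w2, h2), (w2, height), (0, height)]),
    }
    hut = Polygon(
        [
            (0.10 * width, 0.12 * height),
            (0.42 * width, 0.12 * height),
            (0.42 * width, 0.38 * height),
            (0.10 * width, 0.38 * height),
        ]
    )
    window_center = (0.14 * width, 0.90 * height)
    food_points = [(0.80 * width, 0.82 * height), (0.88 * width, 0.90 * height)]
    corners = [(0, 0), (width, 0), (width, height), (0, height)]
    wall_segments = [(corners[i], corners[(i + 1) % 4]) for i in range(4)]
    return CageGeometry(
        width=width,
        height=height,
        quadrants=quadrants,
        hut=hut,
        window_center=window_center,
        food_points=food_points,
        wall_segments=wall_segments,
    )
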