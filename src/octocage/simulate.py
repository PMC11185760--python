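"""Seeded generators for every input the pipeline consumes.

The generators emulate the 8-cage homecage assay: a 22-h schedule of
day/night phases with three visual stimuli, per-frame pose tables for 8
body parts, rendered frame sequences (dark elliptical mouse on a white
or red background), behavioral-syllable label sequences, and walkway
footfall logs.  Group structure (genotype x age x treatment) is planted
as named offsets on the behavioral-state parameters so that every
planted quantity is recoverable from the generated data.

Occupancy-like quantities (hut, window, post-stimulus activity) are
scheduled per 10-minute period with exact frame counts, so planted
fractions are recoverable by brute-force counting; motion-state speeds
sit strictly inside the speed-classification bins, so the motion classes
are exact by construction on noiseless tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .geometry import CageGeometry, default_geometry
from .pose import BODY_PARTS, PoseTrack, pose_from_arrays
from .schedule import AssaySchedule
from .syllables import SYLLABLE_IDS, SYLLABLE_LABELS, SyllableSequence
from . import gait as gait_mod

GENOTYPES = ("WT", "AD")
AGES = ("young", "old", "aged")
TREATMENTS = ("none", "csa", "neb", "cab")

MOTION_STATES = ("still", "scoot", "move", "burst", "escape")
#: per-state speeds (px/s), strictly inside the default classification
#: bins (2, 10, 40, 80) so classes are recovered exactly
STATE_SPEEDS = {"still": 0.0, "scoot": 6.0, "move": 25.0, "burst": 60.0, "escape": 110.0}

#: body length (nose to tail base, px) in normal posture and in
#: stretch-attend posture (SAP)
BODY_LENGTH_PX = 30.0
BODY_LENGTH_SAP_PX = 60.0

#: keypoint offsets along the body axis as fractions of body length
#: (positive = toward the nose) and lateral offsets in px
_PART_LAYOUT = {
    "nose": (0.50, 0.0),
    "right ear": (0.22, 7.0),
    "left ear": (0.22, -7.0),
    "head": (0.32, 0.0),
    "neck": (0.15, 0.0),
    "center": (0.0, 0.0),
    "hip": (-0.28, 0.0),
    "tail base": (-0.50, 0.0),
}


# ---------------------------------------------------------------------------
# configuration and group structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectVector:
    """Named offsets on the simulator's behavioral-state parameters.

    All fields are additive offsets on fractions in [0, 1], except
    ``syllable_bias`` which is a 0..1 repertoire-narrowing intensity.
    """

    activity: float = 0.0
    hut: float = 0.0
    habituation: float = 0.0
    acclimation: float = 0.0
    window: float = 0.0
    sociability: float = 0.0
    sap: float = 0.0
    syllable_bias: float = 0.0

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if not np.isfinite(val):
                raise ValueError(f"effect offset {name} must be finite")

    def scaled(self, factor: float) -> "EffectVector":
        return EffectVector(**{k: v * factor for k, v in vars(self).items()})

    def __add__(self, other: "EffectVector") -> "EffectVector":
        return EffectVector(
            **{k: getattr(self, k) + getattr(other, k) for k in vars(self)}
        )


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group of the genotype x age x treatment design."""

    genotype: str = "WT"
    age: str = "young"
    treatment: str = "none"
    effects: EffectVector = field(default_factory=EffectVector)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.age not in AGES:
            raise ValueError(f"age must be one of {AGES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")

    @property
    def name(self) -> str:
        label = f"{self.genotype}_{self.age}"
        if self.treatment != "none":
            label += f"_{self.treatment}"
        return label


#: age-driven offsets (applied to every genotype)
_AGE_EFFECTS = {
    "young": EffectVector(),
    "old": EffectVector(activity=-0.10, hut=0.10, acclimation=0.05, sap=0.02),
    "aged": EffectVector(activity=-0.14, hut=0.14, acclimation=0.07, sap=0.03),
}

#: genotype-driven offsets of the AD model, by age (the repertoire
#: narrowing is strongest at the old timepoint)
_AD_EFFECTS = {
    "young": EffectVector(
        activity=-0.06, hut=0.05, habituation=-0.18, acclimation=0.08,
        sap=0.05, window=-0.04, sociability=-0.12, syllable_bias=0.25,
    ),
    "old": EffectVector(
        activity=-0.09, hut=0.08, habituation=-0.25, acclimation=0.10,
        sap=0.06, window=-0.05, sociability=-0.15, syllable_bias=0.60,
    ),
    "aged": EffectVector(
        activity=-0.10, hut=0.09, habituation=-0.22, acclimation=0.10,
        sap=0.06, window=-0.05, sociability=-0.15, syllable_bias=0.50,
    ),
}

#: residual fraction of the AD effect left after chronic treatment
_TREATMENT_RESIDUAL = {"none": 1.0, "csa": 0.10, "neb": 0.45, "cab": 0.55}


def design_effects(genotype: str, age: str, treatment: str) -> EffectVector:
    """Planted effect vector for one cell of the experimental design."""
    eff = _AGE_EFFECTS[age]
    if genotype == "AD":
        eff = eff + _AD_EFFECTS[age].scaled(_TREATMENT_RESIDUAL[treatment])
    return eff


def make_group(genotype: str, age: str, treatment: str = "none") -> GroupSpec:
    return GroupSpec(genotype, age, treatment, design_effects(genotype, age, treatment))


@dataclass(frozen=True)
class SimConfig:
    """Global simulation settings."""

    n_mice_per_group: int = 8
    seed: int = 0
    frame_interval: float = 1.0
    image_height: int = 640
    image_width: int = 960
    likelihood_noise: float = 0.10
    keypoint_jitter_px: float = 0.0
    mouse_effect_sd: float = 0.02
    time_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.likelihood_noise <= 1.0:
            raise ValueError("likelihood_noise must lie in [0, 1]")
        if self.n_mice_per_group < 1:
            raise ValueError("n_mice_per_group must be positive")


def make_schedule(config: SimConfig | None = None) -> AssaySchedule:
    """The assay schedule implied by a configuration (canonical 22 h at
    full scale)."""
    config = config or SimConfig()
    return AssaySchedule.scaled(config.time_scale, frame_interval=config.frame_interval)


# ---------------------------------------------------------------------------
# resolved behavioral state
# ---------------------------------------------------------------------------


@dataclass
class BehaviorState:
    """Per-group behavior-state parameters after applying effects.

    Fractions are of frames unless stated otherwise.
    """

    move_day: float = 0.22        # moving share of frames during daytime
    move_night: float = 0.45
    accl_start: float = 0.65      # moving share in the first 10-min bin
    sap_start: float = 0.18       # SAP share of frames in the first bin
    sap_base: float = 0.05
    hut_day: float = 0.50         # in-hut share of frames
    hut_night: float = 0.20
    window_frac: float = 0.10     # near-window share of frames
    peek_frac: float = 0.15       # peeking share of in-hut frames
    post_stim_move: float = 0.55  # moving share in the 10 min after a stimulus
    sociability: float = 0.50     # partner co-occurrence at the window
    scoot_mix: float = 0.45       # composition of moving frames
    walk_mix: float = 0.35
    burst_mix: float = 0.14
    escape_mix: float = 0.06
    syllable_bias: float = 0.0


def resolve_state(group: GroupSpec, rng: np.random.Generator | None = None,
                  mouse_sd: float = 0.0) -> BehaviorState:
    """Baseline state plus the group's planted offsets (plus optional
    per-mouse Gaussian jitter on the offsets)."""
    eff = group.effects
    if rng is not None and mouse_sd > 0:
        jitter = {k: rng.normal(0.0, mouse_sd) for k in vars(eff)}
        eff = eff + EffectVector(**jitter)
    s = BehaviorState()
    s.move_day = _clip_frac(s.move_day + eff.activity)
    s.move_night = _clip_frac(s.move_night + eff.activity)
    s.accl_start = _clip_frac(s.accl_start + eff.activity + eff.acclimation)
    s.sap_start = _clip_frac(s.sap_start + eff.sap)
    s.sap_base = _clip_frac(s.sap_base + 0.5 * eff.sap)
    s.hut_day = _clip_frac(s.hut_day + eff.hut)
    s.hut_night = _clip_frac(s.hut_night + eff.hut)
    s.window_frac = _clip_frac(s.window_frac + eff.window)
    s.post_stim_move = _clip_frac(s.post_stim_move + eff.habituation)
    s.sociability = _clip_frac(s.sociability + eff.sociability)
    s.syllable_bias = float(np.clip(s.syllable_bias + eff.syllable_bias, 0.0, 1.0))
    return s


def _clip_frac(x: float) -> float:
    return float(np.clip(x, 0.01, 0.90))


# ---------------------------------------------------------------------------
# pose-track generator
# ---------------------------------------------------------------------------


def simulate_pose_track(
    group: GroupSpec,
    schedule: AssaySchedule,
    geometry: CageGeometry | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
    state: BehaviorState | None = None,
    window_anchor: dict[int, tuple[int, int]] | None = None,
) -> PoseTrack:
    """Generate one mouse's full-assay pose track with ground truth.

    ``window_anchor`` maps 1-based period ids to (absolute start frame,
    length) window visits that this track must cover — used to plant
    partner co-occurrence.  The returned track carries a ``truth`` dict
    with per-frame in_hut/at_window/peek/sap/motion arrays, realized
    speeds, the resolved :class:`BehaviorState`, and the per-period
    window blocks.
    """
    config = config or SimConfig()
    geometry = geometry or default_geometry()
    if geometry.width < 3 * BODY_LENGTH_PX / 2 or geometry.height < 3 * BODY_LENGTH_PX / 2:
        raise ValueError("cage geometry smaller than the mouse template")
    state = state or resolve_state(group)
    rng = np.random.default_rng(seed)

    n = schedule.n_frames
    dt = schedule.frame_interval
    n_per_f = schedule.period_length / dt
    n_per = round(n_per_f)
    if abs(n_per_f - n_per) > 1e-9:
        raise ValueError("frame_interval must divide the period length")
    if n_per < 4:
        raise ValueError("period too short for the frame interval")

    in_hut = np.zeros(n, bool)
    at_window = np.zeros(n, bool)
    peek = np.zeros(n, bool)
    sap = np.zeros(n, bool)
    intended = np.zeros(n, np.int8)  # motion-state code, 0 = still
    window_blocks: dict[int, tuple[int, int]] = {}

    onset_starts = {
        round(schedule.onset_of(lab) / schedule.period_length) + 1
        for lab, _ in schedule.stimulus_onsets
    }

    mix = np.array([state.scoot_mix, state.walk_mix, state.burst_mix, state.escape_mix])
    mix = mix / mix.sum()

    for p in range(1, schedule.n_periods + 1):
        base = (p - 1) * n_per
        start_s, _ = schedule.period_window(p)
        phase = schedule.phase_at(start_s)
        day = phase.startswith("day")

        # planted per-period fractions
        if p <= 6:  # the six 10-min bins of hour 1: linear acclimation
            frac = (p - 1) / 5.0
            m = state.accl_start + frac * (state.move_day - state.accl_start)
            sap_frac = state.sap_start + frac * (state.sap_base - state.sap_start)
            h = 0.5 * state.hut_day
        elif p in onset_starts:
            m = state.post_stim_move
            sap_frac = state.sap_base
            h = 0.05
        else:
            m = state.move_day if day else state.move_night
            sap_frac = state.sap_base
            h = state.hut_day if day else state.hut_night

        n_hut = round(h * n_per)
        n_win = round(state.window_frac * n_per)

        # window block (possibly anchored for partner co-occurrence)
        taken = np.zeros(n_per, bool)
        if window_anchor is not None and p in window_anchor:
            a_start, a_len = window_anchor[p]
            a0 = min(max(a_start - base, 0), n_per)
            a1 = min(a0 + a_len, n_per)
            taken[a0:a1] = True
            extra = max(n_win - (a1 - a0), 0)
            # own surplus window time goes strictly outside the anchor
            lo = max(a0 - extra, 0)
            taken[lo:a0] = True
            still_extra = extra - (a0 - lo)
            if still_extra > 0:
                taken[a1 : min(a1 + still_extra, n_per)] = True
        elif n_win > 0:
            w0 = int(rng.integers(0, n_per - n_win + 1))
            taken[w0 : w0 + n_win] = True
        win_idx = np.flatnonzero(taken)
        at_window[base + win_idx] = True
        if len(win_idx):
            window_blocks[p] = (base + int(win_idx[0]), int(len(win_idx)))

        # hut block: a time-contiguous run of the remaining frames
        free = np.flatnonzero(~taken)
        n_hut = min(n_hut, len(free))
        if n_hut > 0:
            hut_idx = _contiguous_subset(free, n_hut, rng)
            in_hut[base + hut_idx] = True
            n_peek = round(state.peek_frac * n_hut)
            peek[base + hut_idx[:n_peek]] = True
            free = np.setdiff1d(free, hut_idx)

        # moving frames among the remaining rest frames
        n_move = min(round(m * n_per), len(free))
        if n_move > 0:
            move_idx = rng.choice(free, size=n_move, replace=False)
            counts = _mix_counts(n_move, mix)
            codes = np.repeat(np.arange(1, 5), counts)
            rng.shuffle(codes)
            intended[base + move_idx] = codes
        still_idx = np.setdiff1d(free, intended[base : base + n_per].nonzero()[0])
        n_sap = min(round(sap_frac * n_per), len(still_idx))
        if n_sap > 0:
            sap_idx = rng.choice(still_idx, size=n_sap, replace=False)
            sap[base + sap_idx] = True

    # -- position integration ----------------------------------------------
    pos, heading = _integrate_positions(
        in_hut, at_window, peek, intended, geometry, dt, rng
    )

    # realized kinematics (teleports at segment boundaries make a handful
    # of frames differ from the intended state; truth reports realization)
    disp = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    speed = np.full(n, np.nan)
    speed[:-1] = disp / dt

    body_length = np.where(sap, BODY_LENGTH_SAP_PX, BODY_LENGTH_PX)

    coords = {}
    u = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    nvec = np.stack([-np.sin(heading), np.cos(heading)], axis=1)
    for part, (along, lateral) in _PART_LAYOUT.items():
        xy = pos + u * (along * body_length)[:, None] + nvec * lateral
        if config.keypoint_jitter_px > 0 and part != "center":
            xy = xy + rng.normal(0.0, config.keypoint_jitter_px, xy.shape)
        xy[:, 0] = np.clip(xy[:, 0], 0.0, geometry.width - 1e-6)
        xy[:, 1] = np.clip(xy[:, 1], 0.0, geometry.height - 1e-6)
        coords[part] = xy
    # the center part is the integrated position itself (not clipped)
    coords["center"] = pos.copy()

    likelihoods = {}
    for part in BODY_PARTS:
        low = rng.random(n) < config.likelihood_noise
        lik = rng.uniform(0.95, 1.0, n)
        lik[low] = rng.uniform(0.30, 0.895, low.sum())
        likelihoods[part] = lik

    truth = {
        "group": group,
        "state": state,
        "in_hut": in_hut,
        "at_window": at_window,
        "peek": peek,
        "sap": sap,
        "intended_state": intended,
        "speed": speed,
        "heading": heading,
        "body_length": body_length,
        "window_blocks": window_blocks,
    }
    return pose_from_arrays(schedule.frame_times(), coords, likelihoods, truth=truth)


def _contiguous_subset(free: np.ndarray, length: int, rng) -> np.ndarray:
    """A run of ``length`` consecutive frame indices within ``free``,
    preferring gaps large enough to hold it in one piece."""
    splits = np.flatnonzero(np.diff(free) > 1) + 1
    runs = np.split(free, splits)
    fitting = [r for r in runs if len(r) >= length]
    if fitting:
        run = fitting[int(rng.integers(0, len(fitting)))]
        off = int(rng.integers(0, len(run) - length + 1))
        return run[off : off + length]
    return free[:length]


def _mix_counts(total: int, mix: np.ndarray) -> np.ndarray:
    counts = np.floor(mix * total).astype(int)
    counts[0] += total - counts.sum()
    return counts


def _integrate_positions(in_hut, at_window, peek, intended, geometry, dt, rng):
    """Sequential roam with scheduled hut/window segments.

    Moving frames step by exactly state_speed * dt; heading is a
    persistent random walk steered toward the interior near walls so the
    step length (hence the speed class) is preserved.
    """
    n = len(in_hut)
    speeds = np.array([STATE_SPEEDS[s] for s in MOTION_STATES])
    hut_c = np.array([geometry.hut.centroid.x, geometry.hut.centroid.y])
    door, u_out = _hut_door(geometry)
    win_c = np.asarray(geometry.window_center, float)
    cage_c = np.array([geometry.width / 2.0, geometry.height / 2.0])
    margin = 25.0
    hx0, hy0, hx1, hy1 = geometry.hut.bounds
    avoid_r = geometry.window_radius + 5.0

    def _blocked(p):
        # roaming avoids the hut footprint and the window zone so that
        # hut/window occupancy stays a scheduled, recoverable quantity
        if hx0 - 4 <= p[0] <= hx1 + 4 and hy0 - 4 <= p[1] <= hy1 + 4:
            return True
        if (p[0] - win_c[0]) ** 2 + (p[1] - win_c[1]) ** 2 < avoid_r**2:
            return True
        return not (
            margin <= p[0] <= geometry.width - margin
            and margin <= p[1] <= geometry.height - margin
        )

    pos = np.empty((n, 2))
    heading = np.empty(n)
    cur = cage_c + rng.uniform(-20, 20, 2)
    ang = rng.uniform(0, 2 * np.pi)
    hut_anchor = hut_c.copy()
    win_anchor = win_c.copy()
    prev_hut = prev_win = False
    for i in range(n):
        if in_hut[i]:
            if not prev_hut:
                hut_anchor = hut_c + rng.uniform(-6, 6, 2)
            if peek[i]:
                body = BODY_LENGTH_PX
                cur = door - u_out * 0.2 * body
                ang = float(np.arctan2(u_out[1], u_out[0]))
            else:
                cur = hut_anchor
            prev_hut, prev_win = True, False
        elif at_window[i]:
            if not prev_win:
                r = rng.uniform(0, 0.45 * geometry.window_radius)
                th = rng.uniform(0, 2 * np.pi)
                win_anchor = win_c + r * np.array([np.cos(th), np.sin(th)])
                win_anchor[0] = np.clip(win_anchor[0], 2.0, geometry.width - 2.0)
                win_anchor[1] = np.clip(win_anchor[1], 2.0, geometry.height - 2.0)
            cur = win_anchor
            prev_hut, prev_win = False, True
        else:
            if prev_hut or prev_win or _blocked(cur):
                # re-entry from a hut/window segment: hop to open ground
                cur = cage_c + rng.uniform(-15, 15, 2)
            prev_hut = prev_win = False
        pos[i] = cur
        heading[i] = ang
        # frame i's motion state drives the displacement into frame i+1,
        # so measured speed[i] = |pos[i+1] - pos[i]| / dt matches the state
        code = intended[i]
        if code > 0 and not (in_hut[i] or at_window[i]):
            step = speeds[code] * dt
            ang += rng.normal(0.0, 0.5)
            nxt = cur + step * np.array([np.cos(ang), np.sin(ang)])
            if _blocked(nxt):
                to_c = cage_c - cur
                ang = float(np.arctan2(to_c[1], to_c[0])) + rng.normal(0.0, 0.3)
                nxt = cur + step * np.array([np.cos(ang), np.sin(ang)])
                if _blocked(nxt):
                    nxt = cage_c + rng.uniform(-15, 15, 2)
            cur = nxt
    return pos, heading


def _hut_door(geometry: CageGeometry):
    """Door point on the hut boundary facing the cage center, and the
    outward unit vector."""
    from shapely.geometry import Point
    from shapely.ops import nearest_points

    cage_c = Point(geometry.width / 2.0, geometry.height / 2.0)
    on_hut, _ = nearest_points(geometry.hut.exterior, cage_c)
    door = np.array([on_hut.x, on_hut.y])
    hut_c = np.array([geometry.hut.centroid.x, geometry.hut.centroid.y])
    u = door - hut_c
    u = u / np.linalg.norm(u)
    return door, u


def simulate_pair(
    group: GroupSpec,
    schedule: AssaySchedule,
    geometry: CageGeometry | None = None,
    seed: int = 0,
    config: SimConfig | None = None,
    partner_group: GroupSpec | None = None,
    co_rate: float | None = None,
    state: BehaviorState | None = None,
) -> tuple[PoseTrack, PoseTrack]:
    """A mouse plus its window partner in the neighbouring cage.

    The partner is an independent track except that its window visits
    are scheduled to overlap a fraction ``co_rate`` (default: the
    group's sociability parameter) of the focal mouse's window visits,
    so the planted co-occurrence is recoverable.
    """
    config = config or SimConfig()
    state = state or resolve_state(group)
    if co_rate is None:
        co_rate = state.sociability
    focal = simulate_pose_track(group, schedule, geometry, seed, config, state=state)
    anchors = {
        p: (start, round(co_rate * length))
        for p, (start, length) in focal.truth["window_blocks"].items()
    }
    partner = simulate_pose_track(
        partner_group or group,
        schedule,
        geometry,
        seed + 104729,
        config,
        window_anchor=anchors,
    )
    return focal, partner


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

DAY_BG = np.array([255, 255, 255], np.uint8)
NIGHT_BG = np.array([235, 40, 40], np.uint8)
MOUSE_COLOR = np.array([45, 45, 45], np.uint8)
HUT_COLOR = np.array([150, 30, 30], np.uint8)
BLOB_HALF_WIDTH_PX = 10.0


def render_frame(
    center: np.ndarray,
    heading: float,
    body_length: float,
    hidden: bool,
    phase: str,
    geometry: CageGeometry,
) -> np.ndarray:
    """One per-cage frame: background by phase, hut, and the mouse blob
    (omitted when the mouse is inside the hut)."""
    from skimage.draw import ellipse, polygon as draw_polygon

    h, w = geometry.height, geometry.width
    bg = DAY_BG if phase.startswith("day") else NIGHT_BG
    frame = np.empty((h, w, 3), np.uint8)
    frame[:] = bg
    hx, hy = geometry.hut.exterior.xy
    rr, cc = draw_polygon(np.array(hy), np.array(hx), shape=(h, w))
    frame[rr, cc] = HUT_COLOR
    if not hidden:
        a = 0.55 * body_length            # semi-major (along the body axis)
        b = BLOB_HALF_WIDTH_PX            # semi-minor
        rr, cc = ellipse(
            center[1], center[0], b, a, shape=(h, w), rotation=-heading
        )
        frame[rr, cc] = MOUSE_COLOR
    return frame


def iter_frames(
    track: PoseTrack, geometry: CageGeometry, schedule: AssaySchedule
) -> Iterator[np.ndarray]:
    """Render the assay as a frame sequence (one frame per pose sample)."""
    nose = track.xy("nose")
    tail = track.xy("tail base")
    center = track.xy("center")
    if track.truth is not None:
        hidden = track.truth["in_hut"]
    else:
        hidden = geometry.in_hut_mask(center)
    axis = nose - tail
    heading = np.arctan2(axis[:, 1], axis[:, 0])
    length = np.linalg.norm(axis, axis=1)
    for i in range(track.n_frames):
        phase = schedule.phase_at(min(track.time_s[i], schedule.total_duration - 1e-9))
        yield render_frame(center[i], heading[i], length[i], bool(hidden[i]), phase,
                           geometry)


def simulate_frames(
    track: PoseTrack, geometry: CageGeometry, schedule: AssaySchedule
) -> np.ndarray:
    """Materialize the rendered frame sequence as an (n, H, W, 3) array.

    Intended for short (scaled) assays; use :func:`iter_frames` to
    stream a full-scale one.
    """
    return np.stack(list(iter_frames(track, geometry, schedule)))


# ---------------------------------------------------------------------------
# syllable-sequence generator
# ---------------------------------------------------------------------------


def simulate_syllables(
    transition: np.ndarray,
    mean_durations: np.ndarray,
    schedule: AssaySchedule,
    seed: int = 0,
    alphabet: tuple[int, ...] = SYLLABLE_IDS,
    start_state: int | None = None,
) -> SyllableSequence:
    """Semi-Markov syllable sequence: geometric bout lengths around
    ``mean_durations`` (seconds), label switches by ``transition``."""
    transition = np.asarray(transition, float)
    k = len(alphabet)
    if transition.shape != (k, k):
        raise ValueError(f"transition must be {k} x {k}")
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    if (transition < -1e-12).any():
        raise ValueError("transition entries must be non-negative")
    mean_durations = np.broadcast_to(np.asarray(mean_durations, float), (k,))
    if (mean_durations <= 0).any():
        raise ValueError("mean durations must be positive")

    rng = np.random.default_rng(seed)
    n = schedule.n_frames
    dt = schedule.frame_interval
    mean_frames = np.maximum(mean_durations / dt, 1.0)

    labels = np.empty(n, int)
    idx = (
        alphabet.index(start_state)
        if start_state is not None
        else int(rng.integers(0, k))
    )
    t = 0
    while t < n:
        length = int(rng.geometric(1.0 / mean_frames[idx]))
        labels[t : t + length] = alphabet[idx]
        t += length
        idx = int(rng.choice(k, p=transition[idx]))
    return SyllableSequence(schedule.frame_times(), labels, tuple(alphabet))


#: rough locomotor-intensity score per syllable, used to bias usage
_ACTIVITY_SCORE = {
    sid: (
        1.0 if "burst" in lab or lab in ("loop", "rear_fast")
        else 0.7 if lab.startswith(("rear", "turn", "stretch")) or lab == "food"
        else 0.4 if "groom" in lab or lab == "look"
        else 0.05
    )
    for sid, lab in SYLLABLE_LABELS.items()
}


def group_transition(
    state: BehaviorState | float, alphabet: tuple[int, ...] = SYLLABLE_IDS
) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix and mean durations for a group.

    ``syllable_bias`` in [0, 1] narrows the repertoire toward
    low-activity syllables (usage concentrates, active syllables become
    rare) and lengthens inactive bouts — emulating the reduced
    behavioral repertoire of the impaired, aged model animals.
    """
    bias = state if isinstance(state, (int, float)) else state.syllable_bias
    scores = np.array([_ACTIVITY_SCORE[s] for s in alphabet])
    weights = np.exp(-4.0 * bias * scores)
    k = len(alphabet)
    trans = np.tile(weights, (k, 1))
    np.fill_diagonal(trans, 0.0)
    trans = trans / trans.sum(axis=1, keepdims=True)
    # fixed per-syllable base durations spanning the 2-4 s range
    base = 2.0 + 2.0 * (np.arange(k) % 7) / 6.0
    durations = base * (1.0 + bias * (1.0 - scores))
    return trans, durations


# ---------------------------------------------------------------------------
# footfall-log generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrintSpec:
    """Per-print geometry/intensity targets (arbitrary distance units)."""

    print_length: float = 0.80
    toe_spread: float = 1.20
    intermediate_toe_spread: float = 0.60
    print_area: float = 0.50
    max_contact_area: float = 0.65
    mean_intensity: float = 120.0
    min_intensity: float = 80.0
    print_orientation: float = 5.0
    jitter: float = 0.0           # relative sd applied to each field
    base_of_support_front: float = 1.6
    base_of_support_hind: float = 2.4
    duty_factor: float = 0.55     # stand as a fraction of the step cycle


def simulate_footfalls(
    pattern: str,
    n_steps: int,
    run_speed: float,
    print_spec: PrintSpec | None = None,
    seed: int = 0,
    step_length: float = 5.0,
) -> gait_mod.GaitRun:
    """Footfall log of one walkway crossing.

    ``pattern`` is one of the six normal step-sequence patterns
    (Ca/Cb/Aa/Ab/Ra/Rb) or "random"; paw ids cycle in that order.  The
    animal advances at ``run_speed`` (distance units per second) with a
    stride of ``step_length`` per full 4-step cycle.
    """
    if n_steps < 4:
        raise ValueError("n_steps must be at least 4")
    if pattern != "random" and pattern not in gait_mod.NSSP_PATTERNS:
        raise ValueError(
            f"unknown pattern {pattern!r}; use one of "
            f"{tuple(gait_mod.NSSP_PATTERNS)} or 'random'"
        )
    spec = print_spec or PrintSpec()
    rng = np.random.default_rng(seed)

    if pattern == "random":
        paw_seq = [gait_mod.PAWS[i] for i in rng.integers(0, 4, n_steps)]
    else:
        cycle = gait_mod.NSSP_PATTERNS[pattern]
        paw_seq = [cycle[i % 4] for i in range(n_steps)]

    # one full cycle covers step_length at run_speed -> inter-step time
    tau = step_length / run_speed / 4.0
    cycle_time = 4.0 * tau
    stand = spec.duty_factor * cycle_time

    events = []
    for i, paw in enumerate(paw_seq):
        t0 = i * tau
        x = run_speed * t0
        half = (
            spec.base_of_support_front if paw in gait_mod.FRONT
            else spec.base_of_support_hind
        ) / 2.0
        y = half if paw.startswith("R") else -half
        vals = {}
        for name in (
            "print_length",
            "toe_spread",
            "intermediate_toe_spread",
            "print_area",
            "max_contact_area",
            "mean_intensity",
            "min_intensity",
            "print_orientation",
        ):
            target = getattr(spec, name)
            vals[name] = target * (1.0 + spec.jitter * rng.normal()) if spec.jitter else target
        vals["min_intensity"] = min(vals["min_intensity"], vals["mean_intensity"])
        if paw in gait_mod.HIND:
            pass  # toe spread is a hind-paw measure but is logged for all paws
        events.append(
            gait_mod.FootfallEvent(
                paw=paw,
                contact_start_s=t0,
                contact_end_s=t0 + stand,
                x=x,
                y=y,
                **vals,
            )
        )
    return gait_mod.GaitRun(events=events, direction=1)


def simulate_gait_runs(
    group: GroupSpec, n_runs: int = 3, seed: int = 0
) -> list[gait_mod.GaitRun]:
    """Compliant runs for one animal with group-dependent gait.

    The AD genotype takes fewer steps and breaks the normal step
    sequence more often; old animals bear more weight on the hind paws
    (higher intensities, wider hind base of support).
    """
    rng = np.random.default_rng(seed)
    ad = group.genotype == "AD"
    residual = _TREATMENT_RESIDUAL[group.treatment] if ad else 0.0
    old = group.age != "young"

    n_steps = max(8, int(rng.normal(16 - 3 * residual - (2 if old else 0), 1.0)))
    purity = 0.95 - 0.35 * residual - (0.10 if old else 0.0)
    spec = PrintSpec(
        jitter=0.05,
        mean_intensity=120.0 * (1.0 + (0.25 * residual if old else 0.0)),
        min_intensity=80.0 * (1.0 + (0.25 * residual if old else 0.0)),
        base_of_support_hind=2.4 * (1.0 + (0.20 * residual if old else 0.0)),
        print_length=0.80 * (1.0 - 0.10 * residual),
    )
    runs = []
    for r in range(n_runs):
        pat = "Aa" if rng.random() < purity else "random"
        speed = float(rng.uniform(15.0, 25.0))
        runs.append(
            simulate_footfalls(
                pat, n_steps, speed, print_spec=spec, seed=int(rng.integers(2**31))
            )
        )
    return runs
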