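"""End-to-end cohort pipeline: simulate -> parameters -> profiles.

Glues the generators to the parameter, syllable, gait and profile
stages for whole simulated cohorts.  The tracking-derived parameter
block of a simulated mouse is computed from the simulator's
ground-truth centroid track (the frame-rendering + segmentation stage
is verified against that same ground truth separately, on short
rendered assays, and would add nothing but runtime here).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior, gait, profiles, simulate, syllables
from .geometry import CageGeometry, default_geometry
from .pose import PoseTrack
from .schedule import AssaySchedule
from .simulate import (
    BLOB_HALF_WIDTH_PX,
    GroupSpec,
    SimConfig,
    group_transition,
    resolve_state,
    simulate_gait_runs,
    simulate_pair,
    simulate_syllables,
)
from .tracking import Track


def truth_track(pose: PoseTrack, geometry: CageGeometry) -> Track:
    """The centroid track implied by a simulated pose track's ground truth.

    Mirrors what frame rendering + segmentation recovers: the centroid
    is the center keypoint, elongation follows the rendered blob axes,
    and the mouse is missing (occluded) while inside the hut.
    """
    if pose.truth is None:
        raise ValueError("pose track carries no ground truth")
    n = pose.n_frames
    in_hut = pose.truth["in_hut"]
    centroid = pose.xy("center").copy()
    head = pose.xy("nose").copy()
    centroid[in_hut] = np.nan
    head[in_hut] = np.nan
    a = 0.55 * pose.truth["body_length"]
    elongation = np.where(in_hut, np.nan, a / BLOB_HALF_WIDTH_PX)
    area = np.where(in_hut, np.nan, np.pi * a * BLOB_HALF_WIDTH_PX)
    quadrant = np.full(n, -1, dtype=np.int8)
    visible = ~in_hut
    if visible.any():
        quadrant[visible] = geometry.quadrant_codes(centroid[visible])
    from .geometry import QUADRANT_LABELS

    quadrant[in_hut] = QUADRANT_LABELS.index("home")
    return Track(
        time_s=pose.time_s,
        centroid=centroid,
        head=head,
        area=area,
        elongation=elongation,
        in_hut=in_hut.copy(),
        quadrant=quadrant,
    )


def mouse_parameter_row(
    pose: PoseTrack,
    partner: PoseTrack | None,
    geometry: CageGeometry,
    schedule: AssaySchedule,
    track: Track | None = None,
) -> pd.Series:
    """The 67 namespaced behavioral parameters for one mouse."""
    if track is None:
        track = truth_track(pose, geometry)
    return behavior.compute_param_vector(track, pose, partner, geometry, schedule)


def _derive_seed(*parts: int) -> int:
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    groups: list[GroupSpec],
    n_per_group: int = 8,
    seed: int = 0,
    config: SimConfig | None = None,
    schedule: AssaySchedule | None = None,
    geometry: CageGeometry | None = None,
    keep_tracks: bool = False,
) -> dict:
    """Simulate a full cohort and compute every parameter block.

    Returns a dict with per-mouse DataFrames: ``track_params`` (15),
    ``pose_params`` (52), ``syllable_params`` (58 f*/d* entries),
    ``labels`` (genotype/age/treatment/group), and the assembled
    ``profiles`` / ``group_profiles`` (125 columns each).
    """
    config = config or SimConfig()
    schedule = schedule or simulate.make_schedule(config)
    geometry = geometry or default_geometry()

    track_rows, pose_rows, syl_rows, label_rows = {}, {}, {}, {}
    tracks = {}
    for gi, group in enumerate(groups):
        for mi in range(n_per_group):
            mouse = f"{group.name}_m{mi + 1}"
            mouse_seed = _derive_seed(seed, gi, mi)
            rng = np.random.default_rng(mouse_seed)
            state = resolve_state(group, rng=rng, mouse_sd=config.mouse_effect_sd)
            focal, partner = simulate_pair(
                group, schedule, geometry, seed=mouse_seed, config=config, state=state
            )
            focal_f = behavior.filter_pose(focal)
            partner_f = behavior.filter_pose(partner)
            track = truth_track(focal, geometry)
            track_rows[mouse] = behavior.compute_track_params(track, geometry, schedule)
            pose_rows[mouse] = behavior.compute_pose_params(
                focal_f, partner_f, geometry, schedule
            )
            trans, durs = group_transition(state)
            seq = simulate_syllables(
                trans, durs, schedule, seed=_derive_seed(seed, gi, mi, 7)
            )
            syl_rows[mouse] = syllables.profile_entries(syllables.summarize(seq))
            label_rows[mouse] = {
                "genotype": group.genotype,
                "age": group.age,
                "treatment": group.treatment,
                "group": group.name,
            }
            if keep_tracks:
                tracks[mouse] = (focal, partner, track, seq)

    track_params = pd.DataFrame(track_rows).T
    pose_params = pd.DataFrame(pose_rows).T
    syllable_params = pd.DataFrame(syl_rows).T
    labels = pd.DataFrame(label_rows).T
    prof, group_prof, imputed = profiles.assemble_profiles(
        track_params, pose_params, syllable_params, labels["group"]
    )
    out = {
        "track_params": track_params,
        "pose_params": pose_params,
        "syllable_params": syllable_params,
        "labels": labels,
        "profiles": prof,
        "group_profiles": group_prof,
        "imputed": imputed,
    }
    if keep_tracks:
        out["tracks"] = tracks
    return out


def simulate_gait_cohort(
    groups: list[GroupSpec],
    n_per_group: int = 8,
    seed: int = 0,
    n_runs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal gait table plus labels for a simulated cohort."""
    runs_by_animal = {}
    label_rows = {}
    for gi, group in enumerate(groups):
        for mi in range(n_per_group):
            animal = f"{group.name}_m{mi + 1}"
            runs_by_animal[animal] = simulate_gait_runs(
                group, n_runs=n_runs, seed=_derive_seed(seed, 13, gi, mi)
            )
            label_rows[animal] = {
                "genotype": group.genotype,
                "age": group.age,
                "treatment": group.treatment,
                "group": group.name,
            }
    table, excluded = gait.gait_table(runs_by_animal)
    labels = pd.DataFrame(label_rows).T.loc[table.index]
    return table, labels
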