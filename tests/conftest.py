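import numpy as np
import pytest

import octocage as oc
from octocage import behavior, simulate


@pytest.fixture(scope="session")
def geometry():
    return oc.default_geometry()


@pytest.fixture(scope="session")
def schedule_full():
    return oc.AssaySchedule.canonical()


@pytest.fixture(scope="session")
def schedule_small():
    """1/60-scale assay: 22 min, 1320 frames, periods of 10 s."""
    return oc.AssaySchedule.scaled(1 / 60, frame_interval=1.0)


@pytest.fixture(scope="session")
def wt_group():
    return oc.make_group("WT", "young")


@pytest.fixture(scope="session")
def clean_config_small():
    return oc.SimConfig(time_scale=1 / 60, likelihood_noise=0.0)


@pytest.fixture(scope="session")
def small_assay(wt_group, schedule_small, geometry, clean_config_small):
    """A noiseless scaled assay rendered to frames and re-tracked; shared
    by the tracking tests (rendering dominates the cost)."""
    from octocage import pipeline, tracking

    pose = simulate.simulate_pose_track(
        wt_group, schedule_small, geometry, seed=7, config=clean_config_small
    )
    frames = simulate.simulate_frames(pose, geometry, schedule_small)
    track = tracking.track_video(frames, geometry, schedule_small, hut_dwell=1)
    truth = pipeline.truth_track(pose, geometry)
    return {"pose": pose, "frames": frames, "track": track, "truth": truth}


@pytest.fixture(scope="session")
def full_pair(wt_group, schedule_full, geometry):
    """Full-scale 22-h mouse + partner with default likelihood noise."""
    cfg = oc.SimConfig()
    focal, partner = simulate.simulate_pair(
        wt_group, schedule_full, geometry, seed=3, config=cfg
    )
    return behavior.filter_pose(focal), behavior.filter_pose(partner)


@pytest.fixture(scope="session")
def recovery_cohort(geometry):
    """Old-WT vs old-AD cohort (n = 8/group) at full scale, used by the
    planted-effect recovery checks."""
    from octocage import pipeline

    groups = [oc.make_group("WT", "old"), oc.make_group("AD", "old")]
    return pipeline.simulate_cohort(
        groups, n_per_group=8, seed=11, config=oc.SimConfig(), geometry=geometry
    )
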