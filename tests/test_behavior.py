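"""Unit and oracle-equivalence tests for the behavioral parameters.

The oracle is an independently coded, loop-based recount of every
parameter definition, evaluated on a scaled synthetic assay; the
vectorized implementations must agree value for value.
"""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

import octocage as oc
from octocage import behavior, simulate
from octocage.behavior import (
    POSE_PARAM_IDS,
    TRACK_PARAM_IDS,
    acclimation,
    classify_motion,
    compute_param_vector,
    compute_pose_params,
    compute_track_params,
    filter_pose,
    habituation,
    interval_percent,
    speed_series,
)
from octocage.pose import pose_from_arrays


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


class TestFilterPose:
    def test_all_high_likelihood_keeps_everything(self, wt_group, schedule_small,
                                                  geometry, clean_config_small):
        pose = simulate.simulate_pose_track(wt_group, schedule_small, geometry,
                                            seed=1, config=clean_config_small)
        filt = filter_pose(pose)
        assert all(filt.valid_mask(p).all() for p in oc.BODY_PARTS)

    def test_boundary_value_is_kept(self):
        n = 3
        coords = {p: np.zeros((n, 2)) for p in oc.BODY_PARTS}
        liks = {p: np.array([0.95, 0.89, 0.90]) for p in oc.BODY_PARTS}
        pose = pose_from_arrays(np.arange(n), coords, liks)
        filt = filter_pose(pose)
        assert list(filt.valid_mask("nose")) == [True, False, True]

    def test_planted_noise_fraction_removed(self, schedule_full, geometry):
        cfg = oc.SimConfig(likelihood_noise=0.10)
        pose = simulate.simulate_pose_track(oc.make_group("WT", "young"),
                                            schedule_full, geometry, seed=4,
                                            config=cfg)
        filt = filter_pose(pose)
        removed = np.mean([1 - filt.valid_mask(p).mean() for p in oc.BODY_PARTS])
        assert removed == pytest.approx(0.10, abs=0.005)

    def test_bad_threshold_rejected(self, full_pair):
        with pytest.raises(ValueError):
            full_pair[0].filtered(1.5)


class TestSpeedAndClasses:
    def test_static_point_zero_speed(self):
        xy = np.tile([5.0, 5.0], (10, 1))
        s = speed_series(xy, np.arange(10.0))
        assert np.nansum(s) == 0.0

    def test_five_pixel_step_is_five_px_per_s(self):
        xy = np.column_stack([np.arange(10.0) * 5.0, np.zeros(10)])
        s = speed_series(xy, np.arange(10.0))
        assert np.allclose(s[:-1], 5.0)

    def test_random_walk_mean_speed_matches_closed_form(self):
        """2-D Gaussian steps with per-axis sd s have mean step length
        s * sqrt(pi/2)."""
        rng = np.random.default_rng(0)
        sd = 3.0
        steps = rng.normal(0, sd, size=(200_000, 2))
        xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        s = speed_series(xy, np.arange(len(xy), dtype=float))
        expected = sd * math.sqrt(math.pi / 2.0)
        assert np.nanmean(s) == pytest.approx(expected, rel=0.01)

    def test_class_bins(self):
        codes = classify_motion(np.array([0.0, 1.9, 2.0, 9.9, 10.0, 50.0, 80.0]))
        assert list(codes) == [0, 0, 1, 1, 2, 3, 4]

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_motion(np.array([1.0]), thresholds=(2, 10, 5, 80))


class TestWindows:
    def test_interval_percent_simple_counts(self):
        t = np.arange(60.0)
        q = np.zeros(60, bool)
        q[:30] = True
        v = np.ones(60, bool)
        assert interval_percent(q, v, t, (0.0, 60.0)) == pytest.approx(50.0)
        assert interval_percent(v, v, t, (0.0, 60.0)) == 100.0

    def test_empty_denominator_is_nan(self):
        t = np.arange(10.0)
        v = np.zeros(10, bool)
        assert np.isnan(interval_percent(v, v, t, (0.0, 10.0)))

    def test_acclimation_last_minus_first_bin(self, schedule_small):
        n = schedule_small.n_frames
        t = schedule_small.frame_times()
        bin_len = schedule_small.hour_length / 6.0
        q = np.zeros(n, bool)
        q[t < bin_len] = True          # 100 % in the first bin, 0 in the last
        v = np.ones(n, bool)
        assert acclimation(q, v, t, schedule_small) == pytest.approx(-100.0)
        assert acclimation(v, v, t, schedule_small) == pytest.approx(0.0)

    def test_habituation_window_is_one_period(self, schedule_small):
        n = schedule_small.n_frames
        t = schedule_small.frame_times()
        onset = schedule_small.onset_of("moth")
        q = (t >= onset) & (t < onset + schedule_small.period_length / 2.0)
        v = np.ones(n, bool)
        assert habituation(q, v, t, schedule_small, "moth") == pytest.approx(50.0)
        assert habituation(np.zeros(n, bool), v, t, schedule_small,
                           "lines2") == 0.0


class TestLocationParams:
    def test_always_at_window(self, geometry, schedule_small):
        n = 100
        wc = np.asarray(geometry.window_center)
        coords = {p: np.tile(wc, (n, 1)) for p in oc.BODY_PARTS}
        pose = pose_from_arrays(np.arange(n, dtype=float), coords)
        loc = behavior.location_params(pose, geometry)
        assert loc["Window"] == 100.0
        assert loc["DWindow"] == 0.0

    def test_peek_definition(self, geometry):
        n = 50
        door = np.array([geometry.hut.centroid.x, geometry.hut.bounds[3] - 2.0])
        outside = np.array([geometry.width / 2.0, geometry.height / 2.0])
        coords = {p: np.tile(door, (n, 1)) for p in oc.BODY_PARTS}
        coords["nose"] = np.tile(outside, (n, 1))
        pose = pose_from_arrays(np.arange(n, dtype=float), coords)
        loc = behavior.location_params(pose, geometry)
        assert loc["Home"] == 100.0
        assert loc["Peek"] == 100.0

    def test_uniform_positions_mean_wall_distance_closed_form(self):
        """For uniform points in a w x h rectangle the expected distance
        to the nearest edge has a closed form; Monte-Carlo agrees."""
        w, h = 240.0, 320.0
        geom = oc.default_geometry(int(w), int(h))
        rng = np.random.default_rng(1)
        n = 200_000
        pts = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
        got = geom.wall_distance(pts).mean()
        # E[min dist] for a rectangle: a^2 (3b - a) / (6 b) with a = min/2 side
        a, b = min(w, h), max(w, h)
        expected = a**2 * (3 * b - a) / (12.0 * a * b)  # = a(3b-a)/(12b)
        assert got == pytest.approx(expected, rel=0.01)

    def test_partner_never_at_window(self, geometry):
        n = 60
        wc = np.asarray(geometry.window_center)
        far = np.array([geometry.width - 5.0, 5.0])
        a = pose_from_arrays(np.arange(n, dtype=float),
                             {p: np.tile(wc, (n, 1)) for p in oc.BODY_PARTS})
        b = pose_from_arrays(np.arange(n, dtype=float),
                             {p: np.tile(far, (n, 1)) for p in oc.BODY_PARTS})
        wp = behavior.window_partner(a, b, geometry)
        assert wp["Window Partner"] == 0.0

    def test_synchronized_visits_100(self, geometry):
        n = 60
        wc = np.asarray(geometry.window_center)
        a = pose_from_arrays(np.arange(n, dtype=float),
                             {p: np.tile(wc, (n, 1)) for p in oc.BODY_PARTS})
        wp = behavior.window_partner(a, a, geometry)
        assert wp["Window Partner"] == 100.0

    def test_grid_mismatch_rejected(self, geometry):
        a = pose_from_arrays(np.arange(10, dtype=float),
                             {p: np.zeros((10, 2)) for p in oc.BODY_PARTS})
        b = pose_from_arrays(np.arange(9, dtype=float),
                             {p: np.zeros((9, 2)) for p in oc.BODY_PARTS})
        with pytest.raises(ValueError):
            behavior.window_partner(a, b, geometry)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


def _naive_speed(xy, valid, dt):
    n = len(xy)
    out = [float("nan")] * n
    for t in range(n - 1):
        if valid[t] and valid[t + 1]:
            dx = xy[t + 1][0] - xy[t][0]
            dy = xy[t + 1][1] - xy[t][1]
            out[t] = math.hypot(dx, dy) / dt
    return out


def _naive_percent(flags, valid, times, windows):
    num = den = 0
    for t, f, v in zip(times, flags, valid):
        if any(lo <= t < hi for lo, hi in windows) and v:
            den += 1
            if f:
                num += 1
    return float("nan") if den == 0 else 100.0 * num / den


def _naive_mean(values, times, windows):
    vals = [v for t, v in zip(times, values)
            if any(lo <= t < hi for lo, hi in windows) and not math.isnan(v)]
    return float("nan") if not vals else sum(vals) / len(vals)


def _close(a, b):
    if isinstance(a, float) and math.isnan(a):
        return isinstance(b, float) and math.isnan(b) or np.isnan(b)
    return a == pytest.approx(b, abs=1e-8)


@pytest.fixture(scope="module")
def oracle_assay(geometry):
    """A scaled assay with likelihood noise, plus its partner track."""
    sched = oc.AssaySchedule.scaled(1 / 60, frame_interval=1.0)
    cfg = oc.SimConfig(time_scale=1 / 60, likelihood_noise=0.10)
    focal, partner = simulate.simulate_pair(
        oc.make_group("AD", "old"), sched, geometry, seed=17, config=cfg
    )
    return sched, filter_pose(focal), filter_pose(partner)


class TestPoseOracle:
    def test_every_pose_parameter_matches_naive_recount(self, oracle_assay,
                                                        geometry):
        sched, pose, partner = oracle_assay
        got = compute_pose_params(pose, partner, geometry, sched)

        t = list(pose.time_s)
        dt = sched.frame_interval
        center = pose.xy("center")
        cvalid = list(pose.valid_mask("center"))
        speed = _naive_speed(center, cvalid, dt)
        codes = []
        for s in speed:
            if math.isnan(s):
                codes.append(-1)
            elif s < 2:
                codes.append(0)
            elif s < 10:
                codes.append(1)
            elif s < 40:
                codes.append(2)
            elif s < 80:
                codes.append(3)
            else:
                codes.append(4)
        valid = [c >= 0 for c in codes]
        fam = {
            "M": [c >= 1 for c in codes],
            "Sc": [c == 1 for c in codes],
            "B": [c == 3 for c in codes],
            "E": [c == 4 for c in codes],
        }
        hour = sched.hour_length
        windows = {
            "1": [(0.0, hour)],
            "D": sched.daytime,
            "7": [(6 * hour, 7 * hour)],
            "N": sched.nighttime,
        }
        expected = {}
        for pre, ids in (("M", ("M1", "MD", "M7", "MN", "MN-D")),
                         ("Sc", ("Scl", "ScD", "Sc7", "ScN", "ScN-D")),
                         ("B", ("Bl", "BD", "B7", "BN", "BN-D")),
                         ("E", ("El", "ED", "E7", "EN", "EN-D"))):
            for key, win in zip(ids[:4], ("1", "D", "7", "N")):
                expected[key] = _naive_percent(fam[pre], valid, t, windows[win])
            expected[ids[4]] = expected[ids[3]] - expected[ids[1]]
        for key, win in zip(("Spl", "SpD", "Sp7", "SpN"), ("1", "D", "7", "N")):
            expected[key] = _naive_mean(speed, t, windows[win])
        expected["SpN-D"] = expected["SpN"] - expected["SpD"]

        bins = [(i * hour / 6.0, (i + 1) * hour / 6.0) for i in range(6)]
        for key, flags in (("AM", fam["M"]), ("ASc", fam["Sc"]),
                           ("AB", fam["B"]), ("AE", fam["E"])):
            expected[key] = (_naive_percent(flags, valid, t, [bins[5]])
                             - _naive_percent(flags, valid, t, [bins[0]]))
        expected["ASp"] = (_naive_mean(speed, t, [bins[5]])
                           - _naive_mean(speed, t, [bins[0]]))

        onsets = {"M": "moth", "L1": "lines1", "L2": "lines2"}
        for stag, stim in onsets.items():
            o = sched.onset_of(stim)
            win = [(o, o + sched.period_length)]
            expected[f"H{stag}M" if stag != "M" else "HMM"] = _naive_percent(
                fam["M"], valid, t, win
            )
            expected[f"H{stag}Sc" if stag != "M" else "HMSc"] = _naive_percent(
                fam["Sc"], valid, t, win
            )
            expected[f"H{stag}B" if stag != "M" else "HMB"] = _naive_percent(
                fam["B"], valid, t, win
            )
            expected[f"H{stag}E" if stag != "M" else "HME"] = _naive_percent(
                fam["E"], valid, t, win
            )
            expected[f"H{stag}Sp" if stag != "M" else "HMSp"] = _naive_mean(
                speed, t, win
            )

        # location family, counted with scalar shapely operations
        nose = pose.xy("nose")
        nvalid = list(pose.valid_mask("nose"))
        n_home = n_peek = n_win = n_valid = n_both = 0
        wall_d, food_d, win_d = [], [], []
        wc = Point(geometry.window_center)
        for i in range(len(t)):
            if not cvalid[i]:
                continue
            n_valid += 1
            p = Point(center[i])
            in_hut = geometry.hut.intersects(p)
            if in_hut:
                n_home += 1
            if nvalid[i]:
                n_both += 1
                if in_hut and not geometry.hut.intersects(Point(nose[i])):
                    n_peek += 1
            d = p.distance(wc)
            win_d.append(d)
            if d <= geometry.window_radius:
                n_win += 1
            from shapely.geometry import LineString

            wall_d.append(min(LineString(seg).distance(p)
                              for seg in geometry.wall_segments))
            food_d.append(min(Point(fp).distance(p)
                              for fp in geometry.food_points))
        expected["Home"] = 100.0 * n_home / n_valid
        expected["Peek"] = 100.0 * n_peek / n_both
        expected["Window"] = 100.0 * n_win / n_valid
        expected["Wall"] = sum(wall_d) / len(wall_d)
        expected["Food"] = sum(food_d) / len(food_d)
        expected["DWindow"] = sum(win_d) / len(win_d)

        pc = partner.xy("center")
        pvalid = list(partner.valid_mask("center"))
        num = den = 0
        for i in range(len(t)):
            if not (cvalid[i] and pvalid[i]):
                continue
            a_at = Point(center[i]).distance(wc) <= geometry.window_radius
            b_at = Point(pc[i]).distance(wc) <= geometry.window_radius
            if a_at:
                den += 1
                if b_at:
                    num += 1
        expected["Window Partner"] = (
            100.0 * num / den if den else float("nan")
        )

        for key in POSE_PARAM_IDS:
            assert _close(expected[key], got[key]), key

    def test_motion_class_shares_sum_to_100(self, oracle_assay, geometry):
        sched, pose, _ = oracle_assay
        speed = behavior.speed_series(pose.xy_valid("center"), pose.time_s)
        codes = classify_motion(speed)
        valid = codes >= 0
        total = sum(
            interval_percent(codes == c, valid, pose.time_s,
                             (0.0, sched.total_duration))
            for c in range(5)
        )
        assert total == pytest.approx(100.0)


class TestTrackOracle:
    def test_track_parameters_match_naive_recount(self, small_assay, geometry,
                                                  schedule_small):
        track = small_assay["track"]
        got = compute_track_params(track, geometry, schedule_small)
        sched = schedule_small
        t = list(track.time_s)
        xy = track.centroid
        valid_pos = [bool(np.isfinite(xy[i, 0])) for i in range(len(t))]
        speed = _naive_speed(xy, valid_pos, sched.frame_interval)
        valid = [not math.isnan(s) for s in speed]
        moving = [v and s >= 2.0 for v, s in zip(valid, speed)]
        hour = sched.hour_length
        windows = {"1": [(0.0, hour)], "D": sched.daytime,
                   "7": [(6 * hour, 7 * hour)], "N": sched.nighttime}
        assert _close(_naive_percent(moving, valid, t, windows["1"]), got["M1"])
        assert _close(_naive_percent(moving, valid, t, windows["D"]), got["MD"])
        assert _close(_naive_percent(moving, valid, t, windows["7"]), got["M7"])
        assert _close(_naive_percent(moving, valid, t, windows["N"]), got["MN"])
        assert _close(got["MN"] - got["MD"], got["N-D"])
        # occupancy: in-hut counts as home; denominator = known location
        counts = {"home": 0, "wall": 0, "food": 0, "window": 0}
        known = 0
        for i in range(len(t)):
            if track.in_hut[i]:
                counts["home"] += 1
                known += 1
            elif valid_pos[i]:
                counts[oc.geometry.QUADRANT_LABELS[track.quadrant[i]]] += 1
                known += 1
        for key, qid in (("Home", "home"), ("Wall", "wall"), ("Food", "food"),
                         ("Window", "window")):
            assert _close(100.0 * counts[qid] / known, got[key])
        assert _close(got["Wall"] + got["Window"], got["Out"])

    def test_vector_has_67_namespaced_entries(self, small_assay, geometry,
                                              schedule_small, full_pair):
        pose, partner = full_pair
        # track comes from the small assay; pose from the full one — only
        # the structural contract is under test here
        vec = compute_param_vector(small_assay["track"],
                                   *_resample(pose, partner, small_assay),
                                   geometry, schedule_small)
        assert len(vec) == 67
        assert sum(k.startswith("trk:") for k in vec.index) == 15
        assert sum(k.startswith("pose:") for k in vec.index) == 52


def _resample(pose, partner, small_assay):
    """Clip full-scale pose tracks onto the small assay's grid."""
    n = small_assay["track"].time_s.shape[0]
    import pandas as pd

    def clip(p):
        from octocage.pose import PoseTrack

        return PoseTrack(p.time_s[:n], p.data.iloc[:n].reset_index(drop=True),
                         valid={k: v[:n] for k, v in p.valid.items()},
                         truth=None)

    return clip(pose), clip(partner)


class TestInvariances:
    def test_translation_invariance_of_pose_params(self, oracle_assay, geometry):
        sched, pose, partner = oracle_assay
        base = compute_pose_params(pose, partner, geometry, sched)
        shifted = compute_pose_params(pose.translated(3.0, -2.0), partner,
                                      geometry, sched)
        # motion parameters are translation invariant; location parameters
        # reference the fixed cage geometry and are excluded
        motion = [k for k in POSE_PARAM_IDS
                  if k not in ("Home", "Peek", "Window", "Wall", "Food",
                               "DWindow", "Window Partner")]
        for k in motion:
            assert _close(base[k], shifted[k]), k

    def test_distance_params_scale_linearly(self, geometry):
        n = 200
        rng = np.random.default_rng(2)
        pts = np.column_stack([rng.uniform(20, 220, n), rng.uniform(20, 300, n)])
        coords = {p: pts.copy() for p in oc.BODY_PARTS}
        pose = pose_from_arrays(np.arange(n, dtype=float), coords)
        big = oc.default_geometry(geometry.width * 2, geometry.height * 2)
        coords2 = {p: pts * 2.0 for p in oc.BODY_PARTS}
        pose2 = pose_from_arrays(np.arange(n, dtype=float), coords2)
        a = behavior.location_params(pose, geometry)
        b = behavior.location_params(pose2, big)
        assert b["Wall"] == pytest.approx(2 * a["Wall"], rel=1e-9)
        assert b["DWindow"] == pytest.approx(2 * a["DWindow"], rel=1e-9)
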