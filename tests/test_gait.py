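import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octocage.gait import (
    NSSP_PATTERNS,
    PAWS,
    FootfallEvent,
    GaitRun,
    base_of_support,
    gait_table,
    paw_angle_body_axis,
    paw_timing,
    run_stats,
    step_sequence_nssp,
    support_percentages,
    validate_run,
)
from octocage.simulate import PrintSpec, simulate_footfalls


def _event(paw, start, dur=0.2, x=0.0, y=0.0, **kw):
    return FootfallEvent(paw, start, start + dur, x, y, **kw)


def _run(paw_seq, tau=0.25, dur=0.2, speed=10.0):
    events = [
        _event(p, i * tau, dur=dur, x=i * tau * speed,
               y=1.0 if p.startswith("R") else -1.0)
        for i, p in enumerate(paw_seq)
    ]
    return GaitRun(events)


class TestValidateRun:
    def test_fast_monotone_run_compliant(self):
        ok, reasons = validate_run(_run(["RF", "RH", "LF", "LH"] * 3))
        assert ok and not reasons

    def test_slow_run_rejected(self):
        ok, reasons = validate_run(_run(["RF", "RH", "LF", "LH"] * 3, tau=1.2))
        assert not ok
        assert any("duration" in r for r in reasons)

    def test_direction_reversal_rejected(self):
        events = [_event("RF", 0.0, x=0.0), _event("LF", 0.3, x=5.0),
                  _event("RH", 0.6, x=2.0), _event("LH", 0.9, x=7.0)]
        ok, reasons = validate_run(GaitRun(events))
        assert not ok
        assert any("one-directional" in r for r in reasons)

    def test_empty_run_raises(self):
        with pytest.raises(ValueError):
            validate_run(GaitRun([]))


class TestPawTiming:
    def test_textbook_contacts(self):
        run = GaitRun([_event("RF", 0.0, dur=0.2), _event("RF", 0.5, dur=0.2)])
        timing = paw_timing(run, "RF")
        assert timing["stand"] == pytest.approx(0.2)
        assert timing["step_cycle"] == pytest.approx(0.5)
        assert timing["swing"] == pytest.approx(0.3)

    def test_periodic_gait_cycle_exact(self):
        run = _run(["RF", "LF", "RH", "LH"] * 4, tau=0.25)
        assert paw_timing(run, "RF")["step_cycle"] == pytest.approx(1.0)

    def test_single_contact_undefined_cycle(self):
        run = GaitRun([_event("LH", 0.0)])
        assert math.isnan(paw_timing(run, "LH")["step_cycle"])

    def test_jittered_periods_match_brute_force(self):
        rng = np.random.default_rng(0)
        starts = np.cumsum(rng.uniform(0.2, 0.4, 10))
        run = GaitRun([_event("RF", float(s)) for s in starts])
        expected = float(np.diff(starts).mean())
        assert paw_timing(run, "RF")["step_cycle"] == pytest.approx(expected)


class TestRunStats:
    def test_cadence(self):
        run = _run(["RF", "RH", "LF", "LH"] * 3, tau=3.0 / 11.0)
        stats = run_stats(run)
        assert stats["number_of_steps"] == 12
        assert stats["duration"] == pytest.approx(3.0)
        assert stats["cadence"] == pytest.approx(4.0)

    def test_cadence_times_duration_is_step_count(self):
        run = simulate_footfalls("Ra", 17, 22.0, seed=1)
        stats = run_stats(run)
        assert stats["cadence"] * stats["duration"] == pytest.approx(
            stats["number_of_steps"]
        )

    def test_single_event_zero_duration_raises(self):
        with pytest.raises(ValueError):
            run_stats(GaitRun([_event("RF", 0.0)]))


class TestSupportPercentages:
    def test_all_four_down_whole_run(self):
        events = [FootfallEvent(p, 0.0, 1.0, 0.0, 0.0) for p in PAWS]
        pct = support_percentages(GaitRun(events))
        assert pct["four"] == pytest.approx(100.0)
        assert sum(v for k, v in pct.items() if k != "four") == pytest.approx(0.0)

    def test_alternating_diagonal_pairs(self):
        events = []
        for i in range(4):
            t = i * 1.0
            pair = ("RF", "LH") if i % 2 == 0 else ("LF", "RH")
            events += [FootfallEvent(p, t, t + 1.0, float(i), 0.0) for p in pair]
        pct = support_percentages(GaitRun(events))
        assert pct["diagonal"] == pytest.approx(100.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_random_log_matches_discretized_oracle(self, seed):
        rng = np.random.default_rng(seed)
        events = []
        for _ in range(rng.integers(4, 12)):
            paw = PAWS[rng.integers(0, 4)]
            start = round(float(rng.uniform(0, 3.0)), 3)
            dur = round(float(rng.uniform(0.05, 1.0)), 3)
            events.append(FootfallEvent(paw, start, start + dur, 0.0, 0.0))
        run = GaitRun(events)
        pct = support_percentages(run)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)
        # per-millisecond recount
        lo, hi = run.run_start_s, run.run_end_s
        ms = np.arange(lo + 0.0005, hi, 0.001)
        counts = dict.fromkeys(pct, 0)
        from octocage.gait import _support_category

        for t in ms:
            down = frozenset(e.paw for e in events
                             if e.contact_start_s <= t < e.contact_end_s)
            counts[_support_category(down)] += 1
        for cat in pct:
            assert pct[cat] == pytest.approx(100.0 * counts[cat] / len(ms),
                                             abs=0.2)

    def test_time_rescaling_invariance(self):
        events = [FootfallEvent(p, i * 0.2, i * 0.2 + 0.3, float(i), 0.0)
                  for i, p in enumerate(PAWS * 2)]
        base = support_percentages(GaitRun(events))
        scaled = support_percentages(GaitRun([
            FootfallEvent(e.paw, e.contact_start_s * 3, e.contact_end_s * 3,
                          e.x, e.y) for e in events
        ]))
        for cat in base:
            assert base[cat] == pytest.approx(scaled[cat], abs=1e-9)


class TestStepSequence:
    @pytest.mark.parametrize("pattern", sorted(NSSP_PATTERNS))
    def test_pure_pattern_cycles_score_100(self, pattern):
        run = simulate_footfalls(pattern, 12, 20.0)
        assert step_sequence_nssp(run) == 100.0

    def test_repeated_paw_scores_zero(self):
        run = _run(["RF"] * 8)
        assert step_sequence_nssp(run) == 0.0

    def test_too_few_steps_is_nan(self):
        assert math.isnan(step_sequence_nssp(_run(["RF", "LF", "RH"])))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_shuffled_sequence_matches_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = [PAWS[i] for i in rng.integers(0, 4, 20)]
        run = _run(seq)
        got = step_sequence_nssp(run)
        normal = 0
        windows = [tuple(seq[i:i + 4]) for i in range(len(seq) - 3)]
        for w in windows:
            # a window is normal iff it uses each paw exactly once (the six
            # patterns cover every cyclic order of the four paws)
            if len(set(w)) == 4:
                normal += 1
        assert got == pytest.approx(100.0 * normal / len(windows))


class TestBaseOfSupport:
    def test_fixed_separation(self):
        run = _run(["RH", "LH"] * 4)
        assert base_of_support(run, "hind") == pytest.approx(2.0)

    def test_identical_lateral_positions_zero(self):
        events = [_event(p, i * 0.2, y=0.0) for i, p in
                  enumerate(["RF", "LF"] * 3)]
        assert base_of_support(GaitRun(events), "front") == 0.0

    def test_missing_paw_is_nan(self):
        run = _run(["RH"] * 4)
        assert math.isnan(base_of_support(run, "hind"))

    def test_jittered_placements_match_pairing_average(self):
        rng = np.random.default_rng(4)
        events = []
        ys = []
        for i in range(10):
            paw = "RH" if i % 2 == 0 else "LH"
            y = float(rng.normal(1.0 if paw == "RH" else -1.0, 0.1))
            ys.append(y)
            events.append(_event(paw, i * 0.3, y=y))
        expected = np.mean([abs(a - b) for a, b in zip(ys[:-1], ys[1:])])
        assert base_of_support(GaitRun(events), "hind") == pytest.approx(expected)


class TestPawAngle:
    def test_print_aligned_with_travel_is_zero(self):
        run = _run(["RF", "LF", "RH", "LH"] * 3)
        for e in run.events:
            e.print_orientation = 0.0
        assert paw_angle_body_axis(run.events[4], run) == pytest.approx(0.0)

    def test_25_degree_print_on_straight_run(self):
        run = _run(["RF", "LF", "RH", "LH"] * 3)
        e = run.events[4]
        e.print_orientation = 25.0
        assert paw_angle_body_axis(e, run) == pytest.approx(25.0)

    def test_curved_run_matches_local_tangent(self):
        # quarter-circle path: the local tangent rotates along the run
        ts = np.linspace(0, 3, 13)
        events = []
        for i, t in enumerate(ts):
            ang = math.pi / 2 * t / 3.0
            x, y = 10 * math.sin(ang), 10 * (1 - math.cos(ang))
            events.append(_event(PAWS[i % 4], float(t), x=x, y=y,
                                 print_orientation=0.0))
        run = GaitRun(events)
        e = run.events[6]
        same = run.of_paw(e.paw)
        k = same.index(e)
        prev_e, next_e = same[k - 1], same[k + 1]
        tangent = math.degrees(math.atan2(next_e.y - prev_e.y,
                                          next_e.x - prev_e.x))
        expected = (0.0 - tangent + 90.0) % 180.0 - 90.0
        assert paw_angle_body_axis(e, run) == pytest.approx(expected)


class TestGaitTable:
    def test_three_identical_runs_equal_single_run(self):
        runs = [simulate_footfalls("Aa", 12, 20.0, seed=0) for _ in range(3)]
        table, excluded = gait_table({"m1": runs})
        from octocage.gait import run_parameters

        single = run_parameters(runs[0])
        row = table.loc["m1"]
        for key in single.index:
            if math.isnan(single[key]):
                assert math.isnan(row[key])
            else:
                assert row[key] == pytest.approx(single[key])

    def test_non_compliant_runs_excluded_from_average(self):
        good = [simulate_footfalls("Aa", 12, 20.0, seed=s) for s in range(3)]
        slow = simulate_footfalls("Aa", 12, run_speed=1.0, step_length=5.0)
        table_mixed, _ = gait_table({"m": good + [slow]})
        table_clean, _ = gait_table({"m": good})
        assert np.allclose(
            table_mixed.loc["m"].fillna(-1), table_clean.loc["m"].fillna(-1)
        )

    def test_animal_without_three_compliant_runs_excluded(self):
        slow = [simulate_footfalls("Aa", 12, run_speed=1.0, step_length=5.0)
                for _ in range(3)]
        table, excluded = gait_table({"m": slow})
        assert "m" not in table.index
        assert "m" in excluded

    def test_simulated_print_spec_recovered(self):
        spec = PrintSpec(print_length=0.9, jitter=0.02)
        runs = [simulate_footfalls("Aa", 20, 20.0, spec, seed=s)
                for s in range(5)]
        table, _ = gait_table({"m": runs}, min_compliant_runs=3)
        for paw in PAWS:
            assert table.loc["m", f"print_length_{paw}"] == pytest.approx(
                0.9, rel=0.05
            )

    def test_distance_params_scale_timing_invariant(self):
        run = simulate_footfalls("Aa", 12, 20.0)
        scaled = GaitRun([
            FootfallEvent(e.paw, e.contact_start_s, e.contact_end_s,
                          e.x * 2, e.y * 2, print_length=e.print_length)
            for e in run.events
        ])
        assert base_of_support(scaled, "hind") == pytest.approx(
            2 * base_of_support(run, "hind")
        )
        assert run_stats(scaled)["cadence"] == pytest.approx(
            run_stats(run)["cadence"]
        )
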