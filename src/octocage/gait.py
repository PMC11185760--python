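"""Walkway gait analysis from footfall event logs.

Input is the footfall log of one walkway crossing ("run"): one event per
paw contact with timing, position, print geometry and print intensity,
for the four paws RF/LF/RH/LH (right/left fore/hind).  From these logs
the module computes the standard gait parameter set: per-paw timing
(stand, step cycle, swing), run statistics (duration, cadence, number of
steps), support-category percentages, normal-step-sequence-pattern
share, base of support, and paw angle relative to the body axis.

Runs must be compliant — one-directional and faster than 10 s — to enter
the per-animal parameter table; non-compliant runs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PAWS = ("RF", "LF", "RH", "LH")
FRONT = ("RF", "LF")
HIND = ("RH", "LH")

#: the six normal step sequence patterns of healthy rodent gait
NSSP_PATTERNS: dict[str, tuple[str, str, str, str]] = {
    "Ca": ("RF", "LF", "RH", "LH"),  # cruciate
    "Cb": ("LF", "RF", "LH", "RH"),
    "Aa": ("RF", "RH", "LF", "LH"),  # alternate
    "Ab": ("LF", "RH", "RF", "LH"),
    "Ra": ("RF", "LF", "LH", "RH"),  # rotary
    "Rb": ("LF", "RF", "RH", "LH"),
}

#: every 4-step window matching a normal pattern under cyclic continuation
_NORMAL_WINDOWS = frozenset(
    tuple(np.roll(np.array(pat, dtype=object), -k))
    for pat in NSSP_PATTERNS.values()
    for k in range(4)
)

#: paw-pair support categories
_PAIR_CATEGORY = {
    frozenset({"RF", "LF"}): "girdle",
    frozenset({"RH", "LH"}): "girdle",
    frozenset({"RF", "RH"}): "lateral",
    frozenset({"LF", "LH"}): "lateral",
    frozenset({"RF", "LH"}): "diagonal",
    frozenset({"LF", "RH"}): "diagonal",
}

SUPPORT_CATEGORIES = ("zero", "single", "girdle", "lateral", "diagonal", "three", "four")

MAX_COMPLIANT_DURATION_S = 10.0


@dataclass
class FootfallEvent:
    """One paw contact with the walkway."""

    paw: str
    contact_start_s: float
    contact_end_s: float
    x: float                 # position along the direction of travel
    y: float                 # lateral position
    print_length: float = np.nan
    toe_spread: float = np.nan
    intermediate_toe_spread: float = np.nan
    print_area: float = np.nan
    max_contact_area: float = np.nan
    mean_intensity: float = np.nan
    min_intensity: float = np.nan
    print_orientation: float = np.nan   # degrees, relative to the walkway axis

    def __post_init__(self) -> None:
        if self.paw not in PAWS:
            raise ValueError(f"unknown paw {self.paw!r}")
        if not self.contact_end_s > self.contact_start_s:
            raise ValueError("contact_end_s must exceed contact_start_s")
        if np.isfinite(self.mean_intensity) and np.isfinite(self.min_intensity):
            if self.min_intensity > self.mean_intensity + 1e-9:
                raise ValueError("min intensity cannot exceed mean intensity")


@dataclass
class GaitRun:
    """Time-ordered footfall log of one walkway crossing."""

    events: list[FootfallEvent]
    direction: int = 1
    run_start_s: float | None = None
    run_end_s: float | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.contact_start_s)
        if self.run_start_s is None and self.events:
            self.run_start_s = self.events[0].contact_start_s
        if self.run_end_s is None and self.events:
            self.run_end_s = max(e.contact_end_s for e in self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_paw(self, paw: str) -> list[FootfallEvent]:
        return [e for e in self.events if e.paw == paw]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events])


def validate_run(run: GaitRun) -> tuple[bool, list[str]]:
    """Compliance check: one-directional progression in under 10 s."""
    if len(run) == 0:
        raise ValueError("empty run")
    reasons = []
    x = np.array([e.x for e in run.events])
    if len(x) > 1:
        dx = np.diff(x)
        if not ((dx >= 0).all() or (dx <= 0).all()):
            reasons.append("direction reversal (not one-directional)")
    duration = run.events[-1].contact_start_s - run.events[0].contact_start_s
    if duration >= MAX_COMPLIANT_DURATION_S:
        reasons.append(
            f"run duration {duration:.2f} s exceeds {MAX_COMPLIANT_DURATION_S:.0f} s"
        )
    return (not reasons), reasons


def paw_timing(run: GaitRun, paw: str) -> dict[str, float]:
    """stand, step_cycle and swing for one paw (seconds).

    stand is the mean contact duration; step_cycle the mean gap between
    consecutive initial contacts of the paw; swing their difference.
    step_cycle (and swing) are NaN with fewer than two contacts.
    """
    events = run.of_paw(paw)
    if not events:
        return {"stand": np.nan, "step_cycle": np.nan, "swing": np.nan}
    stand = float(np.mean([e.contact_end_s - e.contact_start_s for e in events]))
    if len(events) < 2:
        return {"stand": stand, "step_cycle": np.nan, "swing": np.nan}
    starts = np.array([e.contact_start_s for e in events])
    step_cycle = float(np.mean(np.diff(starts)))
    return {"stand": stand, "step_cycle": step_cycle, "swing": step_cycle - stand}


def run_stats(run: GaitRun, use_run_bounds: bool = False) -> dict[str, float]:
    """duration (s), number_of_steps, and cadence (steps/s).

    Duration spans the first to the last initial contact by default;
    ``use_run_bounds`` switches to the recorded run window.
    """
    if len(run) == 0:
        raise ValueError("empty run")
    if use_run_bounds:
        duration = run.run_end_s - run.run_start_s
    else:
        duration = run.events[-1].contact_start_s - run.events[0].contact_start_s
    if duration <= 0:
        raise ValueError("run duration is zero")
    n = len(run)
    return {"duration": float(duration), "number_of_steps": n, "cadence": n / duration}


def support_percentages(run: GaitRun) -> dict[str, float]:
    """Share of run time spent on each paw-combination support category.

    The run window is partitioned at every contact start/end; each
    elementary interval is classified by the set of paws in contact:
    zero, single, two-paw categories (girdle RF-LF/RH-LH, lateral
    RF-RH/LF-LH, diagonal RF-LH/LF-RH), three, or four.  Percentages sum
    to 100.
    """
    if len(run) == 0:
        raise ValueError("empty run")
    lo, hi = run.run_start_s, run.run_end_s
    cuts = {lo, hi}
    for e in run.events:
        cuts.add(min(max(e.contact_start_s, lo), hi))
        cuts.add(min(max(e.contact_end_s, lo), hi))
    cuts = sorted(cuts)
    totals = dict.fromkeys(SUPPORT_CATEGORIES, 0.0)
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        down = frozenset(
            e.paw for e in run.events if e.contact_start_s <= mid < e.contact_end_s
        )
        totals[_support_category(down)] += b - a
    span = hi - lo
    return {k: 100.0 * v / span for k, v in totals.items()}


def _support_category(down: frozenset) -> str:
    if len(down) == 0:
        return "zero"
    if len(down) == 1:
        return "single"
    if len(down) == 2:
        return _PAIR_CATEGORY[down]
    if len(down) == 3:
        return "three"
    return "four"


def step_sequence_nssp(run: GaitRun, duration_weighted: bool = False) -> float:
    """Percent of 4-step windows matching a normal step sequence pattern.

    The paw-order sequence is scanned in sliding windows of four
    consecutive steps; a window is normal when it matches one of the six
    patterns (cruciate Ca/Cb, alternate Aa/Ab, rotary Ra/Rb) under
    cyclic continuation.  ``duration_weighted`` weights each window by
    its time span instead of counting windows.  NaN with fewer than 4
    steps.
    """
    seq = [e.paw for e in run.events]
    if len(seq) < 4:
        return np.nan
    starts = np.array([e.contact_start_s for e in run.events])
    num = den = 0.0
    for i in range(len(seq) - 3):
        window = tuple(seq[i : i + 4])
        w = (starts[i + 3] - starts[i]) if duration_weighted else 1.0
        den += w
        if window in _NORMAL_WINDOWS:
            num += w
    return 100.0 * num / den


def base_of_support(run: GaitRun, pair: str) -> float:
    """Mean lateral width between successive left/right placements.

    ``pair`` is "front" (RF/LF) or "hind" (RH/LH).  Placements of the
    two paws are merged in time order and each adjacent left-right pair
    contributes its absolute lateral separation.  NaN when either paw is
    missing from the run.
    """
    paws = FRONT if pair == "front" else HIND if pair == "hind" else None
    if paws is None:
        raise ValueError("pair must be 'front' or 'hind'")
    events = [e for e in run.events if e.paw in paws]
    if not {e.paw for e in events} == set(paws):
        return np.nan
    seps = [
        abs(a.y - b.y)
        for a, b in zip(events[:-1], events[1:])
        if a.paw != b.paw
    ]
    if not seps:
        return np.nan
    return float(np.mean(seps))


def paw_angle_body_axis(event: FootfallEvent, run: GaitRun) -> float:
    """Signed acute angle (degrees) between a print and the body axis.

    The body axis is estimated as the local direction of travel at the
    event: the displacement between the neighbouring contacts of the
    same paw, falling back to the overall run direction.  The result is
    normalized to (-90, 90].
    """
    same = run.of_paw(event.paw)
    idx = same.index(event) if event in same else None
    axis = None
    if idx is not None and len(same) > 1:
        prev_e = same[idx - 1] if idx > 0 else same[idx]
        next_e = same[idx + 1] if idx < len(same) - 1 else same[idx]
        dx, dy = next_e.x - prev_e.x, next_e.y - prev_e.y
        if dx != 0 or dy != 0:
            axis = np.degrees(np.arctan2(dy, dx))
    if axis is None:
        first, last = run.events[0], run.events[-1]
        dx, dy = last.x - first.x, last.y - first.y
        if dx == 0 and dy == 0:
            axis = 0.0
        else:
            axis = np.degrees(np.arctan2(dy, dx))
    diff = event.print_orientation - axis
    diff = (diff + 90.0) % 180.0 - 90.0
    if diff == -90.0:
        diff = 90.0
    return float(diff)


def run_parameters(run: GaitRun) -> pd.Series:
    """All gait parameters of a single (compliant) run as a named series."""
    out: dict[str, float] = {}
    out.update(run_stats(run))
    out["nssp_percent"] = step_sequence_nssp(run)
    out["nssp_percent_weighted"] = step_sequence_nssp(run, duration_weighted=True)
    for cat, val in support_percentages(run).items():
        out[f"support_{cat}"] = val
    out["base_of_support_front"] = base_of_support(run, "front")
    out["base_of_support_hind"] = base_of_support(run, "hind")
    for paw in PAWS:
        timing = paw_timing(run, paw)
        out[f"stand_{paw}"] = timing["stand"]
        out[f"step_cycle_{paw}"] = timing["step_cycle"]
        out[f"swing_{paw}"] = timing["swing"]
        events = run.of_paw(paw)
        for attr in (
            "print_length",
            "toe_spread",
            "intermediate_toe_spread",
            "print_area",
            "max_contact_area",
            "mean_intensity",
            "min_intensity",
        ):
            vals = [getattr(e, attr) for e in events]
            out[f"{attr}_{paw}"] = float(np.nanmean(vals)) if vals else np.nan
        angles = [paw_angle_body_axis(e, run) for e in events if np.isfinite(e.print_orientation)]
        out[f"paw_angle_body_axis_{paw}"] = float(np.mean(angles)) if angles else np.nan
    return pd.Series(out)


def gait_table(
    runs_by_animal: dict[str, list[GaitRun]], min_compliant_runs: int = 3
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-animal gait parameter table averaged over compliant runs.

    Animals with fewer than ``min_compliant_runs`` compliant runs are
    excluded and reported in the second return value (animal ->
    exclusion reasons).
    """
    rows = {}
    excluded: dict[str, list[str]] = {}
    for animal, runs in runs_by_animal.items():
        compliant = []
        reasons_all = []
        for run in runs:
            ok, reasons = validate_run(run)
            if ok:
                compliant.append(run)
            else:
                reasons_all.extend(reasons)
        if len(compliant) < min_compliant_runs:
            excluded[animal] = reasons_all or ["insufficient compliant runs"]
            continue
        params = pd.DataFrame([run_parameters(r) for r in compliant])
        rows[animal] = params.mean(axis=0, skipna=True)
    table = pd.DataFrame(rows).T
    table.index.name = "animal"
    return table, excluded
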