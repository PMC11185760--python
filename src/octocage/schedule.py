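"""The 22-hour homecage assay timeline.

The assay presents each mouse with a scripted visual environment: a 6-h
daytime phase (white background), a 6-h nighttime phase (red background),
a 6-h nighttime phase during which three stimuli are shown (a rotating
moth and two sets of moving lines, 2 h apart), and a closing 4-h daytime
phase.  Time is discretized into 132 ten-minute *periods* (1-based); the
first stimulus onset coincides with the start of period 73.
"""

from __future__ import annotations

from dataclasses import dataclass

PHASE_LABELS = ("day1", "night1", "night_stim", "day2")
STIMULUS_LABELS = ("moth", "lines1", "lines2")

#: phase durations as multiples of one assay hour
_PHASE_HOURS = (6, 6, 6, 4)
#: stimulus onsets in elapsed assay hours (moth, lines1, lines2)
_ONSET_HOURS = (12, 14, 16)

HOUR = 3600.0
TOTAL_HOURS = 22


@dataclass(frozen=True)
class AssaySchedule:
    """Ordered day/night phases, stimulus onsets, and the 10-min period grid.

    Attributes
    ----------
    phases : tuple of (label, start_s, end_s)
        Contiguous, non-overlapping phases covering ``[0, total_duration)``.
    stimulus_onsets : tuple of (label, onset_s)
        The three stimulus presentations, inside the ``night_stim`` phase.
    period_length : float
        Length of one analysis period in seconds (600 s at full scale).
    frame_interval : float
        Sampling interval of the recording in seconds (1 s at full scale).
    """

    phases: tuple[tuple[str, float, float], ...]
    stimulus_onsets: tuple[tuple[str, float], ...]
    period_length: float = 600.0
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if tuple(label for label, _, _ in self.phases) != PHASE_LABELS:
            raise ValueError(f"phases must be labelled {PHASE_LABELS} in order")
        t = 0.0
        for _, start, end in self.phases:
            if start != t or end <= start:
                raise ValueError("phases must be contiguous and non-empty")
            t = end
        durations = [end - start for _, start, end in self.phases]
        expected = [h * durations[0] / _PHASE_HOURS[0] for h in _PHASE_HOURS]
        if not all(abs(d - e) < 1e-6 for d, e in zip(durations, expected)):
            raise ValueError("phase durations must be in 6:6:6:4 proportion")
        if tuple(label for label, _ in self.stimulus_onsets) != STIMULUS_LABELS:
            raise ValueError(f"stimulus onsets must be {STIMULUS_LABELS} in order")
        lo, hi = self.phases[2][1], self.phases[2][2]
        for _, onset in self.stimulus_onsets:
            if not lo <= onset < hi:
                raise ValueError("stimulus onsets must fall inside night_stim")
        if abs(self.total_duration / self.period_length - self.n_periods) > 1e-9:
            raise ValueError("period_length must divide total_duration")

    # -- derived quantities -------------------------------------------------

    @property
    def total_duration(self) -> float:
        """Total assay duration in seconds (79,200 at full scale)."""
        return self.phases[-1][2]

    @property
    def n_periods(self) -> int:
        return round(self.total_duration / self.period_length)

    @property
    def n_frames(self) -> int:
        return round(self.total_duration / self.frame_interval)

    @property
    def hour_length(self) -> float:
        """One assay 'hour' in seconds (3600 at full scale)."""
        return self.total_duration / TOTAL_HOURS

    # -- lookups ------------------------------------------------------------

    def phase_at(self, t: float) -> str:
        """Phase label containing elapsed time ``t`` (seconds)."""
        for label, start, end in self.phases:
            if start <= t < end:
                return label
        raise ValueError(f"time {t} outside the assay [0, {self.total_duration})")

    def period_window(self, period: int) -> tuple[float, float]:
        """Half-open time window ``[start, end)`` of a 1-based period id."""
        if not 1 <= period <= self.n_periods:
            raise ValueError(f"period must be in 1..{self.n_periods}")
        start = (period - 1) * self.period_length
        return start, start + self.period_length

    def period_of(self, t: float) -> int:
        """1-based period id containing elapsed time ``t``."""
        if not 0 <= t < self.total_duration:
            raise ValueError("time outside the assay")
        return int(t // self.period_length) + 1

    def hour_window(self, hour: int) -> tuple[float, float]:
        """Half-open window of a 1-based assay hour (hour 1 = first hour)."""
        if not 1 <= hour <= TOTAL_HOURS:
            raise ValueError(f"hour must be in 1..{TOTAL_HOURS}")
        return (hour - 1) * self.hour_length, hour * self.hour_length

    def phase_window(self, label: str) -> tuple[float, float]:
        for plabel, start, end in self.phases:
            if plabel == label:
                return start, end
        raise ValueError(f"unknown phase {label!r}")

    def onset_of(self, stimulus: str) -> float:
        for label, onset in self.stimulus_onsets:
            if label == stimulus:
                return onset
        raise ValueError(f"unknown stimulus {stimulus!r}")

    @property
    def daytime(self) -> list[tuple[float, float]]:
        """Daytime windows (opening and closing day phases)."""
        return [self.phase_window("day1"), self.phase_window("day2")]

    @property
    def nighttime(self) -> list[tuple[float, float]]:
        """Nighttime windows (dark phase and dark-with-stimuli phase)."""
        return [self.phase_window("night1"), self.phase_window("night_stim")]

    def frame_times(self) -> "np.ndarray":
        import numpy as np

        return np.arange(self.n_frames) * self.frame_interval

    # -- constructors -------------------------------------------------------

    @classmethod
    def canonical(cls, frame_interval: float = 1.0) -> "AssaySchedule":
        """The full-scale 22-h schedule (79,200 s, 132 periods)."""
        return cls.scaled(1.0, frame_interval=frame_interval)

    @classmethod
    def scaled(cls, scale: float, frame_interval: float | None = None) -> "AssaySchedule":
        """A proportionally shrunk schedule for fast runs.

        All phase durations, onsets and the period length are multiplied by
        ``scale``; the period grid keeps 132 periods so period arithmetic
        (e.g. "period 73 starts at the first onset") is scale-invariant.
        ``frame_interval`` defaults to 1 s, so a scaled schedule has
        proportionally fewer frames.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        phases = []
        t = 0.0
        for label, hours in zip(PHASE_LABELS, _PHASE_HOURS):
            end = t + hours * HOUR * scale
            phases.append((label, t, end))
            t = end
        onsets = tuple(
            (label, h * HOUR * scale) for label, h in zip(STIMULUS_LABELS, _ONSET_HOURS)
        )
        if frame_interval is None:
            frame_interval = 1.0
        return cls(
            phases=tuple(phases),
            stimulus_onsets=onsets,
            period_length=600.0 * scale,
            frame_interval=frame_interval,
        )
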