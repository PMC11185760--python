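"""Behavioral-syllable sequence summaries.

Unsupervised pose-dynamics segmentation assigns every frame a discrete
behavioral state ("syllable").  This module takes those per-frame label
sequences as input — it performs no model fitting — and summarizes them
as bout-level statistics: usage frequencies, bout durations, transition
matrices/graphs, and per-period summaries around stimulus onsets.

A *bout* is a maximal run of one label.  Frequency is defined on bout
onsets (usage share), which keeps frequency and duration independent;
a frame-share variant is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schedule import AssaySchedule

#: the 29-state alphabet retained by the pose-dynamics model, with
#: human-readable labels.  Ids are sparse on purpose: the segmentation
#: software numbers candidate states 0..63 and discards rare ones.
SYLLABLE_LABELS: dict[int, str] = {
    0: "groom_hunch",
    1: "burst_turn",
    2: "hunch_look",
    3: "burst_short",
    4: "freeze_look",
    5: "rear",
    6: "stretch_burst",
    7: "groom_quick",
    8: "burst_home",
    9: "groom_small",
    10: "rear_climb",
    11: "stretch_sit",
    12: "ball",
    13: "curl",
    14: "rear_fast",
    15: "burst_single",
    16: "stay",
    20: "food",
    21: "stretch",
    24: "groom_tail",
    27: "loop",
    28: "sleep",
    31: "groom_still",
    34: "turn_behind",
    42: "turn",
    46: "look",
    50: "turn_away",
    61: "freeze_hunch",
    63: "small_burst",
}

SYLLABLE_IDS: tuple[int, ...] = tuple(SYLLABLE_LABELS)


@dataclass
class SyllableSequence:
    """Per-frame syllable labels on the schedule grid."""

    time_s: np.ndarray
    label: np.ndarray
    alphabet: tuple[int, ...] = SYLLABLE_IDS

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.label = np.asarray(self.label, int)
        if len(self.time_s) != len(self.label):
            raise ValueError("time_s and label must have equal length")
        unknown = set(np.unique(self.label)) - set(self.alphabet)
        if unknown:
            raise ValueError(f"labels outside the alphabet: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.label)

    @property
    def frame_interval(self) -> float:
        if len(self.time_s) > 1:
            return float(self.time_s[1] - self.time_s[0])
        return 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "label": self.label})


@dataclass
class SyllableSummary:
    """Bout-level summary of a (window of a) syllable sequence.

    frequency sums to 1 over expressed syllables; duration is NaN for
    unexpressed syllables; the transition matrix is the bout-level chain
    (self-transitions are impossible because bouts are maximal runs).
    """

    alphabet: tuple[int, ...]
    frequency: pd.Series          # bout-onset share per syllable
    frame_share: pd.Series        # frame share per syllable
    duration: pd.Series           # mean bout length, seconds
    transition: pd.DataFrame      # row-stochastic; all-NaN row = never left
    n_bouts: int

    @property
    def n_expressed(self) -> int:
        return int((self.frequency > 0).sum())


def segment_bouts(seq: SyllableSequence) -> list[tuple[int, float, float]]:
    """Maximal constant-label runs as (label, start_s, end_s) tuples.

    End times are exclusive on the frame grid, so bout lengths sum to the
    sequence length and concatenating the bouts reconstructs the sequence.
    """
    if len(seq) == 0:
        raise ValueError("empty syllable sequence")
    lab = seq.label
    dt = seq.frame_interval
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(lab)]])
    t0 = seq.time_s[0]
    return [
        (int(lab[s]), float(t0 + s * dt), float(t0 + e * dt))
        for s, e in zip(starts, ends)
    ]


def summarize(
    seq: SyllableSequence, interval: tuple[float, float] | None = None
) -> SyllableSummary:
    """Bout frequencies, mean durations, and the transition matrix.

    ``interval`` restricts the analysis to frames with
    ``start <= time < end``; bouts are segmented within the window (a
    bout straddling the boundary is truncated).  With zero bouts in the
    window every statistic is the NaN sentinel.
    """
    if interval is not None:
        lo, hi = interval
        mask = (seq.time_s >= lo) & (seq.time_s < hi)
        sub = SyllableSequence(seq.time_s[mask], seq.label[mask], seq.alphabet)
    else:
        sub = seq
    alphabet = tuple(seq.alphabet)
    index = pd.Index(alphabet, name="syllable")
    if len(sub) == 0:
        nan = pd.Series(np.nan, index=index)
        return SyllableSummary(
            alphabet, nan, nan, nan,
            pd.DataFrame(np.nan, index=index, columns=index), 0,
        )
    bouts = segment_bouts(sub)
    labels = np.array([b[0] for b in bouts])
    lengths = np.array([b[2] - b[1] for b in bouts])

    onsets = pd.Series(0.0, index=index)
    onsets = onsets.add(pd.Series(labels).value_counts(), fill_value=0.0)
    onsets = onsets.reindex(index, fill_value=0.0)
    frequency = onsets / onsets.sum()

    frames = pd.Series(0.0, index=index)
    for lab, n in zip(*np.unique(sub.label, return_counts=True)):
        frames[lab] = n
    frame_share = frames / frames.sum()

    duration = pd.Series(np.nan, index=index)
    for lab in np.unique(labels):
        duration[lab] = lengths[labels == lab].mean()

    counts = pd.DataFrame(0.0, index=index, columns=index)
    if len(labels) > 1:
        for a, b in zip(labels[:-1], labels[1:]):
            counts.loc[a, b] += 1
    row_sums = counts.sum(axis=1)
    transition = counts.div(row_sums.where(row_sums > 0), axis=0)
    return SyllableSummary(alphabet, frequency, frame_share, duration, transition,
                           n_bouts=len(bouts))


def period_frequencies(
    seq: SyllableSequence, schedule: AssaySchedule, periods: list[int]
) -> dict[int, SyllableSummary]:
    """Per-period summaries for 1-based 10-minute period ids."""
    out = {}
    for p in periods:
        out[p] = summarize(seq, schedule.period_window(p))
    return out


def profile_entries(summary: SyllableSummary) -> pd.Series:
    """The 58 profile entries: f<id> usage frequencies then d<id> durations.

    An unexpressed syllable contributes frequency 0 and a NaN duration.
    """
    entries = {}
    for sid in summary.alphabet:
        entries[f"f{sid}"] = float(summary.frequency[sid])
    for sid in summary.alphabet:
        entries[f"d{sid}"] = float(summary.duration[sid])
    return pd.Series(entries)


def transition_graph(summary: SyllableSummary):
    """Directed transition graph: one node per expressed syllable, edge
    weights equal to the transition-matrix entries."""
    import networkx as nx

    g = nx.DiGraph()
    expressed = [s for s in summary.alphabet if summary.frequency[s] > 0]
    for s in expressed:
        g.add_node(s, label=SYLLABLE_LABELS.get(s, str(s)))
    for a in expressed:
        for b in expressed:
            w = summary.transition.loc[a, b]
            if np.isfinite(w) and w > 0:
                g.add_edge(a, b, weight=float(w))
    return g


def write_edge_list(summary: SyllableSummary, path) -> None:
    g = transition_graph(summary)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for a, b, d in g.edges(data=True):
            fh.write(f"{a}\t{b}\t{d['weight']:.6g}\n")
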