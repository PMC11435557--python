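"""Drinking-task repetition splitting and sub-phase labelling.

A trial contains repetitions of a four-sub-phase drinking task: reach and
grasp (I), lift and drink (II), place back (III), return to rest (IV).
Repetitions are separated by a long rest (~4 s) whereas sub-phases within a
repetition are separated by short pauses (~1 s), so a gap threshold between
the two timescales splits the segment stream into repetitions; within a
complete repetition the four sub-phases are labelled in temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .threshold_segmentation import SegmentList

__all__ = [
    "split_repetitions",
    "label_subphases",
    "subphase_summary",
    "LabeledPhases",
    "PHASES",
]

PHASES = ("I", "II", "III", "IV")
REST_GAP_THRESHOLD_S = 2.0


def split_repetitions(
    segs: SegmentList, rest_gap_threshold: float = REST_GAP_THRESHOLD_S
) -> list[SegmentList]:
    """Group segments into repetitions at gaps exceeding the rest threshold."""
    if len(segs) == 0:
        return []
    groups: list[list[tuple[int, int]]] = [[segs[0]]]
    for prev, cur in zip(segs, list(segs)[1:]):
        gap_s = (cur[0] - prev[1]) / segs.fs
        if gap_s > rest_gap_threshold:
            groups.append([cur])
        else:
            groups[-1].append(cur)
    return [SegmentList(tuple(g), fs=segs.fs) for g in groups]


@dataclass(frozen=True)
class LabeledPhases:
    """Labelled sub-phase table plus indices of incomplete repetitions."""

    table: pd.DataFrame  # repetition, phase, onset_s, offset_s, duration_s
    incomplete: tuple[int, ...]


def label_subphases(groups) -> LabeledPhases:
    """Assign phases I–IV in temporal order within each complete repetition.

    Repetitions with a segment count other than four are flagged as
    incomplete and excluded from the table.
    """
    rows = []
    incomplete = []
    for rep, group in enumerate(groups):
        if len(group) != len(PHASES):
            incomplete.append(rep)
            continue
        for phase, (a, b) in zip(PHASES, group):
            rows.append(
                {
                    "repetition": rep,
                    "phase": phase,
                    "onset_s": a / group.fs,
                    "offset_s": b / group.fs,
                    "duration_s": (b - a) / group.fs,
                }
            )
    table = pd.DataFrame(
        rows, columns=["repetition", "phase", "onset_s", "offset_s", "duration_s"]
    )
    return LabeledPhases(table=table, incomplete=tuple(incomplete))


def subphase_summary(labeled: LabeledPhases | pd.DataFrame) -> pd.DataFrame:
    """Per-phase mean ± standard error of sub-phase durations.

    With a single observation the standard error is undefined; it is
    reported as 0 with ``se_defined`` False.
    """
    table = labeled.table if isinstance(labeled, LabeledPhases) else labeled
    if table.empty:
        raise ValueError("no labelled sub-phases")
    rows = []
    for phase in PHASES:
        d = table.loc[table["phase"] == phase, "duration_s"].to_numpy()
        if d.size == 0:
            continue
        se = float(np.std(d, ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
        rows.append(
            {
                "phase": phase,
                "n": int(d.size),
                "mean_s": float(d.mean()),
                "se_s": se,
                "se_defined": d.size > 1,
            }
        )
    return pd.DataFrame(rows)
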