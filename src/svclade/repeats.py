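"""Best-overlap repeat assignment and class composition tables.

A variant's inserted/deleted sequence typically hits several entries of a
repeat library; the reduction rule keeps, per variant, the match covering
the most bases of the query sequence (ties broken by higher alignment
score, then lexicographic repeat name), and assigns ``no_match`` when no
hit exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import RepeatMatch


@dataclass
class RepeatAssignment:
    variant_id: str
    match: RepeatMatch | None
    repeat_class: str


def assign_best_repeat(matches, variant_ids=None) -> dict:
    """One RepeatAssignment per variant: argmax overlap, tie score, tie name.

    ``variant_ids`` optionally enumerates the full variant universe so
    variants without any match receive an explicit ``no_match`` assignment.
    Deterministic regardless of the order matches arrive in.
    """
    grouped: dict[str, list[RepeatMatch]] = {}
    for m in matches:
        grouped.setdefault(m.variant_id, []).append(m)
    assignments: dict[str, RepeatAssignment] = {}
    for vid, ms in grouped.items():
        best = max(ms, key=lambda m: (m.overlap_bp, m.score, _neg_name(m.repeat_name)))
        assignments[vid] = RepeatAssignment(vid, best, best.repeat_class)
    if variant_ids is not None:
        for vid in variant_ids:
            if vid not in assignments:
                assignments[vid] = RepeatAssignment(vid, None, "no_match")
    return assignments


class _neg_name(str):
    # inverts lexicographic order so max() prefers the alphabetically first name
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def class_composition(assignments) -> pd.DataFrame:
    """Counts and percentages per repeat class; percentages sum to 100."""
    if not assignments:
        raise ValueError("no assignments")
    values = assignments.values() if isinstance(assignments, dict) else assignments
    classes = [a.repeat_class for a in values]
    counts = pd.Series(classes).value_counts().sort_index()
    df = counts.rename_axis("repeat_class").reset_index(name="count")
    df["percent"] = 100.0 * df["count"] / df["count"].sum()
    return df
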