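"""Multi-caller SV consensus merging and post-calling filters.

Merging follows SURVIVOR-style single-linkage clustering: two calls join
a cluster when they sit on the same chromosome, share a type (when type
matching is on), and their start breakpoints lie within ``max_dist`` bp.
Chaining is transitive, so members of one cluster may individually be
farther apart than ``max_dist`` — deliberate fidelity to the cited
behaviour. Post-calling filters cover read-support and length bounds and
masking against low-mapping-quality regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import SVRecord, read_bed

logger = logging.getLogger(__name__)


@dataclass
class MergeParams:
    max_dist: int = 1000
    min_callers: int = 2
    require_type_match: bool = True
    min_size: int = 0


#: named presets matching the published parameter strings
#: "1000 1 1 0 0 50" (long-read) and "1000 2 1 0 0 0" (short-read consensus)
PRESETS = {
    "lr": MergeParams(max_dist=1000, min_callers=1, require_type_match=True, min_size=50),
    "sr": MergeParams(max_dist=1000, min_callers=2, require_type_match=True, min_size=0),
}


@dataclass
class CallerCallSet:
    """One caller's SV calls, sorted by (chrom, pos)."""

    caller: str
    records: list

    def __post_init__(self) -> None:
        keys = [(r.chrom, r.pos) for r in self.records]
        if keys != sorted(keys):
            raise ValueError(f"call set {self.caller!r} is not sorted by (chrom, pos)")


@dataclass
class MergedCall:
    representative: SVRecord
    callers: frozenset
    members: list = field(default_factory=list)  # (caller, record) pairs

    @property
    def support_count(self) -> int:
        return len(self.callers)


def _pick_representative(members: list) -> SVRecord:
    # member whose svlen is closest to the cluster median; ties resolve to
    # the leftmost start, then lexicographic id
    lens = np.array([r.svlen for _c, r in members], dtype=float)
    med = float(np.median(lens))
    return min(members, key=lambda cr: (abs(cr[1].svlen - med), cr[1].pos, cr[1].id))[1]


def merge_call_sets(
    call_sets,
    max_dist: int = 1000,
    require_type_match: bool = True,
    min_callers: int = 2,
    min_size: int = 0,
) -> list:
    """Single-linkage consensus merge across callers.

    Clusters whose distinct-caller count is below ``min_callers`` or whose
    representative is shorter than ``min_size`` bp are dropped. Output is
    sorted by representative (chrom, pos) and is invariant to the order of
    the input call sets.
    """
    if not call_sets:
        raise ValueError("at least one call set required")
    pool: dict = {}
    for cs in sorted(call_sets, key=lambda c: c.caller):
        for r in cs.records:
            key = (r.chrom, r.svtype) if require_type_match else (r.chrom,)
            pool.setdefault(key, []).append((cs.caller, r))
    merged: list[MergedCall] = []
    for key in sorted(pool):
        members = sorted(pool[key], key=lambda cr: (cr[1].pos, cr[0], cr[1].id))
        cluster: list = [members[0]]
        for cr in members[1:]:
            if cr[1].pos - cluster[-1][1].pos <= max_dist:
                cluster.append(cr)
            else:
                merged.append(_finish_cluster(cluster))
                cluster = [cr]
        merged.append(_finish_cluster(cluster))
    merged = [
        mc
        for mc in merged
        if mc.support_count >= min_callers and mc.representative.svlen >= min_size
    ]
    merged.sort(key=lambda mc: (mc.representative.chrom, mc.representative.pos, mc.representative.id))
    return merged


def _finish_cluster(cluster: list) -> MergedCall:
    return MergedCall(
        representative=_pick_representative(cluster),
        callers=frozenset(c for c, _r in cluster),
        members=list(cluster),
    )


def filter_support_and_length(
    records,
    min_support: int = 5,
    max_support: int = 60,
    max_len: int = 100_000,
) -> list:
    """Keep records with min_support <= support <= max_support and svlen <= max_len."""
    kept = []
    for r in records:
        if r.support is None:
            raise ValueError(f"variant {r.id}: support field required for support filtering")
        if min_support <= r.support <= max_support and r.svlen <= max_len:
            kept.append(r)
    return kept


class LowMQTrack:
    """Per-chromosome low-mapping-quality intervals (1-based inclusive)."""

    def __init__(self, intervals: dict) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            for s, e in ivs:
                if s < 0 or e < s:
                    raise ValueError(f"bad interval ({s}, {e}) on {chrom}")
            # merge touching/overlapping intervals
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @classmethod
    def from_bed(cls, path) -> "LowMQTrack":
        intervals: dict = {}
        for chrom, start, end in read_bed(path):
            intervals.setdefault(chrom, []).append((start + 1, end))  # to 1-based inclusive
        return cls(intervals)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._starts)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end] (1-based inclusive) intersects any interval."""
        if chrom not in self._starts:
            return False
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = int(np.searchsorted(starts, end, side="right"))
        return i > 0 and ends[i - 1] >= start


def mask_low_mq(records, track: LowMQTrack) -> list:
    """Drop records whose [pos, end] span intersects the low-MQ track.

    A single base of overlap suffices; adjacency does not. Chromosomes
    absent from the track are treated as unmasked (warning logged once).
    """
    warned: set[str] = set()
    kept = []
    for r in records:
        if r.chrom not in track.chromosomes:
            if r.chrom not in warned:
                logger.warning("chromosome %s absent from low-MQ track; treated as unmasked", r.chrom)
                warned.add(r.chrom)
            kept.append(r)
            continue
        start, end = r.interval
        if not track.overlaps(r.chrom, start, end):
            kept.append(r)
    return kept
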