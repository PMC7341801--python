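"""Phylogenetically informed SV genotype filtering.

Two clades that diverged deep in the past share essentially no
polymorphism by descent, and under the infinite-sites model the same
structural mutation is not expected to recur independently in both. A
variant genuinely segregating in the focal clade should therefore be
invisible in the other clade (the outgroup). Each variant is screened
against the outgroup in one of two modes:

* ``homref_outgroup`` — every outgroup individual must be homozygous
  reference; discordant (non-zero dosage) outgroup calls count as errors.
* ``fixed_outgroup`` — the outgroup must be fixed for either allele; the
  majority homozygous state s in {0, 2} is determined among non-missing
  calls (tie -> 0) and calls differing from s count as errors.

A variant is retained for a clade when its outgroup error count does not
exceed that outgroup's genotyping-error tolerance. MISSING outgroup calls
are by default excluded from the error count (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, ChromTable, CladeMap, GenotypeMatrix, SVRecord

MODES = ("homref_outgroup", "fixed_outgroup")

REASONS = ("clean", "within_tolerance", "cross_clade", "all_missing")


@dataclass
class CladeVerdict:
    """Outcome of screening one variant for one focal clade."""

    retained: bool
    error_count: int
    reason: str


@dataclass
class FilterVerdict:
    variant_id: str
    retained_for_clade_A: bool
    retained_for_clade_B: bool
    error_count_A: int  # outgroup errors in the clade-A analysis
    error_count_B: int  # outgroup errors in the clade-B analysis
    reason: str

    @property
    def retained(self) -> bool:
        return self.retained_for_clade_A or self.retained_for_clade_B


def classify_variant(
    dosage_row: np.ndarray,
    individual_ids,
    clade_map: CladeMap,
    focal_clade: str,
    mode: str,
    tolerance: int | None = None,
    count_missing_as_error: bool = False,
) -> CladeVerdict:
    """Screen one dosage row for clade-exclusive segregation.

    The outgroup is every individual not in ``focal_clade``. ``tolerance``
    defaults to the clade map's tolerance for the outgroup clade.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    dosage_row = np.asarray(dosage_row)
    idx = {s: j for j, s in enumerate(individual_ids)}
    focal_inds = clade_map.members(focal_clade)
    if not focal_inds:
        raise ValueError(f"focal clade {focal_clade!r} is empty")
    out_inds = [s for s in clade_map.individuals if clade_map.clade_of(s) != focal_clade]
    if not out_inds:
        raise ValueError("outgroup is empty")
    if tolerance is None:
        out_clades = {clade_map.clade_of(s) for s in out_inds}
        tolerance = min(clade_map.tolerance(c) for c in out_clades)
    out = dosage_row[[idx[s] for s in out_inds]]
    if np.all(dosage_row[[idx[s] for s in clade_map.individuals]] == MISSING):
        return CladeVerdict(retained=False, error_count=0, reason="all_missing")
    missing = out == MISSING
    called = out[~missing]
    if mode == "homref_outgroup":
        errors = int((called != 0).sum())
    else:
        s = 0 if (called == 0).sum() >= (called == 2).sum() else 2
        errors = int((called != s).sum())
    if count_missing_as_error:
        errors += int(missing.sum())
    retained = errors <= tolerance
    if not retained:
        reason = "cross_clade"
    elif errors == 0:
        reason = "clean"
    else:
        reason = "within_tolerance"
    return CladeVerdict(retained=retained, error_count=errors, reason=reason)


def apply_phylo_filter(
    matrix: GenotypeMatrix,
    clade_map: CladeMap,
    clade_a: str = "A",
    clade_b: str = "B",
    count_missing_as_error: bool = False,
) -> tuple[list[FilterVerdict], dict[str, set], set]:
    """Run both clade analyses over every variant.

    The clade-A analysis requires the clade-B outgroup homozygous
    reference (tolerance of clade B); the clade-B analysis requires the
    clade-A outgroup fixed for either allele (tolerance of clade A).
    Returns (verdicts, per-clade retained id sets, union retained set).
    """
    unknown = [s for s in matrix.individual_ids if s not in clade_map.assignments]
    if unknown:
        raise ValueError(f"individuals absent from clade map: {unknown[:5]}")
    verdicts: list[FilterVerdict] = []
    retained: dict[str, set] = {clade_a: set(), clade_b: set()}
    union: set = set()
    for vid, row in zip(matrix.variant_ids, matrix.dosage):
        va = classify_variant(
            row, matrix.individual_ids, clade_map, clade_a, "homref_outgroup",
            tolerance=clade_map.tolerance(clade_b),
            count_missing_as_error=count_missing_as_error,
        )
        vb = classify_variant(
            row, matrix.individual_ids, clade_map, clade_b, "fixed_outgroup",
            tolerance=clade_map.tolerance(clade_a),
            count_missing_as_error=count_missing_as_error,
        )
        if va.reason == "all_missing":
            reason = "all_missing"
        elif not (va.retained or vb.retained):
            reason = "cross_clade"
        elif max(va.error_count, vb.error_count) == 0:
            reason = "clean"
        else:
            reason = "within_tolerance"
        verdicts.append(
            FilterVerdict(
                variant_id=vid,
                retained_for_clade_A=va.retained,
                retained_for_clade_B=vb.retained,
                error_count_A=va.error_count,
                error_count_B=vb.error_count,
                reason=reason,
            )
        )
        if va.retained:
            retained[clade_a].add(vid)
        if vb.retained:
            retained[clade_b].add(vid)
        if va.retained or vb.retained:
            union.add(vid)
    return verdicts, retained, union


def retention_percent(n_initial: int, n_retained: int) -> float:
    """Percentage of the initial, unfiltered variant set that was retained."""
    if n_initial <= 0:
        raise ValueError("initial count must be positive")
    return 100.0 * n_retained / n_initial


def distance_to_chrom_end(record: SVRecord, chrom_table: ChromTable) -> int:
    """Distance (bp) from the variant to the nearer chromosome end."""
    length = chrom_table[record.chrom]
    if record.end > length:
        raise ValueError(f"{record.id}: end {record.end} exceeds {record.chrom} length {length}")
    return min(record.pos, length - record.end)


def retention_summary(
    verdicts,
    records,
    chrom_table: ChromTable,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Retained/excluded counts by SV type and distance-to-chromosome-end bin.

    Bins are equal-width over [0, max observed distance]. Marginal totals
    equal the verdict counts.
    """
    by_id = {v.variant_id: v for v in verdicts}
    dist = np.array([distance_to_chrom_end(r, chrom_table) for r in records], dtype=float)
    edges = np.linspace(0.0, max(dist.max(), 1.0), n_bins + 1)
    bins = np.clip(np.digitize(dist, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for r, b in zip(records, bins):
        v = by_id[r.id]
        rows.append((r.svtype, int(b), v.retained))
    df = pd.DataFrame(rows, columns=["svtype", "distance_bin", "retained"])
    out = (
        df.groupby(["svtype", "distance_bin"])["retained"]
        .agg(retained="sum", total="count")
        .reset_index()
    )
    out["retained"] = out["retained"].astype(int)
    out["excluded"] = out["total"] - out["retained"]
    out["bin_start"] = edges[out["distance_bin"].to_numpy()]
    out["bin_end"] = edges[out["distance_bin"].to_numpy() + 1]
    return out[["svtype", "distance_bin", "bin_start", "bin_end", "retained", "excluded", "total"]]


def verdicts_to_frame(verdicts) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in verdicts],
            "retained_for_clade_A": [v.retained_for_clade_A for v in verdicts],
            "retained_for_clade_B": [v.retained_for_clade_B for v in verdicts],
            "error_count_A": [v.error_count_A for v in verdicts],
            "error_count_B": [v.error_count_B for v in verdicts],
            "reason": [v.reason for v in verdicts],
        }
    )
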