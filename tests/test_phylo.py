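"""Clade-exclusivity genotype filter: classification rules, truth recovery,
monotonicity, and retention summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svclade.io import MISSING, ChromTable, CladeMap, GenotypeMatrix, SVRecord
from svclade.phylo import (
    apply_phylo_filter,
    classify_variant,
    distance_to_chrom_end,
    retention_percent,
    retention_summary,
)


def study_map():
    assignments = {f"j{i}": ("jackdaw", "A") for i in range(8)}
    assignments |= {f"c{i}": ("crow", "B") for i in range(24)}
    return CladeMap(assignments)  # default tolerances: A->2, B->4


def row(a_dosages, b_dosages):
    return np.array(list(a_dosages) + list(b_dosages), dtype=np.int8)


IDS = [f"j{i}" for i in range(8)] + [f"c{i}" for i in range(24)]


def test_clean_outgroup_retained():
    cm = study_map()
    r = row([0, 1, 2, 1, 0, 0, 1, 0], [0] * 24)
    v = classify_variant(r, IDS, cm, "A", "homref_outgroup", tolerance=4)
    assert v.retained and v.error_count == 0 and v.reason == "clean"


def test_homref_outgroup_threshold_boundary():
    cm = study_map()
    base = [0, 1, 2, 1, 0, 0, 1, 0]
    r4 = row(base, [1, 1, 1, 1] + [0] * 20)
    r5 = row(base, [1, 1, 1, 1, 2] + [0] * 19)
    assert classify_variant(r4, IDS, cm, "A", "homref_outgroup", tolerance=4).retained
    v5 = classify_variant(r5, IDS, cm, "A", "homref_outgroup", tolerance=4)
    assert not v5.retained and v5.error_count == 5 and v5.reason == "cross_clade"


def test_fixed_outgroup_majority_alt():
    """Outgroup of 8 with dosages 2x7 + 1x1: majority state 2, one error."""
    cm = study_map()
    r = row([2] * 7 + [1], [0, 1, 2, 1] + [0] * 20)
    v = classify_variant(r, IDS, cm, "B", "fixed_outgroup", tolerance=2)
    assert v.retained and v.error_count == 1 and v.reason == "within_tolerance"


def test_fixed_outgroup_tie_resolves_to_reference():
    cm = study_map()
    r = row([0, 0, 0, 0, 2, 2, 2, 2], [1] + [0] * 23)
    v = classify_variant(r, IDS, cm, "B", "fixed_outgroup", tolerance=4)
    assert v.error_count == 4  # the four alt homozygotes vs majority state 0


def test_missing_calls_excluded_from_error_count():
    cm = study_map()
    r = row([0, 1, 2, 0, 0, 0, 0, 0], [1, MISSING, MISSING] + [0] * 21)
    v = classify_variant(r, IDS, cm, "A", "homref_outgroup", tolerance=2)
    assert v.error_count == 1
    v2 = classify_variant(r, IDS, cm, "A", "homref_outgroup", tolerance=2,
                          count_missing_as_error=True)
    assert v2.error_count == 3


def test_all_missing_row():
    cm = study_map()
    r = np.full(32, MISSING, dtype=np.int8)
    v = classify_variant(r, IDS, cm, "A", "homref_outgroup", tolerance=4)
    assert v.reason == "all_missing" and not v.retained


def test_clean_cohort_full_truth_recovery(clean_cohort):
    """eps=0: all clade-private variants retained, all injected FPs excluded."""
    verdicts, _by_clade, union = apply_phylo_filter(clean_cohort.genotypes, clean_cohort.clade_map)
    truth = clean_cohort.truth
    fps = set(truth.loc[truth.origin == "cross_clade_FP", "variant_id"])
    privates = set(truth.variant_id) - fps
    assert union & fps == set()
    assert privates <= union
    assert {v.variant_id for v in verdicts} == set(truth.variant_id)  # partition


def test_verdicts_unchanged_under_individual_permutation(clean_cohort):
    gm = clean_cohort.genotypes
    rng = np.random.default_rng(0)
    perm = rng.permutation(gm.n_individuals)
    shuffled = GenotypeMatrix(
        gm.variant_ids, [gm.individual_ids[i] for i in perm], gm.dosage[:, perm]
    )
    v1, _, u1 = apply_phylo_filter(gm, clean_cohort.clade_map)
    v2, _, u2 = apply_phylo_filter(shuffled, clean_cohort.clade_map)
    assert u1 == u2
    assert [(v.variant_id, v.error_count_A, v.error_count_B) for v in v1] == [
        (v.variant_id, v.error_count_A, v.error_count_B) for v in v2
    ]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    dosages=st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=32, max_size=32),
    tol_lo=st.integers(min_value=0, max_value=6),
    extra=st.integers(min_value=0, max_value=6),
    mode=st.sampled_from(["homref_outgroup", "fixed_outgroup"]),
)
def test_raising_tolerance_never_excludes(dosages, tol_lo, extra, mode):
    cm = study_map()
    r = np.array(dosages, dtype=np.int8)
    focal = "A" if mode == "homref_outgroup" else "B"
    lo = classify_variant(r, IDS, cm, focal, mode, tolerance=tol_lo)
    hi = classify_variant(r, IDS, cm, focal, mode, tolerance=tol_lo + extra)
    if lo.retained:
        assert hi.retained
    assert lo.error_count == hi.error_count


def test_noisy_cohort_shows_cross_clade_tolerance_slack(noisy_cohort):
    """With eps>0 some retained variants appear (spuriously) in both clades."""
    _verdicts, by_clade, _union = apply_phylo_filter(noisy_cohort.genotypes, noisy_cohort.clade_map)
    cm = noisy_cohort.clade_map
    idx = {s: j for j, s in enumerate(noisy_cohort.genotypes.individual_ids)}
    a_idx = [idx[s] for s in cm.members("A")]
    b_idx = [idx[s] for s in cm.members("B")]
    both = 0
    for vid in by_clade["A"] | by_clade["B"]:
        r = noisy_cohort.genotypes.row(vid)
        if (r[a_idx] > 0).any() and (r[b_idx] > 0).any():
            both += 1
    assert both > 0


def test_retention_percent_formula():
    assert retention_percent(200, 150) == pytest.approx(75.0)
    with pytest.raises(ValueError):
        retention_percent(0, 1)


def test_distance_to_chrom_end():
    table = ChromTable({"chr1": 1_000_000})
    r = SVRecord("chr1", 100, "v", "DEL", 50, 149)
    assert distance_to_chrom_end(r, table) == 100
    far = SVRecord("chr1", 999_000, "w", "DEL", 500, 999_499)
    assert distance_to_chrom_end(far, table) == 501
    out = SVRecord("chr1", 999_900, "x", "DEL", 200, 1_000_099)
    with pytest.raises(ValueError):
        distance_to_chrom_end(out, table)


def test_distance_matches_brute_force(clean_cohort):
    table = clean_cohort.chrom_table
    rng = np.random.default_rng(5)
    for r in list(np.array(clean_cohort.records, dtype=object)[rng.choice(len(clean_cohort.records), 50, replace=False)]):
        d = distance_to_chrom_end(r, table)
        assert d == min(r.pos, table[r.chrom] - r.end)
        assert d >= 0


def test_retention_summary_marginals(clean_cohort):
    verdicts, _b, union = apply_phylo_filter(clean_cohort.genotypes, clean_cohort.clade_map)
    table = retention_summary(verdicts, clean_cohort.records, clean_cohort.chrom_table, n_bins=8)
    assert table.retained.sum() == len(union)
    assert table.total.sum() == len(clean_cohort.records)
    assert (table.retained + table.excluded == table.total).all()


def test_fp_exclusion_enriched_near_chromosome_ends(clean_cohort):
    """Injected FPs sit near chromosome ends, so the excluded fraction
    decays with distance from the end."""
    verdicts, _b, _u = apply_phylo_filter(clean_cohort.genotypes, clean_cohort.clade_map)
    table = retention_summary(verdicts, clean_cohort.records, clean_cohort.chrom_table, n_bins=4)
    agg = table.groupby("distance_bin")[["excluded", "total"]].sum()
    frac = agg.excluded / agg.total
    assert frac.iloc[0] > frac.iloc[-1]
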