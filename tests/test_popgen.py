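"""Population-genetic summaries: AFS folding, Weir–Cockerham variance
components vs an independent ANOVA-route evaluation, outlier scans,
window densities, and genotype PCA."""

import numpy as np
import pandas as pd
import pytest

from svclade.io import MISSING, ChromTable, GenotypeMatrix, SVRecord
from svclade.popgen import (
    FstResult,
    chrom_enrichment,
    folded_afs,
    fst_outliers,
    fst_scan,
    genotype_pca,
    weir_cockerham_fst,
    window_density,
)


def anova_theta(dosages, labels):
    """Independent Weir–Cockerham evaluation via the ANOVA mean squares.

    Treats each diploid's two alleles as nested observations: SSG (within
    individuals), SSI (among individuals within populations), SSP (among
    populations), then a = (MSP-MSI)/(2 nc), b = (MSI-MSG)/2, c = MSG.
    """
    dosages = np.asarray(dosages, dtype=float)
    labels = np.asarray(labels)
    pops = [p for p in dict.fromkeys(labels) if (dosages[labels == p] != MISSING).any()]
    r = len(pops)
    n_i, p_i, ssg, ssi = [], [], 0.0, 0.0
    groups = []
    for p in pops:
        d = dosages[labels == p]
        d = d[d != MISSING]
        groups.append(d)
        n_i.append(len(d))
        p_i.append(d.sum() / (2 * len(d)))
    n_i = np.array(n_i, dtype=float)
    p_i = np.array(p_i)
    S1 = n_i.sum()
    p_bar = (n_i * p_i).sum() / S1
    for d, pi in zip(groups, p_i):
        for dos in d:
            x = {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (1.0, 1.0)}[int(dos)]
            mean_ij = sum(x) / 2
            ssg += (x[0] - mean_ij) ** 2 + (x[1] - mean_ij) ** 2
            ssi += 2 * (mean_ij - pi) ** 2
    ssp = float((2 * n_i * (p_i - p_bar) ** 2).sum())
    msg = ssg / S1
    msi = ssi / (S1 - r) if S1 > r else 0.0
    msp = ssp / (r - 1)
    nc = (S1 - (n_i**2).sum() / S1) / (r - 1)
    a = (msp - msi) / (2 * nc)
    b = (msi - msg) / 2
    c = msg
    denom = a + b + c
    return (a, b, c, a / denom) if denom != 0 else (a, b, c, None)


def test_fixed_difference_theta_is_one():
    dos = [0, 0, 0, 2, 2, 2]
    labels = ["p1"] * 3 + ["p2"] * 3
    res = weir_cockerham_fst(dos, labels)
    assert res.theta_hat == pytest.approx(1.0, abs=1e-12)


def test_identical_configurations_non_positive():
    dos = [0, 1, 2, 0, 1, 2]
    labels = ["p1"] * 3 + ["p2"] * 3
    res = weir_cockerham_fst(dos, labels)
    assert res.defined and res.theta_hat <= 0


def test_two_pop_textbook_case_matches_anova_route():
    dos = [0, 1, 2, 2]
    labels = ["p1", "p1", "p2", "p2"]
    res = weir_cockerham_fst(dos, labels)
    a, b, c, theta = anova_theta(dos, labels)
    assert res.a == pytest.approx(a, abs=1e-10)
    assert res.b == pytest.approx(b, abs=1e-10)
    assert res.c == pytest.approx(c, abs=1e-10)
    assert res.theta_hat == pytest.approx(theta, abs=1e-10)


def test_estimator_matches_anova_route_on_random_configurations():
    """1,000 random <=6-individual configurations agree to 1e-10."""
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 1000:
        n1 = int(rng.integers(1, 4))
        n2 = int(rng.integers(1, 4))
        n3 = int(rng.integers(0, 2))  # sometimes a third population
        sizes = [n1, n2] + ([n3] if n3 else [])
        labels = np.concatenate([[f"p{i}"] * n for i, n in enumerate(sizes)])
        dos = rng.integers(0, 3, size=len(labels))
        if rng.random() < 0.2:
            dos[rng.integers(0, len(dos))] = MISSING
        valid_pops = {p for p, d in zip(labels, dos) if d != MISSING}
        if len(valid_pops) < 2:
            continue
        counts = [sum(1 for p, d in zip(labels, dos) if p == vp and d != MISSING) for vp in valid_pops]
        if np.mean(counts) <= 1:
            # one allele pair per population: within-population variance has
            # no degrees of freedom and the estimator is undefined
            assert not weir_cockerham_fst(dos, labels).defined
            continue
        res = weir_cockerham_fst(dos, labels)
        a, b, c, theta = anova_theta(dos, labels)
        assert res.a == pytest.approx(a, abs=1e-10)
        assert res.b == pytest.approx(b, abs=1e-10)
        assert res.c == pytest.approx(c, abs=1e-10)
        if theta is None:
            assert not res.defined
        else:
            assert res.defined
            assert res.theta_hat == pytest.approx(theta, abs=1e-10)
        checked += 1


def test_monomorphic_flagged_undefined():
    res = weir_cockerham_fst([0, 0, 0, 0], ["p1", "p1", "p2", "p2"])
    assert not res.defined and np.isnan(res.theta_hat)


def test_single_population_rejected():
    with pytest.raises(ValueError):
        weir_cockerham_fst([0, 1], ["p1", "p1"])


def test_folding_symmetry():
    """Alt counts k and 2N-k land in the same folded bin."""
    n = 24
    low = np.zeros(n, dtype=np.int8)
    low[:3] = 1  # k = 3
    high = np.full(n, 2, dtype=np.int8)
    high[:3] = 1  # k = 45 = 48 - 3
    gm = GenotypeMatrix(["v1", "v2"], [f"s{i}" for i in range(n)], np.vstack([low, high]))
    (afs,) = folded_afs(gm)
    assert afs.counts[3] == 2
    assert afs.n_segregating == 2


def test_monomorphic_contributes_nothing():
    gm = GenotypeMatrix(
        ["v1", "v2"],
        ["s1", "s2"],
        np.array([[0, 0], [2, 2]], dtype=np.int8),
    )
    spectra = folded_afs(gm)
    assert all(sp.n_segregating == 0 for sp in spectra)


def test_afs_mass_equals_segregating_count(clean_cohort):
    cm = clean_cohort.clade_map
    sub = clean_cohort.genotypes.subset_individuals(cm.members("B"))
    grouping = dict(zip(clean_cohort.truth.variant_id, clean_cohort.truth.repeat_class))
    spectra = folded_afs(sub, grouping)
    n_seg = 0
    for row in sub.dosage:
        k = row[row != MISSING].sum()
        nn = (row != MISSING).sum()
        if 0 < k < 2 * nn:
            n_seg += 1
    assert sum(sp.n_segregating for sp in spectra) == n_seg


def test_tandem_class_shifted_to_intermediate_frequencies(clean_cohort):
    """Hypermutable tandem loci have higher mean minor-allele frequency
    than unannotated variants."""
    cm = clean_cohort.clade_map
    truth = clean_cohort.truth
    private_b = truth.loc[truth.origin == "B"]
    sub = clean_cohort.genotypes.subset_variants(private_b.variant_id).subset_individuals(
        cm.members("B")
    )
    grouping = dict(zip(private_b.variant_id, private_b.repeat_class))
    spectra = {sp.label: sp for sp in folded_afs(sub, grouping)}
    assert (
        spectra["tandem"].mean_minor_allele_frequency()
        > spectra["no_match"].mean_minor_allele_frequency()
    )


def test_outliers_quantile_definition():
    values = np.arange(1, 101) / 100.0
    out = fst_outliers(values, percentile=99)
    assert out == {99}  # only the top value exceeds the interpolated quantile


def test_outliers_all_equal_empty():
    assert fst_outliers([0.5] * 10) == set()


def test_outliers_stable_under_subthreshold_addition():
    vals = list(np.arange(1, 101) / 100.0)
    base = fst_outliers(vals)
    more = fst_outliers(vals + [0.5])  # a mid-range, clearly non-outlier value
    assert base == {99}
    assert more == {99}  # same positions flagged; the addition changes nothing


def test_outliers_require_defined_values():
    undef = FstResult("v", 0, 0, 0, float("nan"), {}, defined=False)
    with pytest.raises(ValueError):
        fst_outliers([undef])


def test_enrichment_closed_form():
    table = ChromTable({"chrA": 900, "chrB": 100})
    records = [
        SVRecord("chrB", 10, "o1", "INS", 60, 10),
        SVRecord("chrB", 20, "o2", "INS", 60, 20),
        SVRecord("chrA", 30, "o3", "INS", 60, 30),
    ]
    # all outliers on a chromosome covering 10% of the genome -> 10x
    enr = chrom_enrichment({"o1", "o2"}, records, table, "chrB")
    assert enr == pytest.approx((2 / 2) / 0.1)
    with pytest.raises(ValueError):
        chrom_enrichment(set(), records, table, "chrB")


def test_enrichment_uniform_outliers_near_one():
    rng = np.random.default_rng(1)
    table = ChromTable({"c1": 5_000_000, "c2": 3_000_000, "c3": 2_000_000})
    chroms = rng.choice(["c1", "c2", "c3"], p=[0.5, 0.3, 0.2], size=4000)
    records = []
    for i, c in enumerate(chroms):
        pos = int(rng.integers(1, table[c] - 100))
        records.append(SVRecord(c, pos, f"o{i}", "INS", 60, pos))
    ids = {r.id for r in records}
    for chrom in table:
        assert chrom_enrichment(ids, records, table, chrom) == pytest.approx(1.0, abs=0.15)


def test_window_density_collapse_rule():
    table = ChromTable({"chr1": 1_000_000})
    recs = [
        SVRecord("chr1", 100, "a", "DEL", 200, 299),
        SVRecord("chr1", 250, "b", "DEL", 200, 449),  # overlaps a
        SVRecord("chr1", 10_000, "c", "DEL", 100, 10_099),
    ]
    collapsed = window_density(recs, table)
    assert collapsed["count"].sum() == 2
    raw = window_density(recs, table, collapse_overlapping=False)
    assert raw["count"].sum() == 3


def test_window_density_empty_chromosome_emits_zero_windows():
    table = ChromTable({"chr1": 2_500_000, "chr2": 1_000_000})
    recs = [SVRecord("chr1", 5, "a", "INS", 60, 5)]
    df = window_density(recs, table)
    assert set(df.chrom) == {"chr1", "chr2"}
    assert df.loc[df.chrom == "chr2", "count"].sum() == 0
    assert len(df) == 3 + 1  # ceil tiling


def test_window_density_matches_quadratic_scan():
    rng = np.random.default_rng(9)
    table = ChromTable({"c1": 3_000_000})
    recs = []
    for i in range(60):
        pos = int(rng.integers(1, 2_900_000))
        ln = int(rng.integers(51, 5000))
        recs.append(SVRecord("c1", pos, f"v{i}", "DEL", ln, pos + ln - 1))
    df = window_density(recs, table, collapse_overlapping=False)
    for _, rowd in df.iterrows():
        w0, w1 = rowd.start, rowd.start + 1_000_000
        manual = sum(1 for r in recs if w0 < r.pos <= w1)
        assert rowd["count"] == manual


def test_pca_separates_clades(clean_cohort):
    res = genotype_pca(clean_cohort.genotypes, n_components=2)
    cm = clean_cohort.clade_map
    pc1 = dict(zip(res.individual_ids, res.coordinates[:, 0]))
    a_scores = [pc1[s] for s in cm.members("A")]
    b_scores = [pc1[s] for s in cm.members("B")]
    assert max(a_scores) < min(b_scores) or max(b_scores) < min(a_scores)


def test_pca_duplicated_individual_identical_coordinates():
    rng = np.random.default_rng(2)
    dosage = rng.integers(0, 3, size=(50, 5)).astype(np.int8)
    dosage[:, 4] = dosage[:, 3]  # duplicate
    gm = GenotypeMatrix([f"v{i}" for i in range(50)], [f"s{j}" for j in range(5)], dosage)
    res = genotype_pca(gm, n_components=3)
    np.testing.assert_allclose(res.coordinates[3], res.coordinates[4], atol=1e-8)


def test_pca_explained_variance_bounded(clean_cohort):
    res = genotype_pca(clean_cohort.genotypes, n_components=5)
    assert (np.diff(res.explained_variance) <= 1e-9).all()  # decreasing
    assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9


def test_pca_zero_variance_rejected():
    gm = GenotypeMatrix(["v1"], ["s1", "s2"], np.array([[1, 1]], dtype=np.int8))
    with pytest.raises(ValueError, match="variance"):
        genotype_pca(gm)


def test_fst_scan_drops_other_populations(clean_cohort):
    cm = clean_cohort.clade_map
    pop_of = {s: cm.population_of(s) for s in clean_cohort.genotypes.individual_ids}
    results = fst_scan(clean_cohort.genotypes, pop_of, pops=["B_pop1", "B_pop2"])
    assert len(results) == clean_cohort.genotypes.n_variants
    assert set(results[0].n_per_pop) <= {"B_pop1", "B_pop2"}
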