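"""Population-genetic summaries on SV genotype matrices.

Folded allele-frequency spectra by repeat class, per-variant
Weir–Cockerham F_ST with its a/b/c variance components, percentile
outlier scans, chromosomal enrichment of outliers, 1-Mb window densities,
and genotype PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, ChromTable, GenotypeMatrix


@dataclass
class FoldedAFS:
    """Folded spectrum for one variant class.

    ``counts[i]`` is the number of segregating variants with minor-allele
    count i; index 0 is unused (monomorphic variants are excluded).
    """

    label: str
    counts: np.ndarray
    n_diploids: int

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())

    def mean_minor_allele_frequency(self) -> float:
        i = np.arange(len(self.counts))
        total = self.counts.sum()
        if total == 0:
            return float("nan")
        return float((i * self.counts).sum() / total / (2 * self.n_diploids))


def folded_afs(matrix: GenotypeMatrix, grouping=None) -> list[FoldedAFS]:
    """Folded AFS per variant class from minor-allele counts.

    ``grouping`` maps variant id -> class label (None puts everything in
    one class "all"). Per variant the minor-allele count is
    min(k, 2N' - k) over the N' non-missing diploids; monomorphic variants
    contribute to no bin.
    """
    n = matrix.n_individuals
    max_i = n  # floor(2N/2)
    spectra: dict[str, np.ndarray] = {}
    for vid, row in zip(matrix.variant_ids, matrix.dosage):
        label = grouping.get(vid, "no_match") if grouping is not None else "all"
        counts = spectra.setdefault(label, np.zeros(max_i + 1, dtype=np.int64))
        valid = row != MISSING
        nprime = int(valid.sum())
        if nprime == 0:
            continue
        k = int(row[valid].sum())
        if k == 0 or k == 2 * nprime:
            continue
        counts[min(k, 2 * nprime - k)] += 1
    return [FoldedAFS(label=lab, counts=cnt, n_diploids=n) for lab, cnt in sorted(spectra.items())]


@dataclass
class FstResult:
    """Per-variant Weir–Cockerham variance components and theta-hat."""

    variant_id: str
    a: float  # among populations
    b: float  # among individuals within populations
    c: float  # within individuals
    theta_hat: float
    n_per_pop: dict
    defined: bool = True


def weir_cockerham_fst(dosage_row, population_labels, variant_id: str = "") -> FstResult:
    """Weir & Cockerham's theta-hat for one biallelic diploid variant.

    Computes the two-level variance components a (among populations),
    b (among individuals within populations) and c (within individuals)
    from per-population sample sizes, allele frequencies, and observed
    heterozygosity; theta_hat = a / (a + b + c). Missing individuals are
    dropped per variant. theta_hat may be negative; a monomorphic variant
    (a + b + c == 0) is flagged undefined.
    """
    dos = np.asarray(dosage_row, dtype=float)
    labels = np.asarray(population_labels)
    valid = dos != MISSING
    pops = [p for p in dict.fromkeys(labels) if valid[labels == p].any()]
    if len(pops) < 2:
        raise ValueError("need >= 2 populations with >= 1 non-missing diploid each")
    r = len(pops)
    n_i = np.array([int(valid[labels == p].sum()) for p in pops], dtype=float)
    p_i = np.array([dos[(labels == p) & valid].sum() / (2 * n) for p, n in zip(pops, n_i)])
    h_i = np.array([(dos[(labels == p) & valid] == 1).mean() for p in pops])
    n_bar = n_i.mean()
    n_total = n_i.sum()
    if n_bar <= 1:
        return FstResult(variant_id, 0.0, 0.0, 0.0, float("nan"), dict(zip(pops, n_i.astype(int))), defined=False)
    n_c = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    p_bar = (n_i * p_i).sum() / n_total
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / n_total
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    denom = a + b + c
    n_map = dict(zip(pops, n_i.astype(int)))
    if denom == 0.0:
        return FstResult(variant_id, a, b, c, float("nan"), n_map, defined=False)
    return FstResult(variant_id, a, b, c, a / denom, n_map)


def fst_scan(matrix: GenotypeMatrix, population_of, pops=None) -> list[FstResult]:
    """Per-variant F_ST over the matrix. ``population_of`` maps individual -> pop."""
    labels = np.array([population_of[s] for s in matrix.individual_ids])
    if pops is not None:
        keep = np.isin(labels, list(pops))
        sub = matrix.subset_individuals([s for s, k in zip(matrix.individual_ids, keep) if k])
        labels = labels[keep]
        matrix = sub
    return [
        weir_cockerham_fst(row, labels, variant_id=vid)
        for vid, row in zip(matrix.variant_ids, matrix.dosage)
    ]


def fst_outliers(results, percentile: float = 99.0) -> set:
    """Ids (or indices) with theta strictly above the percentile threshold.

    The threshold is the linear-interpolation quantile of the defined
    theta values; undefined (monomorphic) results are excluded.
    """
    items = []
    for i, res in enumerate(results):
        if isinstance(res, FstResult):
            if res.defined:
                items.append((res.variant_id or i, res.theta_hat))
        elif np.isfinite(res):
            items.append((i, float(res)))
    if len(items) < 2:
        raise ValueError("need >= 2 defined theta values")
    values = np.array([t for _k, t in items])
    threshold = float(np.percentile(values, percentile, method="linear"))
    return {k for k, t in items if t > threshold}


def chrom_enrichment(outlier_ids, records, chrom_table: ChromTable, chrom: str) -> float:
    """Fold enrichment of outliers on one chromosome vs its genome share."""
    if chrom not in chrom_table:
        raise ValueError(f"chromosome {chrom!r} not in table")
    outlier_ids = set(outlier_ids)
    if not outlier_ids:
        raise ValueError("no outliers: enrichment undefined")
    by_id = {r.id: r for r in records}
    on_chrom = sum(1 for vid in outlier_ids if by_id[vid].chrom == chrom)
    frac_outliers = on_chrom / len(outlier_ids)
    frac_genome = chrom_table[chrom] / chrom_table.total_length
    return frac_outliers / frac_genome


@dataclass
class WindowDensity:
    chrom: str
    start: int  # 0-based, half-open window of fixed width
    count: int


def window_density(
    records,
    chrom_table: ChromTable,
    window: int = 1_000_000,
    collapse_overlapping: bool = True,
) -> pd.DataFrame:
    """SV counts in fixed-width windows tiling every chromosome.

    With ``collapse_overlapping`` (the non-overlapping-SV convention),
    same-type records whose reference spans intersect merge into a single
    counted cluster. A record/cluster is assigned to the window containing
    its start (1-based start -> 0-based window arithmetic).
    """
    spans: dict = {}
    for r in records:
        if r.chrom not in chrom_table:
            raise ValueError(f"{r.id}: chromosome {r.chrom} not in table")
        s, e = r.interval
        if e > chrom_table[r.chrom]:
            raise ValueError(f"{r.id}: outside chromosome bounds")
        spans.setdefault((r.chrom, r.svtype), []).append((s, e))
    starts_by_chrom: dict[str, list[int]] = {c: [] for c in chrom_table}
    for (chrom, _svtype), ivs in spans.items():
        ivs.sort()
        if collapse_overlapping:
            clusters = []
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:  # 1-bp overlap merges; adjacency does not
                    cur_e = max(cur_e, e)
                else:
                    clusters.append(cur_s)
                    cur_s, cur_e = s, e
            clusters.append(cur_s)
            starts_by_chrom[chrom].extend(clusters)
        else:
            starts_by_chrom[chrom].extend(s for s, _e in ivs)
    rows = []
    for chrom, length in chrom_table.items():
        n_windows = (length + window - 1) // window
        counts = np.zeros(n_windows, dtype=np.int64)
        for s in starts_by_chrom[chrom]:
            counts[(s - 1) // window] += 1
        for w in range(n_windows):
            rows.append((chrom, w * window, int(counts[w])))
    return pd.DataFrame(rows, columns=["chrom", "start", "count"])


@dataclass
class PCAResult:
    individual_ids: list
    coordinates: np.ndarray  # individuals x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def genotype_pca(matrix: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of individuals from the dosage matrix.

    Missing calls are mean-imputed per variant, variants are centered by
    mean dosage, and the individual x individual covariance is
    eigendecomposed. Components are ordered by decreasing eigenvalue with
    the sign convention that each component's largest-magnitude loading is
    positive. Coordinates are eigenvectors scaled by sqrt(eigenvalue).
    """
    if matrix.n_individuals < 2:
        raise ValueError("need >= 2 individuals")
    X = matrix.dosage.astype(float)
    miss = X == MISSING
    X[miss] = np.nan
    row_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
    row_means = np.where(np.isnan(row_means), 0.0, row_means)
    inds = np.where(np.isnan(X))
    X[inds] = row_means[inds[0]]
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = max(matrix.n_variants - 1, 1)
    C = (Xc.T @ Xc) / denom
    if np.allclose(C, 0.0):
        raise ValueError("genotype matrix has zero variance")
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    k = min(n_components, len(eigvals))
    eigvals = np.clip(eigvals[order][:k], 0.0, None)
    eigvecs = eigvecs[:, order][:, :k]
    for j in range(k):
        if eigvecs[np.argmax(np.abs(eigvecs[:, j])), j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    coords = eigvecs * np.sqrt(eigvals)
    total = float(np.trace(C))
    return PCAResult(
        individual_ids=list(matrix.individual_ids),
        coordinates=coords,
        explained_variance=eigvals,
        explained_variance_ratio=eigvals / total if total > 0 else eigvals * 0.0,
    )


def afs_to_frame(spectra) -> pd.DataFrame:
    rows = []
    for sp in spectra:
        for i, cnt in enumerate(sp.counts):
            if i == 0:
                continue
            rows.append((sp.label, i, int(cnt)))
    return pd.DataFrame(rows, columns=["class", "minor_allele_count", "n_variants"])


def fst_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "theta_hat": [r.theta_hat for r in results],
            "defined": [r.defined for r in results],
        }
    )
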