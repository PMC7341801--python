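"""Synthetic two-clade diploid SV cohorts with ground truth.

The generator emulates the population-genetic structure the downstream
analyses assume: two deeply diverged clades (defaults: 8 and 24 diploids)
whose true variants are clade-private under the infinite-sites premise,
with minor-allele counts drawn from the neutral ~1/i spectrum for
interspersed and unannotated variants and from an intermediate-frequency
(symmetric Beta) model for hypermutable tandem-repeat loci. On top of the
truth it injects the two artifact modes the clade filter targets:
cross-clade false positives (intermediate-frequency, heterozygote-excess
polymorphisms segregating in both clades, the signature of collapsed
paralogs) and per-call genotyping error (uniform flips to one of the other
two dosage states). Every variant carries a truth label so each pipeline
stage can be scored.

All randomness flows from one integer seed fanned out into named
substreams, so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MISSING, ChromTable, CladeMap, GenotypeMatrix, RepeatMatch, SVRecord

#: default karyotype: macro- and microchromosomes plus a small chromosome
#: of ~1.4% of the assembly, mirroring an avian-like genome at reduced scale
DEFAULT_CHROMOSOMES = ChromTable(
    {
        "chr1": 150_000_000,
        "chr2": 120_000_000,
        "chr3": 100_000_000,
        "chr4": 80_000_000,
        "chr5": 60_000_000,
        "chr6": 40_000_000,
        "chr7": 30_000_000,
        "chr8": 25_000_000,
        "chr9": 20_000_000,
        "chr10": 15_000_000,
        "chr18": 10_000_000,
        "chrZ": 75_000_000,
    }
)

#: class mix of the four modelled repeat classes, renormalised from the
#: observed composition of a long-read avian SV call set (tandem 21.48,
#: LTR 23.53, LINE/CR1 2.27, no match 52.19 percent of all variants)
DEFAULT_CLASS_MIX = {
    "tandem": 0.215,
    "LTR": 0.236,
    "LINE/CR1": 0.023,
    "no_match": 0.526,
}

_REPEAT_NAMES = {
    "tandem": ["(TA)n", "(AAGG)n", "(CCCTAA)n", "A-rich"],
    "LTR": ["corLTRK1b", "corLTRK2", "corLTR-ERV1", "corLTRK3a"],
    "LINE/CR1": ["CR1-E1_cor", "CR1-J2_cor", "CR1-X1"],
}

_RM_CLASS = {"tandem": "Simple_repeat", "LTR": "LTR/ERVK", "LINE/CR1": "LINE/CR1"}

#: full-length LTR retrotransposon families produce characteristic length
#: peaks; (mean bp, sd bp, weight)
LTR_LENGTH_PEAKS = ((900.0, 90.0, 0.45), (2400.0, 240.0, 0.35), (6500.0, 650.0, 0.20))

MIN_SV_LEN = 51


@dataclass
class SimulationParams:
    """Study conditions of the synthetic cohort; defaults are the defaults."""

    n_clade_A: int = 8
    n_clade_B: int = 24
    m_variants: int = 10_000
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    fp_cross_clade_rate: float = 0.05
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    fp_end_bias: float = 0.9  # fraction of FPs placed in the outer 5% of a chromosome
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_variants < 1:
            raise ValueError("m_variants must be >= 1")
        if self.n_clade_A < 1 or self.n_clade_B < 1:
            raise ValueError("clade sizes must be positive")
        for name in ("fp_cross_clade_rate", "genotyping_error_rate", "missing_rate", "fp_end_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"class_mix must sum to 1, sums to {total}")


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces, truth included."""

    records: list
    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # variant_id, origin, repeat_class, true_length
    repeat_matches: list
    clade_map: CladeMap
    chrom_table: ChromTable
    true_dosage: np.ndarray  # pre-error, pre-missing dosages

    def __iter__(self):
        return iter((self.records, self.genotypes, self.truth, self.repeat_matches))


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _draw_one_over_i(rng: np.random.Generator, n_alleles: int) -> int:
    i = np.arange(1, n_alleles)
    w = 1.0 / i
    return int(rng.choice(i, p=w / w.sum()))


def _private_genotypes(rng: np.random.Generator, n: int, repeat_class: str) -> np.ndarray:
    """Dosages for a variant segregating in one clade of n diploids."""
    n_alleles = 2 * n
    if repeat_class == "tandem":
        # hypermutable loci converge to intermediate frequencies
        while True:
            p = rng.beta(2.0, 2.0)
            j = int(rng.binomial(n_alleles, p))
            if 1 <= j <= n_alleles - 1:
                break
    else:
        j = _draw_one_over_i(rng, n_alleles)
    chroms = np.zeros(n_alleles, dtype=np.int8)
    chroms[rng.choice(n_alleles, size=j, replace=False)] = 1
    return chroms.reshape(n, 2).sum(axis=1).astype(np.int8)


def _fp_genotypes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Cross-clade artifact dosages: intermediate frequency, het excess.

    Collapsed-paralog artifacts genotype as spurious heterozygotes across
    many individuals; a floor of ceil(n/3) heterozygotes per clade keeps
    every injected FP clearly polymorphic in both clades.
    """
    min_hets = math.ceil(n / 3)
    while True:
        p = rng.beta(5.0, 5.0)
        dos = rng.binomial(2, p, size=n).astype(np.int8)
        if int((dos == 1).sum()) >= min_hets:
            return dos


def _draw_lengths(rng: np.random.Generator, repeat_class: str, size: int) -> np.ndarray:
    if repeat_class == "LTR":
        means, sds, weights = zip(*LTR_LENGTH_PEAKS)
        comp = rng.choice(len(means), size=size, p=np.array(weights))
        vals = rng.normal(np.array(means)[comp], np.array(sds)[comp])
    elif repeat_class == "tandem":
        vals = rng.lognormal(mean=np.log(120.0), sigma=0.8, size=size)
    elif repeat_class == "LINE/CR1":
        vals = rng.lognormal(mean=np.log(500.0), sigma=0.7, size=size)
    else:
        vals = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=size)
    return np.maximum(MIN_SV_LEN, np.round(vals)).astype(np.int64)


def default_clade_map(params: SimulationParams) -> CladeMap:
    """Clade A split into two populations, clade B into three."""
    assignments: dict[str, tuple[str, str]] = {}
    for i in range(params.n_clade_A):
        pop = "A_pop1" if i < params.n_clade_A // 2 else "A_pop2"
        assignments[f"A{i + 1:02d}"] = (pop, "A")
    third = max(1, params.n_clade_B // 3)
    for i in range(params.n_clade_B):
        pop = f"B_pop{min(3, i // third + 1)}"
        assignments[f"B{i + 1:02d}"] = (pop, "B")
    return CladeMap(assignments)


def simulate_cohort(params: SimulationParams) -> SimulatedCohort:
    """Generate a two-clade SV cohort with full truth labels.

    Deterministic under a fixed ``params.seed``. With
    ``genotyping_error_rate == 0`` and ``fp_cross_clade_rate == 0`` every
    variant segregates in exactly one clade.
    """
    rngs = _substreams(
        params.seed,
        ("classes", "origins", "lengths", "positions", "genotypes", "errors", "missing", "repeats", "support"),
    )
    m = params.m_variants
    clade_map = default_clade_map(params)
    inds_A = clade_map.members("A")
    inds_B = clade_map.members("B")
    individuals = inds_A + inds_B
    nA, nB = len(inds_A), len(inds_B)

    classes = list(params.class_mix)
    probs = np.array([params.class_mix[c] for c in classes])
    var_class = rngs["classes"].choice(classes, size=m, p=probs)

    is_fp = rngs["origins"].random(m) < params.fp_cross_clade_rate
    focal = np.where(rngs["origins"].random(m) < 0.5, "A", "B")
    origin = np.where(is_fp, "cross_clade_FP", focal)

    svtype = rngs["classes"].choice(["INS", "DEL", "INV"], size=m, p=[0.555, 0.428, 0.017])

    lengths = np.empty(m, dtype=np.int64)
    for cls in classes:
        mask = var_class == cls
        lengths[mask] = _draw_lengths(rngs["lengths"], cls, int(mask.sum()))

    # positions: chromosome proportional to length; FPs biased toward ends
    chrom_table = DEFAULT_CHROMOSOMES
    chroms = list(chrom_table)
    clen = np.array([chrom_table[c] for c in chroms], dtype=float)
    chrom_idx = rngs["positions"].choice(len(chroms), size=m, p=clen / clen.sum())
    pos = np.empty(m, dtype=np.int64)
    for i in range(m):
        L = int(clen[chrom_idx[i]])
        span = max(1, L - int(lengths[i]) - 1)
        if is_fp[i] and rngs["positions"].random() < params.fp_end_bias:
            edge = max(2, int(0.05 * L))
            d = int(rngs["positions"].integers(1, edge))
            p0 = d if rngs["positions"].random() < 0.5 else max(1, L - int(lengths[i]) - d)
            pos[i] = min(max(1, p0), span)
        else:
            pos[i] = int(rngs["positions"].integers(1, span + 1))

    dosage = np.zeros((m, nA + nB), dtype=np.int8)
    grng = rngs["genotypes"]
    for i in range(m):
        if origin[i] == "cross_clade_FP":
            dosage[i, :nA] = _fp_genotypes(grng, nA)
            dosage[i, nA:] = _fp_genotypes(grng, nB)
        elif origin[i] == "A":
            dosage[i, :nA] = _private_genotypes(grng, nA, var_class[i])
        else:
            dosage[i, nA:] = _private_genotypes(grng, nB, var_class[i])
    true_dosage = dosage.copy()

    eps = params.genotyping_error_rate
    if eps > 0:
        flip = rngs["errors"].random(dosage.shape) < eps
        shift = 1 + (rngs["errors"].random(dosage.shape) < 0.5).astype(np.int8)
        dosage = np.where(flip, (dosage + shift) % 3, dosage).astype(np.int8)
    if params.missing_rate > 0:
        miss = rngs["missing"].random(dosage.shape) < params.missing_rate
        dosage = np.where(miss, np.int8(MISSING), dosage).astype(np.int8)

    order = np.lexsort((pos, chrom_idx))
    records: list[SVRecord] = []
    ids = []
    for rank, i in enumerate(order):
        vid = f"sv{rank:06d}"
        ids.append(vid)
        p0 = int(pos[i])
        L = int(lengths[i])
        st = str(svtype[i])
        end = p0 if st == "INS" else p0 + L - 1
        support = int(min(60, max(5, rngs["support"].poisson(18) + 2)))
        records.append(
            SVRecord(
                chrom=chroms[chrom_idx[i]],
                pos=p0,
                id=vid,
                svtype=st,
                svlen=L,
                end=end,
                support=support,
            )
        )
    dosage = dosage[order]
    true_dosage = true_dosage[order]
    matrix = GenotypeMatrix(ids, individuals, dosage)

    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "origin": np.asarray(origin)[order],
            "repeat_class": np.asarray(var_class)[order],
            "true_length": lengths[order],
        }
    )

    matches: list[RepeatMatch] = []
    rrng = rngs["repeats"]
    for vid, cls, L in zip(ids, truth["repeat_class"], truth["true_length"]):
        if cls == "no_match":
            continue
        true_overlap = int(max(1, round(rrng.uniform(0.6, 1.0) * L)))
        names = _REPEAT_NAMES[cls]
        matches.append(
            RepeatMatch(
                variant_id=vid,
                repeat_name=str(rrng.choice(names)),
                repeat_class=cls,
                overlap_bp=true_overlap,
                score=float(np.round(true_overlap * rrng.uniform(1.5, 2.5), 1)),
            )
        )
        for _ in range(int(rrng.integers(0, 3))):
            decoy_cls = str(rrng.choice([c for c in _REPEAT_NAMES if c != cls]))
            decoy_overlap = int(max(1, round(true_overlap * rrng.uniform(0.1, 0.9))))
            matches.append(
                RepeatMatch(
                    variant_id=vid,
                    repeat_name=str(rrng.choice(_REPEAT_NAMES[decoy_cls])),
                    repeat_class=decoy_cls,
                    overlap_bp=decoy_overlap,
                    score=float(np.round(decoy_overlap * rrng.uniform(1.0, 2.0), 1)),
                )
            )

    return SimulatedCohort(
        records=records,
        genotypes=matrix,
        truth=truth,
        repeat_matches=matches,
        clade_map=clade_map,
        chrom_table=DEFAULT_CHROMOSOMES,
        true_dosage=true_dosage,
    )


def make_caller_replicates(
    records,
    n_callers: int = 3,
    jitter_sd: float = 50.0,
    dropout: float = 0.1,
    seed: int = 0,
):
    """Emulate independent SV callers on the same sample.

    Each pseudo-caller re-reports every record with breakpoint jitter
    (Gaussian, sd ``jitter_sd`` bp) and per-record dropout. Returns a list
    of :class:`svclade.merge.CallerCallSet`.
    """
    from .merge import CallerCallSet

    rng = np.random.default_rng(seed)
    call_sets = []
    for c in range(n_callers):
        recs = []
        for r in records:
            if rng.random() < dropout:
                continue
            shift = int(round(rng.normal(0.0, jitter_sd)))
            p0 = max(1, r.pos + shift)
            end = p0 if r.svtype == "INS" else p0 + r.svlen - 1
            recs.append(
                SVRecord(
                    chrom=r.chrom,
                    pos=p0,
                    id=f"{r.id}.c{c}",
                    svtype=r.svtype,
                    svlen=r.svlen,
                    end=end,
                    seq=r.seq,
                    support=r.support,
                )
            )
        recs.sort(key=lambda r: (r.chrom, r.pos))
        call_sets.append(CallerCallSet(caller=f"caller{c + 1}", records=recs))
    return call_sets


_BASES = np.array(list("ACGT"))


def simulate_ltr_pair(
    age_myr: float,
    ltr_len: int = 296,
    rate_per_site_per_myr: float = 0.0158,
    seed: int | None = None,
) -> tuple[str, str]:
    """Two terminal repeats of one retrotransposon insertion, aged ``age_myr``.

    The repeats are identical at insertion and each accumulates neutral
    substitutions independently, so the pairwise difference count is
    Poisson with mean 2 * mu * L * t. Saturation is not modelled: an
    expected difference count exceeding L raises.
    """
    if age_myr < 0:
        raise ValueError("age must be >= 0")
    if ltr_len < 1:
        raise ValueError("ltr_len must be >= 1")
    if rate_per_site_per_myr <= 0:
        raise ValueError("substitution rate must be > 0")
    expected = 2.0 * rate_per_site_per_myr * ltr_len * age_myr
    if expected > ltr_len:
        raise ValueError(f"expected differences {expected:.1f} exceed LTR length {ltr_len}")
    rng = np.random.default_rng(seed)
    left = rng.choice(_BASES, size=ltr_len)
    right = left.copy()
    k = min(int(rng.poisson(expected)), ltr_len)
    if k:
        sites = rng.choice(ltr_len, size=k, replace=False)
        for s in sites:
            choices = [b for b in "ACGT" if b != left[s]]
            right[s] = rng.choice(choices)
    return "".join(left), "".join(right)


def simulate_phenotypes(
    dosages,
    additive_effect: float,
    dominance_effect: float,
    noise_sd: float,
    seed: int | None = None,
    individual_ids=None,
) -> pd.DataFrame:
    """Per-individual phenotype y = b_a*additive + b_d*dominance + N(0, sd).

    ``dosages`` is a vector of {0,1,2,MISSING} for one variant; MISSING
    individuals are dropped. additive is the dosage itself, dominance the
    heterozygote indicator.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (np.isfinite(additive_effect) and np.isfinite(dominance_effect)):
        raise ValueError("effects must be finite")
    dos = np.asarray(dosages, dtype=int)
    if individual_ids is None:
        individual_ids = [f"ind{i + 1}" for i in range(len(dos))]
    keep = dos != MISSING
    dos = dos[keep]
    ids = [s for s, k in zip(individual_ids, keep) if k]
    rng = np.random.default_rng(seed)
    additive = dos.astype(float)
    dominance = (dos == 1).astype(float)
    y = additive_effect * additive + dominance_effect * dominance
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(dos))
    return pd.DataFrame(
        {"individual": ids, "additive": additive, "dominance": dominance, "phenotype": y}
    )
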