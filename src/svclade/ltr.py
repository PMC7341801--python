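"""LTR retrotransposon insertion dating from terminal-repeat divergence.

The two long terminal repeats flanking a full-length LTR retrotransposon
are identical at the moment of insertion; each subsequently accumulates
neutral substitutions independently. With k observed differences over an
effective repeat length of L sites and a neutral substitution rate of mu
per site per million years, the insertion age is

    t = k / (2 * mu * L)   [Myr]

Because some apparent differences may still be segregating rather than
fixed, the estimate is an upper bound on the true age.

Difference counting follows the substitutions-plus-1-bp-indels rule:
mismatched non-gap alignment columns each count once, an isolated
single-base gap (in either sequence) counts once, and gap runs of two or
more bases are excluded from both k and the effective length L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DatingParams:
    """mu: neutral substitution rate per site per million years."""

    mu: float = 0.0158

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")


@dataclass
class LTRPair:
    left: str
    right: str
    L: int  # effective aligned length (gap runs >= 2 bp excluded)
    k: int  # substitutions + isolated 1-bp indels

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0 <= self.k <= self.L:
            raise ValueError("k must satisfy 0 <= k <= L")


@dataclass
class AgeEstimate:
    age_myr: float
    age_years: float
    k: int
    L: int
    mu: float


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def count_ltr_differences(left_aligned: str, right_aligned: str) -> LTRPair:
    """Count differences between two aligned terminal repeats.

    Both strings must be the same length with gaps as '-'. Returns the
    pair with k (substitutions + isolated 1-bp gap events) and the
    effective length L (columns not inside a >= 2 bp gap run).
    """
    if len(left_aligned) != len(right_aligned):
        raise ValueError("aligned sequences must be equal length")
    if not left_aligned:
        raise ValueError("empty alignment")
    n = len(left_aligned)
    excluded = np.zeros(n, dtype=bool)
    k = 0
    for seq in (left_aligned, right_aligned):
        for start, end in _gap_runs(seq):
            if end - start >= 2:
                excluded[start:end] = True
            else:
                k += 1  # isolated single-base indel event
    for i in range(n):
        if excluded[i]:
            continue
        a, b = left_aligned[i], right_aligned[i]
        if a != "-" and b != "-" and a.upper() != b.upper():
            k += 1
    L = int(n - excluded.sum())
    if L < 1:
        raise ValueError("no alignment columns left after excluding gap runs")
    return LTRPair(left=left_aligned, right=right_aligned, L=L, k=k)


def estimate_insertion_age(k: int, L: int, params: DatingParams | float = DatingParams()) -> AgeEstimate:
    """Insertion age t = k / (2 * mu * L), in Myr and years (upper bound)."""
    mu = params.mu if isinstance(params, DatingParams) else float(params)
    if L < 1:
        raise ValueError("L must be >= 1")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if not 0 <= k <= L:
        raise ValueError("k must satisfy 0 <= k <= L")
    age = k / (L * 2.0 * mu)
    return AgeEstimate(age_myr=age, age_years=age * 1e6, k=k, L=L, mu=mu)


def align_ltr_pair(left: str, right: str) -> tuple[str, str]:
    """Global pairwise alignment of two short terminal-repeat sequences."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(left, right)[0]
    return str(aln[0]), str(aln[1])
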