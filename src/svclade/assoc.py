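"""Genotype–phenotype association with additive/dominance decomposition.

A diploid locus's effect is decomposed into an additive component (the
count of non-inserted minor-allele copies, 0/1/2, as a covariate) and a
dominance component (heterozygote indicator, homozygous = 0,
heterozygous = 1). Models are ordinary least squares fits compared by
small-sample-corrected AIC (AICc) and BIC, with a delta-AICc >= 2 rule
for selecting the candidate model. The information-criterion parameter
count p includes the intercept and the residual variance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import MISSING

logger = logging.getLogger(__name__)


@dataclass
class CodedGenotypes:
    individual_ids: list
    additive: np.ndarray  # copies of the non-inserted allele, 0/1/2
    dominance: np.ndarray  # heterozygote indicator

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"individual": self.individual_ids, "additive": self.additive, "dominance": self.dominance}
        )


def code_genotypes(dosages, insertion_is_reference: bool = True, individual_ids=None) -> CodedGenotypes:
    """Additive/dominance coding of diploid dosages at one insertion locus.

    ``dosages`` counts alt-allele copies. When the insertion allele is the
    reference (the locus was called as a deletion relative to an
    insertion-bearing reference), the alt dosage already counts
    non-inserted copies; otherwise additive = 2 - dosage. Flipping
    ``insertion_is_reference`` maps additive a -> 2 - a and leaves
    dominance unchanged. MISSING individuals are dropped (logged).
    """
    dos = np.asarray(dosages, dtype=int)
    if individual_ids is None:
        individual_ids = [f"ind{i + 1}" for i in range(len(dos))]
    keep = dos != MISSING
    dropped = int((~keep).sum())
    if dropped:
        logger.info("code_genotypes: dropped %d individuals with missing genotype", dropped)
    dos = dos[keep]
    ids = [s for s, k in zip(individual_ids, keep) if k]
    additive = dos if insertion_is_reference else 2 - dos
    dominance = (dos == 1).astype(int)
    return CodedGenotypes(ids, additive.astype(int), dominance)


@dataclass
class ModelFit:
    """An OLS fit with Gaussian log-likelihood and information criteria."""

    labels: tuple
    n: int
    p: int  # coefficients + intercept + residual variance
    loglik: float
    aic: float
    aicc: float
    bic: float
    r_squared: float
    coef: pd.DataFrame  # term, estimate, se, t, p_value


def fit_linear_model(response, design: pd.DataFrame, add_intercept: bool = True) -> ModelFit:
    """Ordinary least squares of ``response`` on the design columns.

    AIC = 2p - 2 lnL; AICc = AIC + 2p(p+1)/(n-p-1); BIC = p ln n - 2 lnL,
    with p counting every mean parameter plus the error variance. A
    rank-deficient design raises, naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    X = design.astype(float).copy()
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        keep: list[str] = []
        collinear: list[str] = []
        for col in X.columns:
            trial = X[keep + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(col)
            else:
                collinear.append(col)
        raise ValueError(f"design is rank-deficient; collinear columns: {collinear}")
    n = len(y)
    p = X.shape[1] + 1  # + residual variance
    if n <= p:
        raise ValueError(f"n = {n} must exceed parameter count p = {p}")
    res = sm.OLS(y, X).fit()
    llf = float(res.llf)
    aic = 2 * p - 2 * llf
    aicc = aic + (2 * p * (p + 1)) / (n - p - 1)
    bic = p * math.log(n) - 2 * llf
    coef = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p_value": res.pvalues.to_numpy(),
        }
    )
    return ModelFit(
        labels=tuple(design.columns),
        n=n,
        p=p,
        loglik=llf,
        aic=aic,
        aicc=aicc,
        bic=bic,
        r_squared=float(res.rsquared),
        coef=coef,
    )


@dataclass
class ModelComparison:
    delta_aicc: float  # AICc(baseline) - AICc(candidate)
    delta_bic: float
    candidate_selected: bool
    bic_agrees: bool


def compare_models(fit_candidate: ModelFit, fit_baseline: ModelFit, aicc_threshold: float = 2.0) -> ModelComparison:
    """Select the candidate model iff delta-AICc >= threshold.

    delta-AICc = AICc(baseline) - AICc(candidate); the BIC verdict is
    reported alongside and may disagree. Both fits must be on the same
    response subset (equal n).
    """
    if fit_candidate.n != fit_baseline.n:
        raise ValueError("model comparison requires fits on the same subset (equal n)")
    d_aicc = fit_baseline.aicc - fit_candidate.aicc
    d_bic = fit_baseline.bic - fit_candidate.bic
    selected = d_aicc >= aicc_threshold
    return ModelComparison(
        delta_aicc=d_aicc,
        delta_bic=d_bic,
        candidate_selected=selected,
        bic_agrees=(d_bic >= 0) == (d_aicc >= 0),
    )


def expression_association(
    expression,
    coded: CodedGenotypes,
    include_dominance: bool = False,
) -> ModelFit:
    """OLS of normalized expression on the additive (+ dominance) coding."""
    y = np.asarray(expression, dtype=float)
    if len(y) != len(coded.additive):
        raise ValueError("expression and genotype lengths differ")
    if len(y) < 3:
        raise ValueError("need >= 3 individuals")
    if len(np.unique(coded.additive)) < 2:
        raise ValueError("need >= 2 genotype classes")
    design = pd.DataFrame({"additive": coded.additive})
    if include_dominance:
        design["dominance"] = coded.dominance
    return fit_linear_model(y, design)
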