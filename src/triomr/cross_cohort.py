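"""Fixed-effects pooling across cohorts and the pooled two-stage IV ratio.

Cohort results are combined by inverse-variance-weighted fixed-effects
meta-analysis with Cochran's Q and I^2 for heterogeneity.  The pooled
MR estimate follows the two-stage recipe: pool the stage-1 coefficients
(maternal score -> maternal BMI) and the stage-2 coefficients (maternal
score -> offspring outcome) separately across cohorts, then take their
ratio, with a first-order Taylor-series SE

    SE = sqrt(se2^2 / b1^2 + b2^2 * se1^2 / b1^4).

The Taylor SE omits the covariance between the two stage coefficients
(they are estimated on the same subjects within a cohort); this is a
documented approximation, flagged in the result label and checked by
simulation against individual-level TSLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EffectEstimate, _Z975
from .mr_summary import _ivw

log = logging.getLogger(__name__)

TAYLOR_SE_NOTE = "taylor_se_omits_stage_covariance"


@dataclass
class MetaResult:
    """A pooled estimate with heterogeneity statistics."""

    estimate: EffectEstimate
    q: float
    i2: float
    k: int


@dataclass
class CohortStageEstimates:
    """Per-cohort first- and second-stage IV regression coefficients.

    Stage 1: maternal allele score -> maternal BMI (optionally
    offspring-score-adjusted).  Stage 2: maternal allele score ->
    offspring outcome (same adjustment).  Both per unit of the same
    score so they are poolable across cohorts.
    """

    cohort: str
    beta_stage1: float
    se_stage1: float
    beta_stage2: float
    se_stage2: float
    n: int

    def __post_init__(self) -> None:
        if self.se_stage1 < 0 or self.se_stage2 < 0:
            raise ValueError("stage SEs must be non-negative")


def fe_meta(estimates: list[EffectEstimate], label: str = "fe_meta") -> MetaResult:
    """Inverse-variance-weighted fixed-effects meta-analysis with Q and I^2."""
    if not estimates:
        raise ValueError("no estimates to pool")
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all SEs must be positive for inverse-variance pooling")
    pooled, se, q, i2 = _ivw(betas, ses)
    n = sum(e.n for e in estimates) if all(e.n is not None for e in estimates) else None
    est = EffectEstimate(pooled, se, pooled - _Z975 * se, pooled + _Z975 * se,
                         n=n, df=None, label=label)
    return MetaResult(estimate=est, q=q, i2=i2, k=len(estimates))


def pooled_iv_ratio(stages: list[CohortStageEstimates]) -> EffectEstimate:
    """Pooled MR causal effect: pooled stage-2 over pooled stage-1.

    With a single cohort this reduces to that cohort's Wald ratio from
    the same two regressions.  SEs of exactly zero are treated as the
    limiting case of a degenerate (infinitely precise) stage.
    """
    if not stages:
        raise ValueError("no cohort stage estimates supplied")

    def pool(betas, ses):
        betas, ses = np.asarray(betas, float), np.asarray(ses, float)
        if np.any(ses == 0):
            # degenerate stage: the zero-SE estimate dominates entirely
            keep = ses == 0
            if not np.allclose(betas[keep], betas[keep][0]):
                raise ValueError("conflicting zero-SE stage estimates")
            return float(betas[keep][0]), 0.0
        pooled, se, _, _ = _ivw(betas, ses)
        return pooled, se

    b1, se1 = pool([s.beta_stage1 for s in stages], [s.se_stage1 for s in stages])
    b2, se2 = pool([s.beta_stage2 for s in stages], [s.se_stage2 for s in stages])
    if b1 == 0:
        raise ValueError("pooled stage-1 coefficient is zero; ratio undefined")
    ratio = b2 / b1
    se = float(np.sqrt(se2 ** 2 / b1 ** 2 + b2 ** 2 * se1 ** 2 / b1 ** 4))
    n = sum(s.n for s in stages)
    return EffectEstimate(ratio, se, ratio - _Z975 * se, ratio + _Z975 * se,
                          n=n, df=None,
                          label=f"pooled_iv_ratio[{TAYLOR_SE_NOTE}]")


def cohort_stage_estimates(cohort, label: str = "cohort",
                           adjust_offspring_score: bool = True,
                           covariates=None) -> CohortStageEstimates:
    """Compute the two stage regressions for one (simulated) trio cohort.

    Stage 1 regresses maternal BMI on the maternal weighted score;
    stage 2 regresses the offspring outcome on the maternal weighted
    score; both optionally adjust for the offspring weighted score.
    """
    from .estimators import ols_fit

    zm = cohort.maternal_score()
    covs = None
    if adjust_offspring_score:
        covs = pd.DataFrame({"offspring_score": cohort.offspring_score()})
        if covariates is not None:
            covs = pd.concat([covs, pd.DataFrame(covariates)], axis=1)
    elif covariates is not None:
        covs = pd.DataFrame(covariates)
    s1 = ols_fit(cohort.x_m, zm, covariates=covs, label="stage1")
    s2 = ols_fit(cohort.y_o, zm, covariates=covs, label="stage2")
    return CohortStageEstimates(label, s1.beta, s1.se, s2.beta, s2.se,
                                n=cohort.n_families)


def read_stage_tsv(path) -> list[CohortStageEstimates]:
    """Read cohort stage estimates from a long TSV
    (cohort, stage, beta, se, n) with stage in {1, 2}."""
    df = pd.read_csv(path, sep="\t")
    need = ["cohort", "stage", "beta", "se", "n"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"stage-estimate file {path} is missing columns {missing}")
    out = []
    for cohort, grp in df.groupby("cohort", sort=False):
        by_stage = {int(r.stage): r for r in grp.itertuples()}
        if set(by_stage) != {1, 2}:
            raise ValueError(f"cohort {cohort!r} must have exactly stages 1 and 2")
        out.append(CohortStageEstimates(str(cohort),
                                        by_stage[1].beta, by_stage[1].se,
                                        by_stage[2].beta, by_stage[2].se,
                                        int(by_stage[1].n)))
    return out


def write_stage_tsv(stages: list[CohortStageEstimates], path) -> None:
    rows = []
    for s in stages:
        rows.append({"cohort": s.cohort, "stage": 1, "beta": s.beta_stage1,
                     "se": s.se_stage1, "n": s.n})
        rows.append({"cohort": s.cohort, "stage": 2, "beta": s.beta_stage2,
                     "se": s.se_stage2, "n": s.n})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
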