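"""Estimator-recovery simulation study and the non-transmitted
haplotype analysis.

Adjusting the maternal-score IV model for the offspring allele score is
necessary to block genetic transmission, but the offspring genotype is
a collider between the parental genotypes: conditioning on it induces a
negative dependence between the maternal and (unmeasured) paternal
scores, so any paternal-phenotype effect on the offspring outcome
(beta_pat > 0) biases the offspring-adjusted IV estimate toward the
null.  This module quantifies that bias by simulation — running each
estimator over many replicate cohorts and aggregating bias, empirical
SD, mean model SE and CI coverage — and implements the transmission-
free alternative: regression on the maternal non-transmitted haplotype
score, which cannot reach the offspring through inheritance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import score_builder
from .estimators import EffectEstimate, ols_fit, tsls_fit, _Z975
from .synthetic_trios import SimScenario, TrioCohort, replicate, simulate_cohort

log = logging.getLogger(__name__)

ESTIMATORS = ("ols_adjusted", "iv_unadjusted", "iv_offspring",
              "iv_offspring_paternal", "non_transmitted")


@dataclass
class SimStudyResult:
    """Aggregated estimator performance over replicate cohorts.

    ``table`` has one row per scenario x estimator: mean estimate,
    empirical SD, mean model SE, bias vs beta_int, 95% CI coverage, the
    Monte-Carlo SE of the mean, and the replicate count.  ``seeds``
    records the per-replicate RNG seeds for auditability.
    """

    table: pd.DataFrame
    seeds: pd.DataFrame


def _fit_estimator(cohort: TrioCohort, estimator: str) -> EffectEstimate:
    y, x = cohort.y_o, cohort.x_m
    zm = cohort.maternal_score()
    if estimator == "ols_adjusted":
        covs = cohort.covariates()
        return ols_fit(y, x, covariates=covs if covs.shape[1] else None,
                       label=estimator)
    if estimator == "iv_unadjusted":
        est, _ = tsls_fit(y, x, zm, label=estimator)
        return est
    if estimator == "iv_offspring":
        est, _ = tsls_fit(y, x, zm,
                          covariates=cohort.offspring_score()[:, None],
                          label=estimator)
        return est
    if estimator == "iv_offspring_paternal":
        covs = np.column_stack([cohort.offspring_score(), cohort.paternal_score()])
        est, _ = tsls_fit(y, x, zm, covariates=covs, label=estimator)
        return est
    if estimator == "non_transmitted":
        # transmission-free instrument: the maternal non-transmitted
        # haplotype score reaches the offspring only through X_m, so no
        # offspring-score adjustment (and no collider) is needed
        _, nt = score_builder.haplotype_scores(
            cohort.maternal_h1, cohort.maternal_h2,
            cohort.maternal_transmitted_index, cohort.panel)
        est, _ = tsls_fit(y, x, nt, label=estimator)
        return est
    raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")


def run_sim_study(scenarios: list[SimScenario], reps: int,
                  estimators=ESTIMATORS, seed: int = 0) -> SimStudyResult:
    """Fit each estimator over ``reps`` independent replicate cohorts
    per scenario and aggregate.  Deterministic given ``seed``."""
    if reps < 50:
        raise ValueError("reps must be >= 50")
    for est in estimators:
        if est not in ESTIMATORS:
            raise ValueError(f"unknown estimator {est!r}; choose from {ESTIMATORS}")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2 ** 31 - 1, size=(len(scenarios), reps))
    rows, seed_rows = [], []
    for i, scenario in enumerate(scenarios):
        betas = {e: np.empty(reps) for e in estimators}
        ses = {e: np.empty(reps) for e in estimators}
        covers = {e: np.empty(reps, dtype=bool) for e in estimators}
        for r in range(reps):
            s = int(rep_seeds[i, r])
            seed_rows.append({"scenario": i, "rep": r, "seed": s})
            cohort = simulate_cohort(replicate(scenario, s))
            for e in estimators:
                fit = _fit_estimator(cohort, e)
                betas[e][r] = fit.beta
                ses[e][r] = fit.se
                covers[e][r] = fit.ci_low <= scenario.beta_int <= fit.ci_high
        for e in estimators:
            emp_sd = float(np.std(betas[e], ddof=1))
            rows.append({
                "scenario": i,
                "beta_int": scenario.beta_int,
                "beta_pat": scenario.beta_pat,
                "n_families": scenario.n_families,
                "estimator": e,
                "mean": float(np.mean(betas[e])),
                "empirical_sd": emp_sd,
                "mean_se": float(np.mean(ses[e])),
                "bias": float(np.mean(betas[e]) - scenario.beta_int),
                "coverage": float(np.mean(covers[e])),
                "mc_se": emp_sd / np.sqrt(reps),
                "reps": reps,
            })
    return SimStudyResult(table=pd.DataFrame(rows), seeds=pd.DataFrame(seed_rows))


def non_transmitted_regression(cohort: TrioCohort
                               ) -> tuple[EffectEstimate, EffectEstimate]:
    """Joint regression of the offspring outcome on the transmitted and
    non-transmitted maternal haplotype scores.

    Both scores are empirically standardised so the coefficients are SD
    change in outcome per SD of score.  A transmitted-score association
    with a null non-transmitted score indicates offspring-genotype
    effects without an intrauterine (maternal phenotype) effect; an
    intrauterine effect makes both nonzero, since both haplotypes act
    on the maternal phenotype.
    """
    t_score, nt_score = score_builder.haplotype_scores(
        cohort.maternal_h1, cohort.maternal_h2,
        cohort.maternal_transmitted_index, cohort.panel)

    def zscore(a):
        sd = np.std(a, ddof=1)
        if sd == 0:
            raise ValueError("haplotype score has zero variance")
        return (a - np.mean(a)) / sd

    n = cohort.n_families
    design = np.column_stack([np.ones(n), zscore(t_score), zscore(nt_score)])
    res = sm.OLS(cohort.y_o, design).fit()
    out = []
    for i, lab in ((1, "transmitted"), (2, "non_transmitted")):
        b, se = float(res.params[i]), float(res.bse[i])
        out.append(EffectEstimate(b, se, b - _Z975 * se, b + _Z975 * se,
                                  n=n, df=n - 3, label=lab))
    return out[0], out[1]
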