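"""Synthetic mother-father-offspring cohorts for intergenerational MR.

The generator reproduces the statistical structure the analysis relies
on: unlinked biallelic SNPs in Hardy-Weinberg proportions, Mendelian
transmission of one maternal and one paternal haplotype per locus, a
maternal polygenic score that explains a tunable fraction ``rho2_m`` of
maternal BMI variance (the paper-scale default is 2.2%), a tunable
intrauterine causal effect ``beta_int`` of maternal BMI on the
offspring outcome, a direct offspring-genotype effect ``lambda_o``, an
optional paternal-phenotype path ``beta_pat`` (which opens the collider
when the offspring score is conditioned on), and a shared family
confounder.

All phenotypes are generated directly on the SD scale, so ``beta_int``
is directly comparable to MR estimates expressed as SD change in
offspring outcome per SD of maternal BMI.

Structural model (scores Z* are the weighted allele scores centred and
scaled by their theoretical Hardy-Weinberg moments):

    X_m = sqrt(rho2_m) * Z*_m + c_x * C + e_x        Var(X_m) = 1
    X_f = sqrt(rho2_m) * Z*_f + c_x * C + e_f        Var(X_f) = 1
    Y_o = beta_int * X_m + lambda_o * Z*_o + beta_pat * X_f
          + c_y * C + delta * P_m + e_y              Var(Y_o) = 1

where C ~ N(0,1) is shared within family, ``delta`` is an optional
constant per-allele direct (pleiotropic) effect of the maternal
genotype on the outcome with P_m the centred maternal allele count, and
residual variances are solved so each phenotype has unit variance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .score_builder import SNPPanel

log = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


def default_panel(n_snps: int = 32, seed: int = 7) -> SNPPanel:
    """A synthetic GWAS-style BMI panel.

    Per-allele weights are drawn uniformly in [0.02, 0.10] SD per allele
    and effect-allele frequencies uniformly in [0.10, 0.90], bracketing
    the published BMI hits the real 32- and 97-SNP scores are built
    from.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    weight = rng.uniform(0.02, 0.10, n_snps)
    freq = rng.uniform(0.10, 0.90, n_snps)
    ids = [f"rs{1000000 + 37 * i}" for i in range(n_snps)]
    eff, oth = [], []
    for _ in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        eff.append(_BASES[a])
        oth.append(_BASES[b])
    return SNPPanel(ids, eff, oth, weight, freq)


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for one simulated trio cohort.

    beta_int : intrauterine causal effect of maternal BMI on the
        offspring outcome (SD per SD); the quantity MR estimates target.
    lambda_o : direct effect of the offspring's own standardised allele
        score on the outcome (SD per score SD).
    beta_pat : effect of the paternal phenotype on the offspring outcome
        (SD per SD); any nonzero value opens the collider path once the
        offspring score is adjusted for.
    rho2_m : fraction of maternal (and paternal) phenotype variance
        explained by the standardised allele score.
    c_x, c_y : loadings of the shared family confounder on the parental
        phenotypes and the offspring outcome.
    pleiotropy_delta : constant per-allele direct effect of the maternal
        genotype on the outcome (directional pleiotropy; default 0).
    confounder_observed : whether C is exported to the observed
        covariate table (confounded vs adjustable analyses).
    """

    n_families: int
    panel: SNPPanel
    beta_int: float = 0.0
    lambda_o: float = 0.15
    beta_pat: float = 0.0
    rho2_m: float = 0.022
    c_x: float = 0.3
    c_y: float = 0.3
    confounder_observed: bool = False
    pleiotropy_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.rho2_m < 1.0:
            raise ValueError("rho2_m must lie in [0, 1)")
        if self.rho2_m + self.c_x ** 2 > 1.0 + 1e-12:
            raise ValueError(
                "variance budget exceeded: rho2_m + c_x^2 must be <= 1 "
                f"(got {self.rho2_m + self.c_x ** 2:.4f})")

    def outcome_explained_variance(self) -> float:
        """Variance of Y_o contributed by the structural terms.

        Exact under the generative model (unlinked loci, random mating);
        used to solve the residual outcome variance so Var(Y_o) = 1.
        """
        a, l, b = self.beta_int, self.lambda_o, self.beta_pat
        cy, cx = self.c_y, self.c_x
        r = np.sqrt(self.rho2_m)
        d = self.pleiotropy_delta
        p, w = self.panel.freq, self.panel.weight
        sd_z = self.panel.score_sd
        # cov(P_m, Z*_m) for the centred unweighted maternal allele count
        c_pz = float(np.sum(w * 2.0 * p * (1.0 - p))) / sd_z
        v_p = float(np.sum(2.0 * p * (1.0 - p)))
        var = (a * a + l * l + b * b + cy * cy
               + 2.0 * a * l * (r * 0.5)          # cov(X_m, Z*_o)
               + 2.0 * a * b * (cx * cx)          # cov(X_m, X_f) via shared C
               + 2.0 * a * cy * cx                # cov(X_m, C)
               + 2.0 * l * b * (r * 0.5)          # cov(Z*_o, X_f)
               + 2.0 * b * cy * cx                # cov(X_f, C)
               + d * d * v_p
               + 2.0 * d * (a * r * c_pz + l * 0.5 * c_pz))
        return var


@dataclass
class TrioCohort:
    """Phased trio genotypes, transmissions and SD-scale phenotypes.

    Haplotype arrays are (n_families, n_snps) with effect-allele coded
    alleles in {0,1}; transmitted-index arrays record which parental
    haplotype (0 = hap1, 1 = hap2) went to the offspring, so Mendelian
    consistency is testable per record.
    """

    panel: SNPPanel
    maternal_h1: np.ndarray
    maternal_h2: np.ndarray
    paternal_h1: np.ndarray
    paternal_h2: np.ndarray
    maternal_transmitted_index: np.ndarray
    paternal_transmitted_index: np.ndarray
    offspring_genotype: np.ndarray
    x_m: np.ndarray
    x_f: np.ndarray
    y_o: np.ndarray
    confounder: np.ndarray
    confounder_observed: bool = False

    @property
    def n_families(self) -> int:
        return self.maternal_h1.shape[0]

    @property
    def n_snps(self) -> int:
        return self.panel.n_snps

    @property
    def family_id(self) -> np.ndarray:
        return np.array([f"FAM{i + 1:06d}" for i in range(self.n_families)])

    @property
    def mother_id(self) -> np.ndarray:
        return np.array([f"M{i + 1:06d}" for i in range(self.n_families)])

    @property
    def father_id(self) -> np.ndarray:
        return np.array([f"F{i + 1:06d}" for i in range(self.n_families)])

    @property
    def child_id(self) -> np.ndarray:
        return np.array([f"O{i + 1:06d}" for i in range(self.n_families)])

    @property
    def maternal_genotype(self) -> np.ndarray:
        return self.maternal_h1 + self.maternal_h2

    @property
    def paternal_genotype(self) -> np.ndarray:
        return self.paternal_h1 + self.paternal_h2

    @property
    def maternal_transmitted_allele(self) -> np.ndarray:
        return np.where(self.maternal_transmitted_index == 1,
                        self.maternal_h2, self.maternal_h1)

    @property
    def maternal_nontransmitted_allele(self) -> np.ndarray:
        return np.where(self.maternal_transmitted_index == 1,
                        self.maternal_h1, self.maternal_h2)

    @property
    def paternal_transmitted_allele(self) -> np.ndarray:
        return np.where(self.paternal_transmitted_index == 1,
                        self.paternal_h2, self.paternal_h1)

    def covariates(self) -> pd.DataFrame:
        """Observed covariate table (confounder only if exported)."""
        df = pd.DataFrame(index=range(self.n_families))
        if self.confounder_observed:
            df["confounder"] = self.confounder
        return df

    # Raw weighted scores; analyses are invariant to instrument scale.
    def maternal_score(self) -> np.ndarray:
        return self.maternal_genotype @ self.panel.weight

    def paternal_score(self) -> np.ndarray:
        return self.paternal_genotype @ self.panel.weight

    def offspring_score(self) -> np.ndarray:
        return self.offspring_genotype @ self.panel.weight

    def standardised_score(self, genotype: np.ndarray) -> np.ndarray:
        """Score centred/scaled by theoretical Hardy-Weinberg moments."""
        return (genotype @ self.panel.weight - self.panel.score_mean) / self.panel.score_sd


def simulate_cohort(scenario: SimScenario) -> TrioCohort:
    """Generate a trio cohort under the structural model. Deterministic given seed."""
    panel = scenario.panel
    n, m = scenario.n_families, panel.n_snps
    explained = scenario.outcome_explained_variance()
    if explained > 1.0 + 1e-9:
        raise ValueError(
            "variance budget exceeded: structural terms explain "
            f"{explained:.3f} > 1 of the outcome variance; reduce effect sizes")
    rng = np.random.default_rng(scenario.seed)
    p = panel.freq

    def haplotype() -> np.ndarray:
        return (rng.random((n, m)) < p).astype(np.int8)

    m1, m2 = haplotype(), haplotype()
    f1, f2 = haplotype(), haplotype()
    tm = rng.integers(0, 2, size=(n, m), dtype=np.int8)
    tf = rng.integers(0, 2, size=(n, m), dtype=np.int8)
    mat_t = np.where(tm == 1, m2, m1)
    pat_t = np.where(tf == 1, f2, f1)
    offspring = (mat_t + pat_t).astype(np.int8)

    mu, sd = panel.score_mean, panel.score_sd
    z_m = ((m1 + m2) @ panel.weight - mu) / sd
    z_f = ((f1 + f2) @ panel.weight - mu) / sd
    z_o = (offspring @ panel.weight - mu) / sd

    c = rng.standard_normal(n)
    r = np.sqrt(scenario.rho2_m)
    e_sd = np.sqrt(max(0.0, 1.0 - scenario.rho2_m - scenario.c_x ** 2))
    x_m = r * z_m + scenario.c_x * c + e_sd * rng.standard_normal(n)
    x_f = r * z_f + scenario.c_x * c + e_sd * rng.standard_normal(n)

    p_m = (m1 + m2 - 2.0 * p).sum(axis=1)  # centred maternal allele count
    e_y = np.sqrt(max(0.0, 1.0 - explained)) * rng.standard_normal(n)
    y_o = (scenario.beta_int * x_m + scenario.lambda_o * z_o
           + scenario.beta_pat * x_f + scenario.c_y * c
           + scenario.pleiotropy_delta * p_m + e_y)

    return TrioCohort(panel, m1, m2, f1, f2, tm, tf, offspring,
                      x_m, x_f, y_o, c, scenario.confounder_observed)


def mendelian_check(cohort: TrioCohort) -> int:
    """Count (family, SNP) records where the offspring genotype is not
    the sum of the recorded transmitted parental alleles."""
    if cohort.n_families == 0:
        return 0
    expected = cohort.maternal_transmitted_allele + cohort.paternal_transmitted_allele
    return int((cohort.offspring_genotype != expected).sum())


def replicate(scenario: SimScenario, seed: int) -> SimScenario:
    """The same scenario with a different RNG seed (for replicate draws)."""
    return dataclasses.replace(scenario, seed=int(seed))
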