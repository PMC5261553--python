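"""Per-SNP causal estimates, IVW pooling and MR-Egger regression.

Each SNP supplies a Wald ratio — the SNP-outcome association (with
offspring-score adjustment) divided by the SNP-exposure association —
with a first-order delta-method SE.  Inverse-variance-weighted (IVW)
fixed-effects pooling combines the ratios; Cochran's Q and I^2 quantify
their heterogeneity, and MR-Egger regression (weighted regression of
SNP-outcome on SNP-exposure associations with an intercept) tests for
directional pleiotropy and provides a pleiotropy-robust slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimators import EffectEstimate, _Z975

log = logging.getLogger(__name__)


@dataclass
class SNPAssoc:
    """Instrument-exposure and instrument-outcome associations for one SNP."""

    snp: str
    beta_zx: float
    se_zx: float
    beta_zy: float
    se_zy: float

    def __post_init__(self) -> None:
        if self.se_zx <= 0 or self.se_zy <= 0:
            raise ValueError(f"SNP {self.snp}: standard errors must be positive")

    def oriented(self) -> "SNPAssoc":
        """Orient to a non-negative exposure association (flip both betas)."""
        if self.beta_zx >= 0:
            return self
        return SNPAssoc(self.snp, -self.beta_zx, self.se_zx,
                        -self.beta_zy, self.se_zy)


@dataclass
class MRSummaryResult:
    """Pooled summary-level MR output (IVW and/or Egger fields)."""

    ratios: list[EffectEstimate] | None = None
    beta_ivw: float | None = None
    se_ivw: float | None = None
    q: float | None = None
    i2: float | None = None
    k: int | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    egger_slope: float | None = None
    egger_slope_se: float | None = None
    egger_slope_p: float | None = None


def wald_ratio(assoc: SNPAssoc) -> EffectEstimate:
    """Per-SNP causal estimate beta_zy / beta_zx.

    The SE is the first-order delta approximation se_zy / |beta_zx|,
    appropriate for strong instruments; the ratio is invariant to
    rescaling both associations.
    """
    if assoc.beta_zx == 0:
        raise ValueError(f"SNP {assoc.snp}: zero exposure association, ratio undefined")
    beta = assoc.beta_zy / assoc.beta_zx
    se = assoc.se_zy / abs(assoc.beta_zx)
    return EffectEstimate(beta, se, beta - _Z975 * se, beta + _Z975 * se,
                          label=f"wald:{assoc.snp}")


def _ivw(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float, float]:
    w = 1.0 / ses ** 2
    pooled = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(((betas - pooled) / ses) ** 2))
    k = len(betas)
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return pooled, se, q, i2


def ivw_pool(ratios: list[EffectEstimate]) -> MRSummaryResult:
    """Fixed-effects inverse-variance-weighted pooling of Wald ratios.

    pooled = sum(b/se^2)/sum(1/se^2); Q = sum(((b - pooled)/se)^2);
    I^2 = max(0, (Q - (k-1))/Q) * 100.  Permutation-invariant in its
    inputs.
    """
    if not ratios:
        raise ValueError("no ratios to pool")
    betas = np.array([r.beta for r in ratios], dtype=float)
    ses = np.array([r.se for r in ratios], dtype=float)
    if np.any(ses <= 0):
        raise ValueError("all ratio SEs must be positive")
    pooled, se, q, i2 = _ivw(betas, ses)
    return MRSummaryResult(ratios=list(ratios), beta_ivw=pooled, se_ivw=se,
                           q=q, i2=i2, k=len(ratios))


def egger_fit(assocs: list[SNPAssoc]) -> MRSummaryResult:
    """MR-Egger: weighted regression of beta_zy on beta_zx with intercept.

    Associations are first oriented so every beta_zx >= 0; weights are
    1/se_zy^2.  The intercept tests overall directional pleiotropy; the
    slope is a causal estimate valid under pleiotropy (given InSIDE).
    p-values use the t distribution with k-2 df, as in the standard
    weighted-lm implementations.
    """
    if len(assocs) < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    oriented = [a.oriented() for a in assocs]
    bx = np.array([a.beta_zx for a in oriented])
    by = np.array([a.beta_zy for a in oriented])
    sy = np.array([a.se_zy for a in oriented])
    if np.allclose(bx, bx[0]):
        raise ValueError("all exposure associations are equal; Egger slope unidentified")
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy ** 2).fit()
    dfree = len(assocs) - 2
    out = MRSummaryResult(k=len(assocs))
    out.egger_intercept = float(res.params[0])
    out.egger_intercept_se = float(res.bse[0])
    out.egger_intercept_p = 2.0 * float(stats.t.sf(abs(res.tvalues[0]), dfree))
    out.egger_slope = float(res.params[1])
    out.egger_slope_se = float(res.bse[1])
    out.egger_slope_p = 2.0 * float(stats.t.sf(abs(res.tvalues[1]), dfree))
    return out


def summarise(assocs: list[SNPAssoc]) -> MRSummaryResult:
    """Wald ratios, IVW pooling and (k >= 3) MR-Egger in one result."""
    result = ivw_pool([wald_ratio(a.oriented()) for a in assocs])
    if len(assocs) >= 3:
        egger = egger_fit(assocs)
        result.egger_intercept = egger.egger_intercept
        result.egger_intercept_se = egger.egger_intercept_se
        result.egger_intercept_p = egger.egger_intercept_p
        result.egger_slope = egger.egger_slope
        result.egger_slope_se = egger.egger_slope_se
        result.egger_slope_p = egger.egger_slope_p
    return result


def _simple_ols(y: np.ndarray, columns: list[np.ndarray], target: int
                ) -> tuple[float, float]:
    """Beta and classical SE for one column of a small OLS design."""
    n = len(y)
    d = np.column_stack([np.ones(n)] + columns)
    dtd_inv = np.linalg.inv(d.T @ d)
    b = dtd_inv @ (d.T @ y)
    u = y - d @ b
    sigma2 = float(u @ u) / (n - d.shape[1])
    return float(b[target]), float(np.sqrt(sigma2 * dtd_inv[target, target]))


def snp_associations(maternal_genotype: np.ndarray, exposure, outcome,
                     offspring_score, snp_ids: list[str],
                     covariates=None) -> list[SNPAssoc]:
    """Per-SNP association pairs from individual-level trio data.

    For each SNP: beta_zx from regressing the maternal exposure on the
    maternal dosage, and beta_zy from regressing the offspring outcome
    on the maternal dosage with adjustment for the offspring weighted
    allele score (mirroring the offspring-adjusted IV models).
    """
    g = np.asarray(maternal_genotype, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    zo = np.asarray(offspring_score, dtype=float)
    if covariates is not None:
        cov = covariates.to_numpy(float) if isinstance(covariates, pd.DataFrame) \
            else np.atleast_2d(np.asarray(covariates, dtype=float).T).T
        extra = [cov[:, j] for j in range(cov.shape[1])]
    else:
        extra = []
    out = []
    for j, snp in enumerate(snp_ids):
        gj = g[:, j]
        bzx, sezx = _simple_ols(x, [gj] + extra, target=1)
        bzy, sezy = _simple_ols(y, [gj, zo] + extra, target=1)
        out.append(SNPAssoc(snp, bzx, sezx, bzy, sezy))
    return out


def assoc_table(assocs: list[SNPAssoc]) -> pd.DataFrame:
    return pd.DataFrame([{"snp": a.snp, "beta_zx": a.beta_zx, "se_zx": a.se_zx,
                          "beta_zy": a.beta_zy, "se_zy": a.se_zy} for a in assocs])


def read_assoc_tsv(path) -> list[SNPAssoc]:
    df = pd.read_csv(path, sep="\t")
    need = ["snp", "beta_zx", "se_zx", "beta_zy", "se_zy"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file {path} is missing columns {missing}")
    return [SNPAssoc(str(r.snp), r.beta_zx, r.se_zx, r.beta_zy, r.se_zy)
            for r in df.itertuples()]
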