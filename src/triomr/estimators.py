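"""Regression and instrumental-variable estimators for trio MR.

The core causal contrast is the multivariable (OLS) association of
maternal BMI with the offspring outcome versus the two-stage
least-squares (TSLS) estimate that uses the maternal weighted allele
score as an instrument, with the offspring allele score added to the IV
model to block the direct transmission path.  A family-resampling
bootstrap provides the z-test for the difference between the two
estimators, and analytic normal-approximation power is available for
design calculations.

All SEs are classical (homoskedastic) by default, matching plain 95%
CIs; heteroskedasticity-robust SEs are available behind ``robust=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class EffectEstimate:
    """A fitted association: beta with SE and 95% normal-theory CI."""

    beta: float
    se: float | None
    ci_low: float
    ci_high: float
    n: int | None = None
    df: int | None = None
    label: str = ""

    @classmethod
    def from_fit(cls, beta: float, se: float, n: int, df: int, label: str = "") -> "EffectEstimate":
        beta, se = float(beta), float(se)
        return cls(beta, se, beta - _Z975 * se, beta + _Z975 * se, int(n), int(df), label)


@dataclass
class FirstStageDiagnostics:
    """Instrument strength from the first-stage regression.

    ``r2`` and ``f_stat`` are the partial R^2 and partial F of the
    instruments given the included covariates.
    """

    r2: float
    f_stat: float
    n: int
    k_instruments: int


@dataclass
class BootstrapDifference:
    """Bootstrap z-test comparing the OLS and IV estimators."""

    z: float
    p_value: float
    beta_ols: float
    beta_iv: float
    var_ols: float
    var_iv: float
    cov_ols_iv: float
    n_boot: int


@dataclass
class LinearityDiagnostic:
    """Augmented partial residuals with a loess smooth and the Wald
    p-value of an added quadratic exposure term."""

    table: pd.DataFrame  # exposure, partial_residual, loess, linear_fit
    p_quadratic: float
    beta_quadratic: float


def _as_2d(a) -> np.ndarray | None:
    if a is None:
        return None
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _covariate_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(float), [str(c) for c in covariates.columns]
    c = _as_2d(covariates)
    return c, [f"cov{i}" for i in range(c.shape[1])]


def _listwise(*arrays):
    """Drop rows with any NaN across the supplied arrays (complete cases)."""
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None or a.size == 0:
            continue
        mask &= np.isfinite(a).all(axis=1) if a.ndim == 2 else np.isfinite(a)
    return [None if a is None else a[mask] for a in arrays], int(mask.sum())


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # pivoted QR flags the columns that add (numerically) nothing
        from scipy.linalg import qr
        _, r, piv = qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = sorted(names[piv[i]] for i in range(len(diag)) if diag[i] <= tol)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def ols_fit(outcome, exposure, covariates=None, robust: bool = False,
            label: str = "ols") -> EffectEstimate:
    """OLS coefficient on the exposure with classical SE and 95% CI.

    Complete-case (listwise) deletion is applied per model, so n can
    differ between models with different covariate sets.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    c, cnames = _covariate_matrix(covariates, len(y))
    (y, x, c), n = _listwise(y, x, c)
    k = 2 + c.shape[1]
    if n < k + 2:
        raise ValueError(f"too few complete cases (n={n}) for {k} parameters")
    design = np.column_stack([np.ones(n), x, c])
    _check_rank(design, ["const", "exposure"] + cnames)
    res = sm.OLS(y, design).fit(cov_type="HC1" if robust else "nonrobust")
    return EffectEstimate.from_fit(res.params[1], res.bse[1], n, n - k, label)


def _partial_diagnostics(x, instruments, cov, n) -> FirstStageDiagnostics:
    """Partial R^2 and F of the instruments given the covariates."""
    w = np.column_stack([np.ones(n), cov])
    bx, *_ = np.linalg.lstsq(w, x, rcond=None)
    x_res = x - w @ bx
    bz, *_ = np.linalg.lstsq(w, instruments, rcond=None)
    z_res = instruments - w @ bz
    k = instruments.shape[1]
    zc = np.column_stack([np.ones(n), z_res])
    bb, *_ = np.linalg.lstsq(zc, x_res, rcond=None)
    rss = float(np.sum((x_res - zc @ bb) ** 2))
    tss = float(np.sum((x_res - x_res.mean()) ** 2))
    if tss <= 0:
        raise ValueError("exposure has no residual variance after covariate adjustment")
    r2 = max(0.0, 1.0 - rss / tss)
    c = cov.shape[1]
    denom_df = n - k - c - 1
    if r2 <= 1e-12:
        raise ValueError("first-stage partial R^2 is zero: model is unidentified")
    # R^2 of 1 (instrument reproduces the exposure) gives an infinite F
    f = np.inf if r2 >= 1.0 - 1e-12 else r2 * denom_df / (k * (1.0 - r2))
    return FirstStageDiagnostics(r2=r2, f_stat=f, n=n, k_instruments=k)


def tsls_fit(outcome, exposure, instruments, covariates=None,
             robust: bool = False, label: str = "tsls"
             ) -> tuple[EffectEstimate, FirstStageDiagnostics]:
    """Two-stage least squares with the standard SE correction.

    Stage 1 regresses the exposure on instruments plus covariates;
    stage 2 regresses the outcome on the fitted exposure plus
    covariates.  SEs use stage-2 residuals recomputed with the observed
    exposure.  With a single instrument and no covariates the estimate
    equals the Wald ratio cov(Z,Y)/cov(Z,X).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = _as_2d(np.asarray(instruments, dtype=float))
    c, cnames = _covariate_matrix(covariates, len(y))
    (y, x, z, c), n = _listwise(y, x, z, c)
    k_inst = z.shape[1]
    k2 = 2 + c.shape[1]
    if n < k2 + k_inst + 2:
        raise ValueError(f"too few complete cases (n={n}) for TSLS")
    diag = _partial_diagnostics(x, z, c, n)

    stage1 = np.column_stack([np.ones(n), z, c])
    _check_rank(stage1, ["const"] + [f"z{i}" for i in range(k_inst)] + cnames)
    b1, *_ = np.linalg.lstsq(stage1, x, rcond=None)
    x_hat = stage1 @ b1

    d = np.column_stack([np.ones(n), x_hat, c])
    _check_rank(d, ["const", "exposure_hat"] + cnames)
    dtd_inv = np.linalg.inv(d.T @ d)
    b2 = dtd_inv @ (d.T @ y)
    observed = np.column_stack([np.ones(n), x, c])
    u = y - observed @ b2
    if robust:
        meat = (d * u[:, None]).T @ (d * u[:, None])
        cov_b = dtd_inv @ meat @ dtd_inv * n / (n - k2)
    else:
        sigma2 = float(u @ u) / (n - k2)
        cov_b = sigma2 * dtd_inv
    se = float(np.sqrt(cov_b[1, 1]))
    est = EffectEstimate.from_fit(b2[1], se, n, n - k2, label)
    return est, diag


def iv_with_offspring_adjustment(outcome, exposure, maternal_score,
                                 offspring_score, covariates=None,
                                 robust: bool = False
                                 ) -> tuple[EffectEstimate, FirstStageDiagnostics]:
    """TSLS with the maternal score as instrument and the offspring
    score as an included exogenous covariate.

    Adding the offspring weighted allele score to the IV model blocks
    the direct genetic-transmission path from maternal genotype to
    offspring outcome, isolating the intrauterine effect.
    """
    oscore = np.asarray(offspring_score, dtype=float)[:, None]
    c, cnames = _covariate_matrix(covariates, len(oscore))
    full = pd.DataFrame(np.column_stack([oscore, c]),
                        columns=["offspring_score"] + cnames)
    return tsls_fit(outcome, exposure, maternal_score, covariates=full,
                    robust=robust, label="iv_offspring_adjusted")


def _lstsq_beta(y, x, cov) -> float:
    d = np.column_stack([np.ones(len(y)), x, cov])
    b, *_ = np.linalg.lstsq(d, y, rcond=None)
    return float(b[1])


def _tsls_beta(y, x, z, cov) -> float:
    n = len(y)
    s1 = np.column_stack([np.ones(n), z, cov])
    b1, *_ = np.linalg.lstsq(s1, x, rcond=None)
    return _lstsq_beta(y, s1 @ b1, cov)


def bootstrap_difference_test(outcome, exposure, instrument,
                              ols_covariates=None, iv_covariates=None,
                              n_boot: int = 1000, seed: int | None = None
                              ) -> BootstrapDifference:
    """Family-resampling bootstrap z-test of OLS vs IV estimates.

    Families are resampled with replacement; each replicate refits the
    covariate-adjusted OLS beta and the IV (TSLS) beta.  The z-statistic
    uses the bootstrap variances and covariance,
    z = (b_OLS - b_IV) / sqrt(var_OLS + var_IV - 2 cov), with a
    two-sided normal p-value.  When the instrument reproduces the
    exposure the two estimators coincide, the bootstrap variance of the
    difference collapses to zero and (z, p) = (0, 1) is returned; a zero
    variance with a nonzero difference raises instead.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = _as_2d(np.asarray(instrument, dtype=float))
    c_ols, _ = _covariate_matrix(ols_covariates, len(y))
    c_iv, _ = _covariate_matrix(iv_covariates, len(y))
    (y, x, z, c_ols, c_iv), n = _listwise(y, x, z, c_ols, c_iv)

    b_ols = _lstsq_beta(y, x, c_ols)
    b_iv = _tsls_beta(y, x, z, c_iv)

    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, 2))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        reps[b, 0] = _lstsq_beta(y[idx], x[idx], c_ols[idx])
        reps[b, 1] = _tsls_beta(y[idx], x[idx], z[idx], c_iv[idx])
    cov = np.cov(reps, rowvar=False)
    var_diff = float(cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1])
    diff = b_ols - b_iv
    if var_diff <= 1e-16:
        if abs(diff) < 1e-10:
            return BootstrapDifference(0.0, 1.0, b_ols, b_iv,
                                       float(cov[0, 0]), float(cov[1, 1]),
                                       float(cov[0, 1]), n_boot)
        raise ValueError("degenerate bootstrap variance for a nonzero difference")
    zstat = diff / np.sqrt(var_diff)
    p = 2.0 * float(stats.norm.sf(abs(zstat)))
    return BootstrapDifference(float(zstat), p, b_ols, b_iv,
                               float(cov[0, 0]), float(cov[1, 1]),
                               float(cov[0, 1]), n_boot)


def linearity_diagnostic(outcome, exposure, covariates=None,
                         loess_frac: float = 0.6) -> LinearityDiagnostic:
    """Augmented-partial-residual check for departures from linearity.

    Fits outcome ~ exposure + exposure^2 + covariates, returns the
    partial residuals augmented with the linear and quadratic exposure
    contributions, a lowess smooth of them against the exposure, the
    corresponding straight-line fit, and the Wald p-value of the
    quadratic term as a numeric linearity test.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    c, cnames = _covariate_matrix(covariates, len(y))
    (y, x, c), n = _listwise(y, x, c)
    k = 3 + c.shape[1]
    if n < k + 2:
        raise ValueError(f"too few complete cases (n={n}) for {k} parameters")
    design = np.column_stack([np.ones(n), x, x ** 2, c])
    _check_rank(design, ["const", "exposure", "exposure_sq"] + cnames)
    res = sm.OLS(y, design).fit()
    apr = res.resid + res.params[1] * x + res.params[2] * x ** 2
    smooth = sm.nonparametric.lowess(apr, x, frac=loess_frac, return_sorted=False)
    line = sm.OLS(apr, sm.add_constant(x)).fit().fittedvalues
    table = pd.DataFrame({"exposure": x, "partial_residual": apr,
                          "loess": smooth, "linear_fit": line})
    return LinearityDiagnostic(table=table, p_quadratic=float(res.pvalues[2]),
                               beta_quadratic=float(res.params[2]))


def power_mr(n: int, rho2: float, beta: float, alpha: float = 0.05) -> float:
    """Asymptotic two-sided power of the IV estimator on standardised data.

    With standardised exposure and outcome the IV estimate has
    approximate SE 1/sqrt(n * rho2), where rho2 is the variance of the
    exposure explained by the instrument, giving

        power = Phi(sqrt(n rho2) |beta| - z_{1-a/2})
              + Phi(-sqrt(n rho2) |beta| - z_{1-a/2}).
    """
    if not 0.0 < rho2 < 1.0:
        raise ValueError("rho2 must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    ncp = np.sqrt(n * rho2) * abs(beta)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))
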