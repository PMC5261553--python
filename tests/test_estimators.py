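"""OLS, TSLS, bootstrap difference test, linearity and power."""

import numpy as np
import pytest

from triomr import (bootstrap_difference_test, iv_with_offspring_adjustment,
                    linearity_diagnostic, ols_fit, power_mr, tsls_fit)


def test_ols_exact_line():
    x = np.arange(10.0)
    est = ols_fit(2 * x, x)
    assert est.beta == pytest.approx(2.0, abs=1e-10)
    assert est.se == pytest.approx(0.0, abs=1e-10)


def test_ols_orthogonal_exposure_near_zero():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal(20000), rng.standard_normal(20000)
    est = ols_fit(y, x)
    assert abs(est.beta) < 3.0 / np.sqrt(20000)


def test_ols_recovers_effect_with_observed_confounder(cohort_factory):
    cohort = cohort_factory(n_families=50000, seed=21, beta_int=0.25,
                            confounder_observed=True)
    est = ols_fit(cohort.y_o, cohort.x_m, covariates=cohort.covariates())
    # residual upward bias from the offspring-genotype path remains:
    # lambda_o * cov(X_m, Z*_o | C) ~ 0.011
    transmission = 0.15 * np.sqrt(0.022) * 0.5
    assert est.beta == pytest.approx(0.25 + transmission, abs=3 * est.se)


def test_ols_rank_deficiency_reported():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(100)
    with pytest.raises(ValueError, match="collinear"):
        ols_fit(rng.standard_normal(100), x, covariates=np.column_stack([x, x]))


def test_ols_listwise_deletion():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(100)
    y = 0.5 * x + rng.standard_normal(100)
    y[:10] = np.nan
    est = ols_fit(y, x)
    assert est.n == 90


def test_tsls_single_instrument_equals_wald_ratio():
    rng = np.random.default_rng(3)
    n = 400
    z = rng.standard_normal(n)
    x = 0.4 * z + rng.standard_normal(n)
    y = 0.7 * x + rng.standard_normal(n)
    est, _ = tsls_fit(y, x, z)
    wald = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
    assert est.beta == pytest.approx(wald, rel=1e-10)


def test_tsls_perfect_instrument_equals_ols():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(500)
    y = 0.3 * x + rng.standard_normal(500)
    est, _ = tsls_fit(y, x, x)
    assert est.beta == pytest.approx(ols_fit(y, x).beta, rel=1e-10)


def test_tsls_removes_unobserved_confounding(cohort_factory):
    cohort = cohort_factory(n_families=50000, seed=22, beta_int=0.25,
                            lambda_o=0.0)
    naive = ols_fit(cohort.y_o, cohort.x_m)
    iv, diag = tsls_fit(cohort.y_o, cohort.x_m, cohort.maternal_score())
    assert naive.beta > 0.30          # confounded upward (c_x * c_y = 0.09)
    assert iv.beta == pytest.approx(0.25, abs=3 * iv.se)
    assert diag.f_stat > 45


def test_first_stage_partial_f_closed_form():
    rng = np.random.default_rng(5)
    n = 3000
    z = rng.standard_normal(n)
    x = 0.2 * z + rng.standard_normal(n)
    _, diag = tsls_fit(0.1 * x + rng.standard_normal(n), x, z)
    f_expected = diag.r2 * (n - 1 - 0 - 1) / (1 * (1 - diag.r2))
    assert diag.f_stat == pytest.approx(f_expected, rel=1e-10)


def test_tsls_unidentified_instrument_errors():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(200)
    z = np.zeros(200)
    with pytest.raises(ValueError):
        tsls_fit(x + rng.standard_normal(200), x, z)


def test_offspring_adjustment_blocks_transmission(cohort_factory):
    # no intrauterine effect; offspring genotype drives its own outcome
    cohort = cohort_factory(n_families=50000, seed=23, beta_int=0.0,
                            lambda_o=0.3)
    unadj, _ = tsls_fit(cohort.y_o, cohort.x_m, cohort.maternal_score())
    adj, _ = iv_with_offspring_adjustment(
        cohort.y_o, cohort.x_m, cohort.maternal_score(),
        cohort.offspring_score())
    assert unadj.beta > 5 * unadj.se           # transmission path open
    assert adj.beta == pytest.approx(0.0, abs=3 * adj.se)


def test_bootstrap_difference_identical_estimators():
    rng = np.random.default_rng(7)
    x = rng.standard_normal(300)
    y = 0.4 * x + rng.standard_normal(300)
    res = bootstrap_difference_test(y, x, x, n_boot=200, seed=1)
    assert res.z == 0.0 and res.p_value == 1.0


def test_bootstrap_difference_detects_confounding(cohort_factory):
    # confounded null: OLS biased away from zero, IV consistent
    cohort = cohort_factory(n_families=20000, seed=24, beta_int=0.0,
                            c_x=0.5, c_y=0.5, rho2_m=0.05)
    res = bootstrap_difference_test(
        cohort.y_o, cohort.x_m, cohort.maternal_score(),
        iv_covariates=cohort.offspring_score()[:, None],
        n_boot=300, seed=2)
    assert res.p_value < 0.01
    assert res.beta_ols > res.beta_iv


def test_bootstrap_seed_determinism(cohort_factory):
    cohort = cohort_factory(n_families=2000, seed=25, beta_int=0.2)
    args = (cohort.y_o, cohort.x_m, cohort.maternal_score())
    a = bootstrap_difference_test(*args, n_boot=150, seed=9)
    b = bootstrap_difference_test(*args, n_boot=150, seed=9)
    assert a.z == b.z
    with pytest.raises(ValueError, match="seed"):
        bootstrap_difference_test(*args, n_boot=150)
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_difference_test(*args, n_boot=50, seed=1)


def test_linearity_diagnostic_null_and_quadratic():
    rng = np.random.default_rng(8)
    n = 4000
    x = rng.standard_normal(n)
    linear = linearity_diagnostic(0.5 * x + rng.standard_normal(n), x)
    assert linear.p_quadratic > 0.001
    assert len(linear.table) == n
    quad = linearity_diagnostic(x ** 2 + 0.3 * rng.standard_normal(n), x)
    assert quad.p_quadratic < 1e-10
    # the loess smooth of a strongly quadratic relation bends: its range
    # exceeds that of the straight-line fit
    assert (quad.table["loess"].max() - quad.table["loess"].min()) > 0


def test_power_size_equals_level():
    assert power_mr(1000, 0.02, 0.0, alpha=0.05) == pytest.approx(0.05, abs=1e-10)


def test_power_consistency_and_hand_value():
    assert power_mr(10 ** 7, 0.02, 0.1) > 0.9999
    # hand evaluation: sqrt(6057*0.022)*0.28 = 3.232; Phi(3.232-1.960) = 0.898
    assert power_mr(6057, 0.022, 0.28, 0.05) == pytest.approx(0.898, abs=0.005)


def test_power_input_validation():
    with pytest.raises(ValueError):
        power_mr(100, 1.5, 0.1)
    with pytest.raises(ValueError):
        power_mr(100, 0.02, 0.1, alpha=0.0)
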