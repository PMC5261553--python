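"""Generator structure: Mendelian consistency, moments, determinism."""

import itertools

import numpy as np
import pytest

from triomr import (SimScenario, SNPPanel, default_panel, mendelian_check,
                    replicate, simulate_cohort)


def _trio_covariance_oracle(p):
    """Brute-force cov(G_m, G_o) for one SNP by enumerating the trio
    distribution: parental haplotypes ~ Bernoulli(p), fair-coin
    transmission.  Under random mating this equals p(1-p), half the
    genotype variance 2p(1-p), so score correlation is exactly 1/2."""
    e_gm_go = e_gm = e_go = 0.0
    for a, b, c, d in itertools.product((0, 1), repeat=4):
        prob_h = (p if a else 1 - p) * (p if b else 1 - p) \
            * (p if c else 1 - p) * (p if d else 1 - p)
        gm = a + b
        for tm, tf in itertools.product((0, 1), repeat=2):
            prob = prob_h * 0.25
            go = (b if tm else a) + (d if tf else c)
            e_gm_go += prob * gm * go
            e_gm += prob * gm
            e_go += prob * go
    return e_gm_go - e_gm * e_go


@pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.8])
def test_single_snp_trio_covariance_enumeration(p):
    assert _trio_covariance_oracle(p) == pytest.approx(p * (1 - p), abs=1e-12)


def test_parent_offspring_score_correlation_half(cohort_factory):
    cohort = cohort_factory(n_families=50000, seed=11)
    r = np.corrcoef(cohort.maternal_score(), cohort.offspring_score())[0, 1]
    assert r == pytest.approx(0.5, abs=0.01)


def test_null_model_no_exposure_outcome_correlation(cohort_factory):
    cohort = cohort_factory(n_families=50000, seed=3, beta_int=0.0,
                            lambda_o=0.0, beta_pat=0.0, c_y=0.0)
    r = np.corrcoef(cohort.x_m, cohort.y_o)[0, 1]
    assert abs(r) < 3.0 / np.sqrt(50000)


def test_instrument_variance_explained_matches_rho2(cohort_factory):
    import statsmodels.api as sm
    cohort = cohort_factory(n_families=50000, seed=5, rho2_m=0.022)
    z = cohort.maternal_score()
    fit = sm.OLS(cohort.x_m, sm.add_constant(z)).fit()
    assert fit.rsquared == pytest.approx(0.022, abs=0.004)


def test_phenotype_moments_and_allele_frequencies(cohort_factory, panel32):
    n = 50000
    cohort = cohort_factory(n_families=n, seed=9, beta_int=0.25, beta_pat=0.1)
    assert cohort.x_m.var() == pytest.approx(1.0, abs=0.03)
    assert cohort.y_o.var() == pytest.approx(1.0, abs=0.03)
    emp = cohort.maternal_genotype.mean(axis=0) / 2.0
    tol = 4.0 * np.sqrt(panel32.freq * (1 - panel32.freq) / (2 * n))
    assert np.all(np.abs(emp - panel32.freq) < tol)


def test_genotype_and_haplotype_ranges(cohort_factory):
    cohort = cohort_factory(n_families=2000, seed=2)
    for hap in (cohort.maternal_h1, cohort.maternal_h2,
                cohort.paternal_h1, cohort.paternal_h2):
        assert set(np.unique(hap)) <= {0, 1}
    assert set(np.unique(cohort.offspring_genotype)) <= {0, 1, 2}


def test_mendelian_check_zero_then_detects_corruption(cohort_factory):
    cohort = cohort_factory(n_families=500, seed=4)
    assert mendelian_check(cohort) == 0
    cohort.offspring_genotype = cohort.offspring_genotype.copy()
    i, j = 17, 3
    cohort.offspring_genotype[i, j] = (cohort.offspring_genotype[i, j] + 1) % 3
    assert mendelian_check(cohort) == 1


def test_mendelian_check_empty_cohort(cohort_factory):
    cohort = cohort_factory(n_families=1, seed=0)
    from triomr.synthetic_trios import TrioCohort
    empty = TrioCohort(cohort.panel,
                       *(a[:0] for a in (cohort.maternal_h1, cohort.maternal_h2,
                                         cohort.paternal_h1, cohort.paternal_h2,
                                         cohort.maternal_transmitted_index,
                                         cohort.paternal_transmitted_index,
                                         cohort.offspring_genotype)),
                       cohort.x_m[:0], cohort.x_f[:0], cohort.y_o[:0],
                       cohort.confounder[:0])
    assert mendelian_check(empty) == 0


def test_transmitted_plus_nontransmitted_equals_genotype(cohort_factory):
    cohort = cohort_factory(n_families=1000, seed=6)
    total = cohort.maternal_transmitted_allele + cohort.maternal_nontransmitted_allele
    assert np.array_equal(total, cohort.maternal_genotype)


def test_fixed_seed_reproduces_cohort_exactly(panel32):
    sc = SimScenario(n_families=300, panel=panel32, beta_int=0.2, seed=42)
    a, b = simulate_cohort(sc), simulate_cohort(sc)
    assert np.array_equal(a.maternal_h1, b.maternal_h1)
    assert np.array_equal(a.offspring_genotype, b.offspring_genotype)
    assert np.array_equal(a.y_o, b.y_o)
    c = simulate_cohort(replicate(sc, 43))
    assert not np.array_equal(a.y_o, c.y_o)


def test_variance_budget_errors(panel32):
    with pytest.raises(ValueError, match="variance budget"):
        SimScenario(n_families=10, panel=panel32, rho2_m=0.5, c_x=0.8)
    sc = SimScenario(n_families=10, panel=panel32, beta_int=1.2, lambda_o=0.5,
                     c_y=0.5)
    with pytest.raises(ValueError, match="variance budget"):
        simulate_cohort(sc)
    with pytest.raises(ValueError, match="n_families"):
        SimScenario(n_families=0, panel=panel32)


def test_empty_panel_rejected():
    with pytest.raises(ValueError, match="at least one SNP"):
        SNPPanel([], [], [], np.array([]), np.array([]))


def test_panel_frequency_bounds():
    with pytest.raises(ValueError, match="frequencies"):
        SNPPanel(["rs1"], ["A"], ["C"], np.array([0.1]), np.array([1.0]))


def test_confounder_export_flag(cohort_factory):
    hidden = cohort_factory(n_families=50, seed=1)
    shown = cohort_factory(n_families=50, seed=1, confounder_observed=True)
    assert hidden.covariates().shape[1] == 0
    assert list(shown.covariates().columns) == ["confounder"]


def test_default_panel_deterministic():
    a, b = default_panel(32, seed=7), default_panel(32, seed=7)
    assert a.snp_id == b.snp_id
    assert np.array_equal(a.weight, b.weight)
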