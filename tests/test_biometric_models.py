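import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import cohort_m2ll, stacked_family_loglik
from twingraph import SimulationSpec, generate_cohort
from twingraph.biometric_models import (
    _stack_families,
    _total_m2ll,
    compare_models,
    falconer_estimates,
    fit_bivariate_ae,
    fit_univariate,
    genetic_correlation,
    profile_ci,
    twin_pair_loglik,
)


# ---------------------------------------------------------------------------
# likelihood machinery vs brute-force oracle
# ---------------------------------------------------------------------------

def test_singleton_standard_normal_density():
    params = {"mean": np.array([0.0]), "V_A": np.array([[0.4]]),
              "V_C": np.array([[0.3]]), "V_E": np.array([[0.3]])}
    family = np.array([[0.0], [np.nan]])
    ll = twin_pair_loglik(params, family, "MZ")
    assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)


def test_singular_family_covariance_penalized():
    params = {"mean": np.array([0.0]), "V_A": np.array([[1.0]]),
              "V_C": np.array([[0.0]]), "V_E": np.array([[0.0]])}
    family = np.array([[0.3], [0.7]])  # MZ pair with A-only model: degenerate
    with pytest.warns(RuntimeWarning, match="singular"):
        ll = twin_pair_loglik(params, family, "MZ")
    assert ll < -1e9


def test_family_loglik_matches_stacked_normal_oracle(small_mixed_cohort):
    means = np.array([0.1, -0.2])
    V_A = np.array([[0.5, 0.2], [0.2, 0.4]])
    V_C = np.array([[0.1, 0.05], [0.05, 0.1]])
    V_E = np.array([[0.4, 0.1], [0.1, 0.5]])
    params = {"mean": means, "V_A": V_A, "V_C": V_C, "V_E": V_E}
    df = small_mixed_cohort.data
    for _, fam in df.groupby("family_id"):
        zyg = fam["zygosity"].iloc[0]
        y = np.full((2, 2), np.nan)
        for _, row in fam.iterrows():
            y[int(row["member_index"]) - 1] = [row["u"], row["v"]]
        assert twin_pair_loglik(params, y, zyg) == pytest.approx(
            stacked_family_loglik(y, means, V_A, V_C, V_E, zyg), abs=1e-8)


def test_fiml_total_equals_bruteforce_bivariate(small_mixed_cohort):
    means = np.array([0.05, -0.1])
    V_A = np.array([[0.45, 0.15], [0.15, 0.35]])
    V_C = np.array([[0.12, 0.02], [0.02, 0.08]])
    V_E = np.array([[0.42, 0.08], [0.08, 0.5]])
    groups = _stack_families(small_mixed_cohort, ["u", "v"])
    fast = _total_m2ll(groups, means, V_A, V_C, V_E)
    slow = cohort_m2ll(small_mixed_cohort, ["u", "v"], means, V_A, V_C, V_E)
    assert fast == pytest.approx(slow, abs=1e-6)


def test_fiml_total_equals_bruteforce_univariate(small_mixed_cohort):
    groups = _stack_families(small_mixed_cohort, ["u"])
    means = np.array([0.0])
    V_A, V_C, V_E = np.array([[0.5]]), np.array([[0.1]]), np.array([[0.4]])
    fast = _total_m2ll(groups, means, V_A, V_C, V_E)
    slow = cohort_m2ll(small_mixed_cohort, ["u"], means, V_A, V_C, V_E)
    assert fast == pytest.approx(slow, abs=1e-6)


# ---------------------------------------------------------------------------
# univariate fits
# ---------------------------------------------------------------------------

def test_null_heritability_recovered():
    spec = SimulationSpec(n_mz_pairs=2000, n_dz_pairs=2000,
                          phenotype_labels=["x"], A_cov=np.zeros((1, 1)),
                          C_cov=np.zeros((1, 1)), E_cov=np.eye(1), seed=13)
    cohort = generate_cohort(spec)
    fit = fit_univariate(cohort, "x", "ACE")
    assert fit.converged
    assert fit.a2 == pytest.approx(0.0, abs=0.05)
    assert fit.c2 == pytest.approx(0.0, abs=0.05)
    assert fit.e2 == pytest.approx(1.0, abs=0.05)


def test_heritability_recovery_agrees_with_falconer(ae_cohort_2000):
    """The ML estimate must track the Falconer moment oracle on the same
    draw (the draw's own sampling deviation affects both equally)."""
    fit = fit_univariate(ae_cohort_2000, "x", "ACE")
    est = falconer_estimates(ae_cohort_2000, "x")
    falconer_a2 = 2 * (est["r_mz"] - est["r_dz"])
    assert fit.a2 == pytest.approx(falconer_a2, abs=0.05)
    assert fit.a2 == pytest.approx(0.6, abs=0.1)
    assert fit.a2 + fit.c2 + fit.e2 == pytest.approx(1.0, abs=1e-8)


def test_nesting_monotonicity_and_restart_stability(ae_cohort_2000):
    ace = fit_univariate(ae_cohort_2000, "x", "ACE")
    ae = fit_univariate(ae_cohort_2000, "x", "AE")
    e = fit_univariate(ae_cohort_2000, "x", "E")
    assert ace.minus2lnL <= ae.minus2lnL + 1e-6
    assert ae.minus2lnL <= e.minus2lnL + 1e-6
    refit = fit_univariate(ae_cohort_2000, "x", "ACE", restart_seed=999)
    assert refit.minus2lnL == pytest.approx(ace.minus2lnL, abs=1e-4)


def test_identifiability_requires_both_zygosity_groups():
    spec = SimulationSpec(n_mz_pairs=50, n_dz_pairs=1, phenotype_labels=["x"],
                          A_cov=np.eye(1) * 0.5, E_cov=np.eye(1) * 0.5, seed=2)
    cohort = generate_cohort(spec)
    with pytest.raises(ValueError, match="DZ"):
        fit_univariate(cohort, "x", "ACE")


def test_singletons_only_cohort_not_identifiable():
    spec = SimulationSpec(n_mz_pairs=1, n_dz_pairs=1, n_singletons=40,
                          phenotype_labels=["x"],
                          A_cov=np.eye(1) * 0.5, E_cov=np.eye(1) * 0.5, seed=6)
    cohort = generate_cohort(spec)
    singles = cohort.data.groupby("family_id").filter(lambda g: len(g) == 1)
    singles_cohort = type(cohort)(singles, cohort.phenotype_labels)
    with pytest.raises(ValueError, match="complete"):
        fit_univariate(singles_cohort, "x", "ACE")


# ---------------------------------------------------------------------------
# nested-model comparison
# ---------------------------------------------------------------------------

def _dummy_fit(m2ll):
    from twingraph.biometric_models import UnivariateFit
    return UnivariateFit("x", "ACE", 0.3, 0.1, 0.6, (0.3, 0.1, 0.6), 0.0,
                         m2ll, True, 10)


def test_mixture_p_at_zero_delta_is_half():
    cmp_res = compare_models(_dummy_fit(100.0), _dummy_fit(100.0), 1)
    assert cmp_res.p_value == pytest.approx(0.5)
    assert cmp_res.delta_minus2lnL == 0.0


def test_mixture_p_halves_chi2_tail():
    # 0.5 * P(chi2_1 > 3.84) ~= 0.025
    cmp_res = compare_models(_dummy_fit(100.0), _dummy_fit(103.84), 1)
    assert cmp_res.p_value == pytest.approx(0.025, abs=5e-4)
    assert cmp_res.mixture_corrected


def test_two_boundary_component_mixture():
    from scipy.stats import chi2
    delta = 5.0
    cmp_res = compare_models(_dummy_fit(0.0), _dummy_fit(delta), 2)
    expected = 0.5 * chi2.sf(delta, 1) + 0.25 * chi2.sf(delta, 2)
    assert cmp_res.p_value == pytest.approx(expected, abs=1e-12)
    plain = compare_models(_dummy_fit(0.0), _dummy_fit(delta), 2,
                           plain_chi2=True)
    assert plain.p_value == pytest.approx(chi2.sf(delta, 2), abs=1e-12)


def test_reduced_better_than_full_raises():
    with pytest.raises(ValueError, match="restart"):
        compare_models(_dummy_fit(100.0), _dummy_fit(99.0), 1)


@given(delta=st.floats(min_value=0.0, max_value=50.0),
       n_boundary=st.integers(min_value=0, max_value=2))
@settings(max_examples=50, deadline=None)
def test_comparison_p_value_in_unit_interval(delta, n_boundary):
    cmp_res = compare_models(_dummy_fit(0.0), _dummy_fit(delta), n_boundary)
    assert 0.0 <= cmp_res.p_value <= 1.0
    assert cmp_res.delta_minus2lnL >= 0.0


# ---------------------------------------------------------------------------
# profile confidence intervals
# ---------------------------------------------------------------------------

def test_profile_ci_brackets_estimate_and_respects_bounds():
    spec = SimulationSpec(n_mz_pairs=500, n_dz_pairs=500, phenotype_labels=["x"],
                          A_cov=np.array([[0.6]]), E_cov=np.array([[0.4]]),
                          seed=11)
    cohort = generate_cohort(spec)
    fit = fit_univariate(cohort, "x", "ACE")
    lo, hi = profile_ci(cohort, fit, "a2")
    assert 0.0 <= lo <= fit.a2 <= hi <= 1.0
    lo_e, hi_e = profile_ci(cohort, fit, "e2")
    assert 0.0 <= lo_e <= fit.e2 <= hi_e <= 1.0


def test_profile_ci_lower_bound_zero_at_boundary():
    spec = SimulationSpec(n_mz_pairs=300, n_dz_pairs=300, phenotype_labels=["x"],
                          A_cov=np.zeros((1, 1)), E_cov=np.eye(1), seed=21)
    cohort = generate_cohort(spec)
    fit = fit_univariate(cohort, "x", "ACE")
    lo, hi = profile_ci(cohort, fit, "a2")
    assert lo == 0.0
    assert hi < 1.0


def test_profile_ci_coverage_on_seeded_replicates():
    """95% intervals should cover the true a2 = 0.6 in most replicates."""
    covered = 0
    n_reps = 20
    for rep in range(n_reps):
        spec = SimulationSpec(n_mz_pairs=500, n_dz_pairs=500,
                              phenotype_labels=["x"],
                              A_cov=np.array([[0.6]]), E_cov=np.array([[0.4]]),
                              seed=3000 + rep)
        cohort = generate_cohort(spec)
        fit = fit_univariate(cohort, "x", "ACE", n_restarts=2)
        lo, hi = profile_ci(cohort, fit, "a2")
        if lo <= 0.6 <= hi:
            covered += 1
    assert covered >= 16  # binomial(20, 0.95) leaves < 0.3% mass below 16


# ---------------------------------------------------------------------------
# bivariate AE Cholesky
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("A, expected", [
    (np.array([[4.0, 1.0], [1.0, 1.0]]), 0.5),
    (np.array([[1.0, -1.0], [-1.0, 1.0]]), -1.0),
    (np.array([[2.0, 0.0], [0.0, 3.0]]), 0.0),
])
def test_genetic_correlation_arithmetic(A, expected):
    assert genetic_correlation(A) == pytest.approx(expected, abs=1e-12)


def test_genetic_correlation_undefined_for_zero_variance():
    assert np.isnan(genetic_correlation(np.array([[0.0, 0.0], [0.0, 1.0]])))


@given(a11=st.floats(0.1, 3.0), a22=st.floats(0.1, 3.0), r=st.floats(-1.0, 1.0))
@settings(max_examples=100, deadline=None)
def test_genetic_correlation_bounded(a11, a22, r):
    a12 = r * np.sqrt(a11 * a22)
    rg = genetic_correlation(np.array([[a11, a12], [a12, a22]]))
    assert -1.0 <= rg <= 1.0


def test_bivariate_recovers_specified_genetic_correlation():
    A = np.array([[0.6, 0.3], [0.3, 0.6]])
    spec = SimulationSpec(n_mz_pairs=2000, n_dz_pairs=2000,
                          phenotype_labels=["x", "y"], A_cov=A,
                          E_cov=np.diag([0.4, 0.4]), seed=3)
    cohort = generate_cohort(spec)
    fit = fit_bivariate_ae(cohort, "x", "y")
    assert fit.converged
    assert fit.rg == pytest.approx(0.5, abs=0.1)
    assert fit.p_edge < 0.001
    # implied covariances are exact Cholesky products
    La = np.array([[fit.chol_A[0], 0], [fit.chol_A[1], fit.chol_A[2]]])
    assert np.allclose(La @ La.T, fit.A_cov, atol=1e-10)


def test_bivariate_symmetric_in_argument_order():
    A = np.array([[0.5, 0.2], [0.2, 0.5]])
    spec = SimulationSpec(n_mz_pairs=300, n_dz_pairs=300,
                          phenotype_labels=["p", "q"], A_cov=A,
                          E_cov=np.diag([0.5, 0.5]), seed=17)
    cohort = generate_cohort(spec)
    f1 = fit_bivariate_ae(cohort, "p", "q")
    f2 = fit_bivariate_ae(cohort, "q", "p")
    assert f1.rg == pytest.approx(f2.rg, abs=1e-6)
    assert f1.p_edge == pytest.approx(f2.p_edge, abs=1e-6)
    assert f1.minus2lnL == pytest.approx(f2.minus2lnL, abs=1e-6)


def test_near_duplicate_phenotype_has_unit_genetic_correlation():
    spec = SimulationSpec(n_mz_pairs=800, n_dz_pairs=800, phenotype_labels=["x"],
                          A_cov=np.array([[0.6]]), E_cov=np.array([[0.4]]),
                          seed=29)
    cohort = generate_cohort(spec)
    rng = np.random.default_rng(5)
    df = cohort.data.copy()
    df["x_copy"] = df["x"] + rng.normal(0, 1e-4, len(df))
    cohort2 = type(cohort)(df, ["x", "x_copy"])
    fit = fit_bivariate_ae(cohort2, "x", "x_copy")
    assert fit.rg == pytest.approx(1.0, abs=0.01)
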