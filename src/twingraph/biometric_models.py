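"""Biometric twin models fitted by full-information maximum likelihood.

Univariate ACE (and nested AE/CE/E) models decompose a phenotype's variance
into additive-genetic (A), shared-environment (C) and unique-environment (E)
components using the MZ/DZ cross-twin covariance contrast: the model-implied
cross-twin covariance is V_A + V_C for MZ pairs and 0.5*V_A + V_C for DZ
pairs.  Bivariate AE Cholesky models partition the covariance of two
phenotypes into genetic and environmental parts and yield the genetic
correlation rg.

Every family contributes the multivariate-normal log density of its observed
sub-vector (FIML): a missing co-twin or missing phenotype entry deletes the
corresponding rows/columns of the model-implied family covariance, so
incomplete pairs still inform mean and variance estimates.  Variance
components are parameterized through their square roots (paths), which keeps
them nonnegative without explicit bounds; likelihood-ratio tests of a
variance component against its zero boundary use the 50:50 chi2(0)/chi2(1)
mixture (the halved-p rule), and the joint two-component test uses the
25:50:25 chi2(0)/chi2(1)/chi2(2) mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from twingraph.synthetic_twins import TwinCohort

_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e10  # -2lnL returned for non-PD implied covariances
_VAR_TOL = 1e-6  # genetic variance below this flags rg as undefined

UNIVARIATE_MODELS = ("ACE", "AE", "CE", "E")


# ---------------------------------------------------------------------------
# data preparation: stack each family into a length-2P vector and group
# families by (zygosity, missingness pattern) for vectorized likelihoods
# ---------------------------------------------------------------------------

@dataclass
class _PatternGroup:
    zygosity: str                 # "MZ" or "DZ"
    observed: np.ndarray          # boolean mask over the stacked 2P vector
    data: np.ndarray              # (n_families, n_observed) observed values


def _stack_families(cohort: TwinCohort, phenotypes: Sequence[str]) -> list[_PatternGroup]:
    p = len(phenotypes)
    df = cohort.data
    wide = {}
    for ph in phenotypes:
        wide[ph] = df.pivot_table(index="family_id", columns="member_index",
                                  values=ph, dropna=False, aggfunc="first")
    fam_ids = wide[phenotypes[0]].index
    zyg = df.drop_duplicates("family_id").set_index("family_id")["zygosity"]
    # stacked order: [twin1 ph1..phP, twin2 ph1..phP]
    y = np.full((len(fam_ids), 2 * p), np.nan)
    for k, ph in enumerate(phenotypes):
        w = wide[ph]
        for member, col in ((1, k), (2, p + k)):
            if member in w.columns:
                y[:, col] = w[member].to_numpy()

    groups: list[_PatternGroup] = []
    zyg_arr = zyg.loc[fam_ids].to_numpy()
    obs = ~np.isnan(y)
    keep = obs.any(axis=1)
    y, obs, zyg_arr = y[keep], obs[keep], zyg_arr[keep]
    keys = {}
    for i in range(len(y)):
        key = (zyg_arr[i], obs[i].tobytes())
        keys.setdefault(key, []).append(i)
    for (z, _), idx in keys.items():
        mask = obs[idx[0]]
        groups.append(_PatternGroup(z, mask, y[np.ix_(idx, np.where(mask)[0])]))
    return groups


def _family_cov(V_A: np.ndarray, V_C: np.ndarray, V_E: np.ndarray,
                genetic_r: float) -> np.ndarray:
    """Model-implied 2P x 2P covariance of a twin pair's stacked phenotypes."""
    within = V_A + V_C + V_E
    cross = genetic_r * V_A + V_C
    return np.block([[within, cross], [cross, within]])


def _group_loglik(group: _PatternGroup, mean2p: np.ndarray,
                  sigma2p: np.ndarray) -> float:
    idx = np.where(group.observed)[0]
    sig = sigma2p[np.ix_(idx, idx)]
    try:
        chol = linalg.cholesky(sig, lower=True)
    except linalg.LinAlgError:
        return -np.inf
    diag = np.diag(chol)
    if np.any(diag <= 0):
        return -np.inf
    n, d = group.data.shape
    resid = group.data - mean2p[idx]
    z = linalg.solve_triangular(chol, resid.T, lower=True)
    logdet = 2.0 * np.sum(np.log(diag))
    return float(-0.5 * (n * d * _LOG2PI + n * logdet + np.sum(z * z)))


def _total_m2ll(groups: list[_PatternGroup], means: np.ndarray,
                V_A: np.ndarray, V_C: np.ndarray, V_E: np.ndarray) -> float:
    mean2p = np.concatenate([means, means])
    sig_mz = _family_cov(V_A, V_C, V_E, 1.0)
    sig_dz = _family_cov(V_A, V_C, V_E, 0.5)
    total = 0.0
    for g in groups:
        ll = _group_loglik(g, mean2p, sig_mz if g.zygosity == "MZ" else sig_dz)
        if not np.isfinite(ll):
            return _PENALTY
        total += ll
    return -2.0 * total


def twin_pair_loglik(params: Mapping[str, np.ndarray], family: np.ndarray,
                     zygosity: str) -> float:
    """Log-likelihood contribution of a single family (reference path).

    ``params`` holds ``mean`` (length P), and P x P matrices ``V_A``,
    ``V_C``, ``V_E``.  ``family`` is a (2, P) array of the two co-twins'
    phenotypes with NaN marking missing entries or a fully absent member.
    Returns the multivariate-normal log density of the observed sub-vector
    under the model-implied family covariance; a singular implied covariance
    returns a large negative penalty (with a warning) so optimizers stay in
    bounds rather than aborting.
    """
    family = np.atleast_2d(np.asarray(family, dtype=float))
    if family.ndim != 2 or family.shape[0] != 2:
        raise ValueError("family must be a (2, P) array (use NaN for absences)")
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    means = np.asarray(params["mean"], dtype=float)
    V_A = np.atleast_2d(np.asarray(params["V_A"], dtype=float))
    V_C = np.atleast_2d(np.asarray(params["V_C"], dtype=float))
    V_E = np.atleast_2d(np.asarray(params["V_E"], dtype=float))
    stacked = family.reshape(-1)
    obs = ~np.isnan(stacked)
    if not obs.any():
        raise ValueError("family has no observed phenotype entries")
    sigma = _family_cov(V_A, V_C, V_E, 1.0 if zygosity == "MZ" else 0.5)
    group = _PatternGroup(zygosity, obs, stacked[obs][None, :])
    ll = _group_loglik(group, np.concatenate([means, means]), sigma)
    if not np.isfinite(ll):
        warnings.warn("singular model-implied family covariance; "
                      "returning penalized log-likelihood", RuntimeWarning)
        return -_PENALTY
    return ll


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class UnivariateFit:
    """Univariate variance decomposition of one phenotype."""

    phenotype: str
    model: str                                   # ACE / AE / CE / E
    a2: float
    c2: float
    e2: float
    raw_variances: tuple[float, float, float]    # (V_A, V_C, V_E)
    mean: float
    minus2lnL: float
    converged: bool
    n_families_used: int
    ci_95: dict[str, tuple[float, float]] | None = None

    @property
    def total_variance(self) -> float:
        return float(sum(self.raw_variances))


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of nested twin models."""

    delta_minus2lnL: float
    df: int
    mixture_corrected: bool
    p_value: float


@dataclass
class BivariateFit:
    """Bivariate AE Cholesky decomposition of a phenotype pair.

    ``chol_A``/``chol_E`` are the lower-triangular path coefficients
    (x11, x21, x22); ``A_cov`` and ``E_cov`` are the implied 2x2 covariance
    matrices (PSD by construction).  ``rg`` is the genetic correlation,
    NaN (with ``flag``) when either genetic variance is numerically zero;
    ``p_edge`` is the plain chi2(1) likelihood-ratio p-value for dropping
    the genetic covariance path.
    """

    labels: tuple[str, str]
    chol_A: tuple[float, float, float]
    chol_E: tuple[float, float, float]
    A_cov: np.ndarray
    E_cov: np.ndarray
    rg: float
    re: float
    p_edge: float
    minus2lnL: float
    converged: bool
    flag: str = ""


# ---------------------------------------------------------------------------
# moment-based starting values
# ---------------------------------------------------------------------------

def falconer_estimates(cohort: TwinCohort, phenotype: str) -> dict[str, float]:
    """Falconer moment estimates: a2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ."""
    r_mz = cohort.cross_twin_correlation(phenotype, "MZ")
    r_dz = cohort.cross_twin_correlation(phenotype, "DZ")
    a2 = float(np.clip(2.0 * (r_mz - r_dz), 0.0, 0.95))
    c2 = float(np.clip(2.0 * r_dz - r_mz, 0.0, 0.95 - a2))
    e2 = max(1.0 - a2 - c2, 0.05)
    y = cohort.data[phenotype].to_numpy()
    y = y[~np.isnan(y)]
    return {"a2": a2, "c2": c2, "e2": e2,
            "vp": float(np.var(y, ddof=1)), "mean": float(np.mean(y)),
            "r_mz": r_mz, "r_dz": r_dz}


def _check_identifiable(cohort: TwinCohort) -> None:
    for z in ("MZ", "DZ"):
        n_complete = cohort.complete_pairs(z)["family_id"].nunique()
        if n_complete < 2:
            raise ValueError(
                f"model not identifiable: need >= 2 complete {z} pairs, "
                f"found {n_complete}"
            )


def _minimize_restarts(fun, starts: list[np.ndarray]) -> optimize.OptimizeResult:
    best = None
    for x0 in starts:
        res = optimize.minimize(fun, x0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9,
                                         "maxiter": 3000, "maxfev": 3000})
        if best is None or res.fun < best.fun:
            best = res
    # simplex polish from the incumbent tightens the optimum; tolerances are
    # absolute, so stay above float64 resolution of a -2lnL of order 1e4
    polished = optimize.minimize(fun, best.x, method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-9,
                                          "maxiter": 2000, "maxfev": 2000})
    out = polished if polished.fun <= best.fun else best
    out.success = bool(polished.success or best.success)
    return out


# ---------------------------------------------------------------------------
# univariate fitting
# ---------------------------------------------------------------------------

def _univariate_m2ll(groups, model: str):
    def fun(theta: np.ndarray) -> float:
        mu = theta[0]
        if model == "ACE":
            va, vc, ve = theta[1] ** 2, theta[2] ** 2, theta[3] ** 2
        elif model == "AE":
            va, vc, ve = theta[1] ** 2, 0.0, theta[2] ** 2
        elif model == "CE":
            va, vc, ve = 0.0, theta[1] ** 2, theta[2] ** 2
        else:  # E
            va, vc, ve = 0.0, 0.0, theta[1] ** 2
        return _total_m2ll(groups, np.array([mu]),
                           np.array([[va]]), np.array([[vc]]), np.array([[ve]]))
    return fun


def _univariate_starts(est: dict[str, float], model: str, n_restarts: int,
                       rng: np.random.Generator) -> list[np.ndarray]:
    vp, mu = est["vp"], est["mean"]
    base = {"a": np.sqrt(max(est["a2"] * vp, 0.01 * vp)),
            "c": np.sqrt(max(est["c2"] * vp, 0.01 * vp)),
            "e": np.sqrt(max(est["e2"] * vp, 0.05 * vp))}
    order = {"ACE": "ace", "AE": "ae", "CE": "ce", "E": "e"}[model]
    x0 = np.array([mu] + [base[k] for k in order])
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        jitter = rng.uniform(0.5, 1.5, size=len(x0) - 1)
        starts.append(np.concatenate([[mu + rng.normal(0, 0.1 * np.sqrt(vp))],
                                      x0[1:] * jitter]))
    return starts


def fit_univariate(cohort: TwinCohort, phenotype: str, model: str = "ACE",
                   n_restarts: int = 5, restart_seed: int = 1234,
                   compute_ci: bool = False) -> UnivariateFit:
    """Fit a univariate twin model by FIML.

    Requires at least two complete pairs in each zygosity group (otherwise
    A and C are not separately identifiable) and the phenotype present in
    the cohort.  Optimization runs ``n_restarts`` Nelder-Mead starts
    jittered around Falconer moment estimates and keeps the best optimum.
    Set ``compute_ci`` to attach 95% profile-likelihood intervals for the
    standardized components.
    """
    if model not in UNIVARIATE_MODELS:
        raise ValueError(f"model must be one of {UNIVARIATE_MODELS}")
    if phenotype not in cohort.phenotype_labels:
        raise ValueError(f"phenotype {phenotype!r} not in cohort")
    _check_identifiable(cohort)
    groups = _stack_families(cohort, [phenotype])
    est = falconer_estimates(cohort, phenotype)
    rng = np.random.default_rng(restart_seed)
    fun = _univariate_m2ll(groups, model)
    best = _minimize_restarts(fun, _univariate_starts(est, model, n_restarts, rng))

    theta = best.x
    mu = float(theta[0])
    if model == "ACE":
        va, vc, ve = theta[1] ** 2, theta[2] ** 2, theta[3] ** 2
    elif model == "AE":
        va, vc, ve = theta[1] ** 2, 0.0, theta[2] ** 2
    elif model == "CE":
        va, vc, ve = 0.0, theta[1] ** 2, theta[2] ** 2
    else:
        va, vc, ve = 0.0, 0.0, theta[1] ** 2
    vp = va + vc + ve
    n_fam = sum(len(g.data) for g in groups)
    fit = UnivariateFit(
        phenotype=phenotype, model=model,
        a2=float(va / vp), c2=float(vc / vp), e2=float(ve / vp),
        raw_variances=(float(va), float(vc), float(ve)),
        mean=mu, minus2lnL=float(best.fun),
        converged=bool(best.success and best.fun < _PENALTY / 2),
        n_families_used=n_fam,
    )
    if compute_ci:
        fit.ci_95 = {comp: profile_ci(cohort, fit, comp)
                     for comp in _model_components(model)}
    return fit


def _model_components(model: str) -> tuple[str, ...]:
    return {"ACE": ("a2", "c2", "e2"), "AE": ("a2", "e2"),
            "CE": ("c2", "e2"), "E": ("e2",)}[model]


# ---------------------------------------------------------------------------
# nested-model comparison with boundary mixtures
# ---------------------------------------------------------------------------

def compare_models(full: UnivariateFit | BivariateFit,
                   reduced: UnivariateFit | BivariateFit,
                   n_boundary_components: int,
                   df: int | None = None,
                   plain_chi2: bool = False,
                   tolerance: float = 1e-6) -> ModelComparison:
    """Likelihood-ratio test of ``reduced`` nested within ``full``.

    Variance components are bounded below by zero, so under the null the
    LR statistic of a single component is a 50:50 mixture of chi2(0) and
    chi2(1): p = 0.5 * P(chi2(1) > delta).  Dropping A and C jointly uses
    the 25:50:25 chi2(0)/chi2(1)/chi2(2) mixture (``plain_chi2`` substitutes
    an uncorrected chi2(2) for sensitivity checks).  With
    ``n_boundary_components=0`` the test is a plain chi-square with ``df``
    degrees of freedom (e.g. for sign-unrestricted covariance paths).
    """
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    delta = reduced.minus2lnL - full.minus2lnL
    if delta < -tolerance:
        raise ValueError(
            f"reduced model fits better than full by {-delta:.4g} -2lnL units; "
            "restart the full-model optimizer"
        )
    delta = max(0.0, float(delta))
    if n_boundary_components == 0:
        use_df = df if df is not None else 1
        p = float(stats.chi2.sf(delta, use_df)) if delta > 0 else 1.0
        return ModelComparison(delta, use_df, False, p)
    if n_boundary_components == 1:
        p = 0.5 * float(stats.chi2.sf(delta, 1))
        if delta == 0.0:
            p = 0.5
        return ModelComparison(delta, 1, True, p)
    if n_boundary_components == 2:
        if plain_chi2:
            return ModelComparison(delta, 2, False, float(stats.chi2.sf(delta, 2)))
        p = 0.5 * float(stats.chi2.sf(delta, 1)) + 0.25 * float(stats.chi2.sf(delta, 2))
        if delta == 0.0:
            p = 1.0
        return ModelComparison(delta, 2, True, p)
    raise ValueError("n_boundary_components must be 0, 1 or 2")


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _constrained_m2ll(groups, model: str, component: str, value: float,
                      start: np.ndarray) -> tuple[float, tuple[float, float, float]]:
    """Minimize -2lnL with one raw variance fixed; returns (m2ll, variances)."""
    comps = _model_components(model)
    free = [c for c in comps if c != component]

    def unpack(theta):
        vals = {component: value}
        for k, c in enumerate(free):
            vals[c] = theta[1 + k] ** 2
        va = vals.get("a2", 0.0)
        vc = vals.get("c2", 0.0)
        ve = vals.get("e2", 0.0)
        return theta[0], va, vc, ve

    def fun(theta):
        mu, va, vc, ve = unpack(theta)
        return _total_m2ll(groups, np.array([mu]),
                           np.array([[va]]), np.array([[vc]]), np.array([[ve]]))

    res = optimize.minimize(fun, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-9,
                                     "maxiter": 3000, "maxfev": 3000})
    _, va, vc, ve = unpack(res.x)
    return float(res.fun), (va, vc, ve)


def profile_ci(cohort: TwinCohort, fit: UnivariateFit, component: str = "a2",
               level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for a standardized variance component.

    The raw variance of ``component`` is profiled: for each fixed value the
    remaining parameters are re-optimized, and the bounds are where -2lnL
    rises by the chi2(1) quantile of ``level`` (3.84 at 95%) above the
    unconstrained minimum.  The lower bound is truncated at the zero
    boundary, and bounds are reported on the standardized scale (clipped to
    [0, 1]).  A likelihood flat out to ten times the phenotypic variance
    yields (0, 1) with a warning.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; no CI")
    comps = _model_components(fit.model)
    if component not in comps:
        raise ValueError(f"component {component!r} not in model {fit.model}")
    groups = _stack_families(cohort, [fit.phenotype])
    crit = float(stats.chi2.ppf(level, 1))
    target = fit.minus2lnL + crit

    idx = {"a2": 0, "c2": 1, "e2": 2}[component]
    v_hat = fit.raw_variances[idx]
    vp = fit.total_variance
    free = [c for c in comps if c != component]
    start = np.array([fit.mean] + [
        np.sqrt(max(fit.raw_variances[{"a2": 0, "c2": 1, "e2": 2}[c]], 0.01 * vp))
        for c in free
    ])

    def g(v: float) -> tuple[float, float]:
        m2ll, (va, vc, ve) = _constrained_m2ll(groups, fit.model, component, v, start)
        total = va + vc + ve
        std = v / total if total > 0 else 0.0
        return m2ll, std

    def bisect(lo: float, hi: float, g_lo: float, g_hi: float) -> float:
        """Root of g(v) - target between lo (below) and hi (above)."""
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            gm, _ = g(mid)
            if (gm - target) * (g_lo - target) <= 0:
                hi, g_hi = mid, gm
            else:
                lo, g_lo = mid, gm
            if abs(hi - lo) < 1e-6 * max(vp, 1e-12):
                break
        return 0.5 * (lo + hi)

    # lower bound
    g0, _ = g(0.0)
    if g0 <= target or v_hat <= 0:
        lower_std = 0.0
    else:
        v_lo = bisect(0.0, v_hat, g0, fit.minus2lnL)
        _, lower_std = g(v_lo)

    # upper bound: expand until crossing
    cap = 10.0 * max(vp, 1e-8)
    hi = max(v_hat, 0.05 * vp)
    g_hi = None
    while hi < cap:
        hi *= 2.0
        g_hi, _ = g(hi)
        if g_hi > target:
            break
    if g_hi is None or g_hi <= target:
        warnings.warn(f"flat profile likelihood for {component}; CI spans [0, 1]",
                      RuntimeWarning)
        return (0.0, 1.0)
    v_hi = bisect(v_hat, hi, fit.minus2lnL, g_hi)
    _, upper_std = g(v_hi)
    return (float(np.clip(lower_std, 0.0, 1.0)),
            float(np.clip(upper_std, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# bivariate AE Cholesky
# ---------------------------------------------------------------------------

def genetic_correlation(A_cov: np.ndarray) -> float:
    """Genetic correlation: shared genetic covariance standardized by the
    geometric mean of the two genetic variances.  NaN when a diagonal
    genetic variance is numerically zero (rg undefined)."""
    A = np.asarray(A_cov, dtype=float)
    a11, a22, a12 = A[0, 0], A[1, 1], A[0, 1]
    if a11 < _VAR_TOL or a22 < _VAR_TOL:
        return float("nan")
    rg = a12 / np.sqrt(a11 * a22)
    if abs(rg) > 1.0 and abs(rg) - 1.0 < 1e-8:
        rg = np.sign(rg)
    return float(rg)


def _bivariate_m2ll(groups, fix_a21: bool):
    def fun(theta: np.ndarray) -> float:
        mu = theta[:2]
        if fix_a21:
            a11, a22, e11, e21, e22 = theta[2:]
            a21 = 0.0
        else:
            a11, a21, a22, e11, e21, e22 = theta[2:]
        La = np.array([[a11, 0.0], [a21, a22]])
        Le = np.array([[e11, 0.0], [e21, e22]])
        V_A = La @ La.T
        V_E = Le @ Le.T
        return _total_m2ll(groups, mu, V_A, np.zeros((2, 2)), V_E)
    return fun


def _bivariate_starts(cohort: TwinCohort, ph1: str, ph2: str,
                      fix_a21: bool, n_restarts: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    e1 = falconer_estimates(cohort, ph1)
    e2 = falconer_estimates(cohort, ph2)
    # cross-trait cross-twin covariances give a moment start for the
    # genetic covariance: cov_g ~= 2 * (MZ cross - DZ cross)
    mz = cohort.complete_pairs("MZ").sort_values(["family_id", "member_index"])
    dz = cohort.complete_pairs("DZ").sort_values(["family_id", "member_index"])

    def cross_cov(sub: pd.DataFrame) -> float:
        x1 = sub[sub["member_index"] == 1][ph1].to_numpy()
        y2 = sub[sub["member_index"] == 2][ph2].to_numpy()
        x2 = sub[sub["member_index"] == 2][ph1].to_numpy()
        y1 = sub[sub["member_index"] == 1][ph2].to_numpy()
        vals = []
        for a, b in ((x1, y2), (x2, y1)):
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() >= 3:
                vals.append(np.cov(a[ok], b[ok])[0, 1])
        return float(np.mean(vals)) if vals else 0.0

    gcov = float(np.clip(2.0 * (cross_cov(mz) - cross_cov(dz)),
                         -0.9 * np.sqrt(e1["vp"] * e2["vp"]),
                         0.9 * np.sqrt(e1["vp"] * e2["vp"])))
    va1 = max(e1["a2"] * e1["vp"], 0.02 * e1["vp"])
    va2 = max(e2["a2"] * e2["vp"], 0.02 * e2["vp"])
    ve1 = max(e1["e2"] * e1["vp"], 0.05 * e1["vp"])
    ve2 = max(e2["e2"] * e2["vp"], 0.05 * e2["vp"])
    a11 = np.sqrt(va1)
    a21 = gcov / a11 if not fix_a21 else None
    if a21 is not None:
        a22 = np.sqrt(max(va2 - a21 ** 2, 0.01 * e2["vp"]))
    else:
        a22 = np.sqrt(va2)
    e11 = np.sqrt(ve1)
    e21 = 0.0
    e22 = np.sqrt(ve2)
    if fix_a21:
        x0 = np.array([e1["mean"], e2["mean"], a11, a22, e11, e21, e22])
    else:
        x0 = np.array([e1["mean"], e2["mean"], a11, a21, a22, e11, e21, e22])
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        jit = x0.copy()
        jit[2:] = jit[2:] * rng.uniform(0.6, 1.4, size=len(x0) - 2) \
            + rng.normal(0, 0.05 * np.sqrt(e1["vp"]), size=len(x0) - 2)
        jit[:2] += rng.normal(0, 0.1, size=2)
        starts.append(jit)
    return starts


def fit_bivariate_ae(cohort: TwinCohort, phenotype_i: str, phenotype_j: str,
                     n_restarts: int = 5, restart_seed: int = 1234) -> BivariateFit:
    """Fit the bivariate AE Cholesky model for a pair of phenotypes.

    The pair is fitted in canonical (lexicographic) order and mapped back to
    the requested order, so (i, j) and (j, i) return identical rg, re and
    p_edge.  ``p_edge`` compares the full model against the submodel with
    the genetic covariance path fixed to zero (plain chi2(1): the path is
    sign-unrestricted).  When a fitted genetic variance is numerically zero
    the genetic correlation is undefined and flagged.
    """
    if phenotype_i == phenotype_j:
        raise ValueError("phenotypes must differ")
    for ph in (phenotype_i, phenotype_j):
        if ph not in cohort.phenotype_labels:
            raise ValueError(f"phenotype {ph!r} not in cohort")
    _check_identifiable(cohort)
    swap = phenotype_i > phenotype_j
    ph1, ph2 = sorted((phenotype_i, phenotype_j))
    groups = _stack_families(cohort, [ph1, ph2])
    rng = np.random.default_rng(restart_seed)

    full_fun = _bivariate_m2ll(groups, fix_a21=False)
    best = _minimize_restarts(
        full_fun, _bivariate_starts(cohort, ph1, ph2, False, n_restarts, rng))
    red_fun = _bivariate_m2ll(groups, fix_a21=True)
    best_red = _minimize_restarts(
        red_fun, _bivariate_starts(cohort, ph1, ph2, True, n_restarts, rng))

    mu = best.x[:2]
    a11, a21, a22, e11, e21, e22 = best.x[2:]
    # canonicalize path signs (L and -L imply the same covariance)
    if a11 < 0:
        a11, a21 = -a11, -a21
    if a22 < 0:
        a22 = -a22
    if e11 < 0:
        e11, e21 = -e11, -e21
    if e22 < 0:
        e22 = -e22
    La = np.array([[a11, 0.0], [a21, a22]])
    Le = np.array([[e11, 0.0], [e21, e22]])
    A_cov = La @ La.T
    E_cov = Le @ Le.T

    delta = max(0.0, float(best_red.fun - best.fun))
    p_edge = float(stats.chi2.sf(delta, 1)) if delta > 0 else 1.0

    rg = genetic_correlation(A_cov)
    ev_ok = E_cov[0, 0] > _VAR_TOL and E_cov[1, 1] > _VAR_TOL
    re = float(E_cov[0, 1] / np.sqrt(E_cov[0, 0] * E_cov[1, 1])) if ev_ok else float("nan")
    flag = ""
    if np.isnan(rg):
        flag = "degenerate_genetic_variance"

    labels = (ph1, ph2)
    if swap:
        # present results in the caller's order; rg/re/p are order-invariant
        perm = np.array([[0, 1], [1, 0]])
        A_cov = perm @ A_cov @ perm
        E_cov = perm @ E_cov @ perm
        labels = (ph2, ph1)
        mu = mu[::-1]
        La = np.linalg.cholesky(A_cov + 1e-12 * np.eye(2))
        Le = np.linalg.cholesky(E_cov + 1e-12 * np.eye(2))
        a11, a21, a22 = La[0, 0], La[1, 0], La[1, 1]
        e11, e21, e22 = Le[0, 0], Le[1, 0], Le[1, 1]

    return BivariateFit(
        labels=labels,
        chol_A=(float(a11), float(a21), float(a22)),
        chol_E=(float(e11), float(e21), float(e22)),
        A_cov=A_cov, E_cov=E_cov,
        rg=rg, re=re, p_edge=p_edge,
        minus2lnL=float(best.fun),
        converged=bool(best.fun < _PENALTY / 2 and best_red.fun < _PENALTY / 2),
        flag=flag,
    )


def fits_to_frame(fits: Sequence[UnivariateFit],
                  comparisons: Mapping[str, Mapping[str, ModelComparison]] | None = None
                  ) -> pd.DataFrame:
    """Tidy one-row-per-phenotype table of univariate estimates and tests."""
    rows = []
    for f in fits:
        row = {
            "phenotype": f.phenotype, "model": f.model,
            "a2": f.a2, "c2": f.c2, "e2": f.e2,
            "mean": f.mean, "minus2lnL": f.minus2lnL,
            "converged": f.converged, "n_families": f.n_families_used,
        }
        if f.ci_95:
            for comp, (lo, hi) in f.ci_95.items():
                row[f"{comp}_ci_lower"] = lo
                row[f"{comp}_ci_upper"] = hi
        if comparisons and f.phenotype in comparisons:
            for test, cmp_res in comparisons[f.phenotype].items():
                row[f"p_{test}"] = cmp_res.p_value
        rows.append(row)
    return pd.DataFrame(rows)
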