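"""Assembly of the genetic correlation matrix across all phenotype pairs.

Phenotypes are first residualized for nuisance covariates (age, scanner site
and the relevant global size measure — mean thickness for CT phenotypes,
total surface area for SA phenotypes).  All univariate and all pairwise
bivariate AE fits are then orchestrated, and the labeled symmetric rg matrix
with its companion edge p-value matrix is assembled.  Pairs whose fit fails
or is degenerate are flagged missing rather than imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from twingraph.biometric_models import (
    BivariateFit,
    UnivariateFit,
    compare_models,
    fit_bivariate_ae,
    fit_univariate,
)
from twingraph.synthetic_twins import TwinCohort

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "scanner", "global_measure")


@dataclass
class GeneticCorrelationMatrix:
    """Labeled symmetric genetic correlation matrix with edge p-values.

    ``rg`` has unit diagonal and NaN for flagged pairs; ``p`` is NaN on the
    diagonal and for flagged pairs.  ``fit_flags`` records per-pair notes
    (non-convergence, degenerate genetic variance).
    """

    labels: list[str]
    rg: pd.DataFrame
    p: pd.DataFrame
    fit_flags: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        n = len(self.labels)
        return n * (n - 1) // 2

    @property
    def n_missing_pairs(self) -> int:
        vals = self.rg.to_numpy()[np.triu_indices(len(self.labels), k=1)]
        return int(np.isnan(vals).sum())

    def edge_table(self) -> pd.DataFrame:
        """Long-format (label_i, label_j, rg, p, flag) table, one row per
        unordered pair in lexicographic order — the canonical exchange
        format with the network stage."""
        rows = []
        for i, j in itertools.combinations(sorted(self.labels), 2):
            rows.append({
                "label_i": i, "label_j": j,
                "rg": self.rg.loc[i, j], "p": self.p.loc[i, j],
                "flag": self.fit_flags.get((i, j), ""),
            })
        return pd.DataFrame(rows)

    @classmethod
    def from_edge_table(cls, edges: pd.DataFrame) -> "GeneticCorrelationMatrix":
        labels = sorted(set(edges["label_i"]) | set(edges["label_j"]))
        rg = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
        p = pd.DataFrame(np.full((len(labels), len(labels)), np.nan),
                         index=labels, columns=labels)
        flags: dict[tuple[str, str], str] = {}
        for _, row in edges.iterrows():
            i, j = row["label_i"], row["label_j"]
            rg.loc[i, j] = rg.loc[j, i] = row["rg"]
            p.loc[i, j] = p.loc[j, i] = row["p"]
            if isinstance(row.get("flag"), str) and row["flag"]:
                flags[tuple(sorted((i, j)))] = row["flag"]
        return cls(labels, rg, p, flags)


def residualize(cohort: TwinCohort, phenotype: str,
                covariates: tuple[str, ...] = DEFAULT_COVARIATES) -> TwinCohort:
    """Replace one phenotype by its OLS residuals on the named covariates.

    Residuals are computed in a single pooled regression across all observed
    individuals (family clustering is ignored for the mean model) and are
    mean-centered because the design includes an intercept.
    """
    df = cohort.data.copy()
    missing_cov = [c for c in covariates if c not in df.columns]
    if missing_cov:
        raise ValueError(f"covariates absent from cohort: {missing_cov}")
    obs = ~df[phenotype].isna()
    X = np.column_stack([np.ones(int(obs.sum()))] +
                        [df.loc[obs, c].to_numpy(dtype=float) for c in covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which covariate fails to add rank
        bad = []
        cols = [np.ones(int(obs.sum()))]
        for c in covariates:
            trial = np.column_stack(cols + [df.loc[obs, c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(df.loc[obs, c].to_numpy(dtype=float))
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    y = df.loc[obs, phenotype].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    df.loc[obs, phenotype] = y - X @ beta
    return TwinCohort(df, cohort.phenotype_labels)


def residualize_panel(cohort: TwinCohort,
                      base_covariates: tuple[str, ...] = ("age", "scanner"),
                      global_covariate: str = "global_measure") -> TwinCohort:
    """Residualize every panel phenotype for its covariate set.

    The global size covariate applies to every measure; with panel-scheme
    labels it plays the role of mean CT for thickness measures and total SA
    for surface-area measures, while age and scanner apply to all.
    Phenotypes whose labels do not follow the panel scheme are adjusted with
    the full default covariate set.
    """
    out = cohort
    for ph in cohort.phenotype_labels:
        covs = base_covariates + (global_covariate,)
        out = residualize(out, ph, covs)
    return out


def run_all_fits(cohort: TwinCohort, labels: list[str] | None = None,
                 n_restarts: int = 5,
                 cache: dict | None = None,
                 progress_every: int = 100) -> GeneticCorrelationMatrix:
    """Run P univariate and P(P-1)/2 bivariate AE fits; assemble matrices.

    Pairs are visited in lexicographic order; ``cache`` (keyed on the
    unordered label pair) makes the run resumable and re-running on a warm
    cache reproduces the identical matrix.  A pair failing its
    preconditions or flagged degenerate yields a missing matrix entry and
    the run continues.
    """
    if labels is None:
        labels = list(cohort.phenotype_labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    labels = sorted(labels)
    cache = cache if cache is not None else {}

    uni: dict[str, UnivariateFit] = {}
    for ph in labels:
        key = ("uni", ph)
        if key not in cache:
            cache[key] = fit_univariate(cohort, ph, model="AE",
                                        n_restarts=n_restarts)
        uni[ph] = cache[key]

    n = len(labels)
    rg = pd.DataFrame(np.eye(n), index=labels, columns=labels)
    p = pd.DataFrame(np.full((n, n), np.nan), index=labels, columns=labels)
    flags: dict[tuple[str, str], str] = {}

    pairs = list(itertools.combinations(labels, 2))
    for k, (i, j) in enumerate(pairs, start=1):
        key = ("bi", i, j)
        if key not in cache:
            try:
                cache[key] = fit_bivariate_ae(cohort, i, j, n_restarts=n_restarts)
            except ValueError as exc:
                cache[key] = exc
        res = cache[key]
        if isinstance(res, Exception):
            rg.loc[i, j] = rg.loc[j, i] = np.nan
            flags[(i, j)] = f"fit_error: {res}"
        else:
            fit: BivariateFit = res
            if not fit.converged:
                rg.loc[i, j] = rg.loc[j, i] = np.nan
                flags[(i, j)] = "not_converged"
            elif fit.flag:
                rg.loc[i, j] = rg.loc[j, i] = np.nan
                flags[(i, j)] = fit.flag
            else:
                rg.loc[i, j] = rg.loc[j, i] = fit.rg
                p.loc[i, j] = p.loc[j, i] = fit.p_edge
        if progress_every and k % progress_every == 0:
            logger.info("bivariate fits: %d / %d", k, len(pairs))

    result = GeneticCorrelationMatrix(labels, rg, p, flags)
    if result.n_missing_pairs:
        logger.warning("%d of %d pairs flagged missing",
                       result.n_missing_pairs, result.n_pairs)
    return result


def shared_environment_screen(cohort: TwinCohort,
                              labels: list[str] | None = None,
                              alpha: float = 0.05,
                              n_restarts: int = 5) -> dict:
    """Test every phenotype for significant shared-environment variance.

    Fits ACE and the nested AE model per phenotype and applies the
    boundary-corrected (halved-p) test of C.  An empty significant list
    justifies dropping C from the bivariate models (AE approved); a
    non-empty list warns that the AE simplification may not hold.
    """
    if labels is None:
        labels = list(cohort.phenotype_labels)
    records = []
    significant = []
    for ph in labels:
        full = fit_univariate(cohort, ph, model="ACE", n_restarts=n_restarts)
        reduced = fit_univariate(cohort, ph, model="AE", n_restarts=n_restarts)
        cmp_res = compare_models(full, reduced, n_boundary_components=1)
        records.append({"phenotype": ph, "c2": full.c2,
                        "p_C": cmp_res.p_value})
        if cmp_res.p_value < alpha:
            significant.append(ph)
    approved = len(significant) == 0
    if not approved:
        logger.warning(
            "significant shared environment for %s; the AE simplification "
            "may not hold on this data", significant)
    return {"significant": significant, "ae_approved": approved,
            "alpha": alpha, "tests": pd.DataFrame(records)}


def screen_from_pvalues(p_C: pd.Series, alpha: float = 0.05) -> dict:
    """Shared-environment screen applied to precomputed C-test p-values
    (e.g. a published univariate table)."""
    significant = list(p_C.index[p_C < alpha])
    return {"significant": significant, "ae_approved": len(significant) == 0,
            "alpha": alpha}
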