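# Methods

## Biometric model

The package fits the classical twin decomposition of phenotypic variance
into additive-genetic (A), shared-environment (C) and unique-environment
(E) components.  The identifying assumptions are the standard ones:
additive-genetic deviates correlate 1.0 between MZ co-twins and 0.5 between
DZ co-twins (random mating, no dominance, no gene–environment interaction);
shared-environment deviates correlate 1.0 within every pair regardless of
zygosity (equal-environments assumption); unique-environment deviates —
which also absorb measurement error — are independent across individuals.
Phenotypes are assumed multivariate normal within families; heavy-tailed
alternatives are out of scope.

### Likelihood

Each family's phenotypes are stacked into a length-2P vector (P phenotypes
per twin).  The model-implied family covariance has within-person blocks
V_A + V_C + V_E and cross-twin blocks r·V_A + V_C with r = 1 (MZ) or
0.5 (DZ).  Estimation is full-information maximum likelihood: a family
contributes the multivariate-normal log density of its observed sub-vector,
obtained by deleting the rows/columns of missing members or entries — never
by dropping the family.  Families are grouped by (zygosity, missingness
pattern) so the likelihood is evaluated with one Cholesky factorization and
one vectorized quadratic form per group; a non-positive-definite implied
covariance returns a large finite penalty so the optimizer stays in bounds.

### Parameterization and optimization

Variance components are parameterized through their square roots (path
coefficients), which enforces nonnegativity without explicit bounds; in the
bivariate model the 2×2 genetic and environmental covariances are
lower-triangular Cholesky products, positive semidefinite by construction.
Optimization is Nelder–Mead over (mean(s), paths) with 5 restarts (default)
jittered around Falconer moment estimates — a² ≈ 2(r_MZ − r_DZ),
c² ≈ 2r_DZ − r_MZ on double-entered cross-twin correlations — followed by a
simplex polish from the best incumbent.  Polish tolerances are absolute
(1e-9 on −2lnL), chosen to sit above float64 resolution at −2lnL values of
order 10⁴.  Refits from independent restart seeds reproduce the best −2lnL
to well under 1e-4 in the test suite.

A bivariate pair is always fitted in lexicographic label order and mapped
back to the caller's order, so fits of (i, j) and (j, i) are identical by
construction rather than merely close.  Path-sign indeterminacy (L and −L
imply the same covariance) is resolved by canonicalizing diagonal paths to
be nonnegative.

### Hypothesis tests

A variance component is bounded below by zero, so the likelihood-ratio
statistic for dropping one component is asymptotically a 50:50 mixture of
χ²(0) and χ²(1); the p-value is half the χ²(1) tail.  Dropping A and C
jointly uses the 25:50:25 χ²(0)/χ²(1)/χ²(2) mixture from standard boundary
theory (a plain χ²(2) is available behind a flag for sensitivity).  The
genetic-covariance path of the bivariate model is sign-unrestricted, so the
edge test is an uncorrected χ²(1).  The test suite verifies the A-test's
type-I rate empirically: 500 null cohorts of 100 MZ + 70 DZ pairs give a
rejection rate within binomial 95% bounds of 0.05.

### Confidence intervals

95% intervals are profile-likelihood based: the raw variance of the target
component is fixed on a grid located by bisection, the remaining parameters
are re-optimized, and the bounds are where −2lnL rises 3.84 above the
unconstrained minimum.  Bounds are reported on the standardized scale by
standardizing at each constrained optimum; the lower bound truncates at the
zero boundary and standardized bounds clip to [0, 1].  This profiles the
raw variance rather than the standardized ratio itself; the two differ only
through the mild dependence of the total variance on the constraint, and
the resulting intervals show the asymmetry characteristic of twin-model
CIs (wide toward zero, tight above).  A profile still below the criterion
at ten times the phenotypic variance is declared flat and yields (0, 1)
with a warning.

Degenerate genetic correlations — either fitted genetic variance below
1e-6 — are recorded as missing, flagged, and excluded from the network
rather than imputed.

## Synthetic cohorts

The generator draws cohorts directly from the biometric model: one shared
genetic deviate per MZ pair; DZ genetic deviates as g_common + g_own with
Var(g_common) = Var(g_own) = A/2 (distributionally equivalent to joint
sampling at cross-twin correlation 0.5, chosen for clarity); C shared
within family; E independent per individual.  Unpaired twins are generated
as full pairs with one member dropped at random, alternating zygosity.
Covariates are simulation fixtures: age uniform on [51, 60] years (matching
a midlife twin cohort), scanner a Bernoulli(0.5) site indicator, and a
standard-normal global size measure; their effects enter linearly with
user-chosen slopes.  Default family counts (100 MZ pairs, 70 DZ pairs, 89
singletons) mirror that cohort's composition.

What the generator does *not* emulate: non-normal phenotype distributions,
age–zygosity confounding, site-specific variance differences, spatial
structure of the underlying cortical surfaces, or selection effects.
Passing parameter-recovery tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not robustness to their
violation.

Within-pair correlation levels for synthetic panels were chosen to span the
published heritability range of the 48-measure panel (a² roughly 0.2–0.7)
rather than to match any particular dataset; the bilateral-structure helper
builds A matrices with homologue genetic correlation 0.8 and configurable
background correlation.

## Covariate adjustment

Phenotypes are residualized before model fitting by pooled OLS on age,
scanner and the global size measure (playing the role of mean CT for
thickness measures and total SA for area measures), with the intercept
absorbed so residuals are centered.  Family clustering is ignored in this
mean model; variance-component estimates are insensitive to the mean-model
choice at these sample sizes.  Re-residualizing at the regional stage is
configurable — callers may skip it if their inputs are already adjusted.

## Network analysis

Edges are genetic correlations with p < α (default 0.05, uncorrected —
the analyses are exploratory; an FDR mode exists but is off by default),
binarized into an undirected unweighted graph with rg signs retained for
reporting.  Conventions, chosen where the field varies:

- **Mean degree** is computed under both conventions — E/N ("paper") and
  2E/N ("standard") — and labeled; the E/N convention feeds the
  small-world estimability comparison against ln N.
- **Clustering** of a degree-<2 node is 0 and included in the mean.
- **Path length** on disconnected graphs averages over reachable ordered
  pairs only, with the excluded count reported.
- **Efficiencies**: global efficiency averages 1/d with 1/∞ = 0; local
  efficiency averages the global efficiency of each node's
  neighbor-induced subgraph.
- **Rich club**: Φk is computed for every integer k in [0, k_max − 1] on
  the subgraph induced by nodes of degree > k; Φ_unc(k) = k²/(⟨k⟩N) with
  ⟨k⟩ = 2E/N, and ρ_unc(k) = Φk/Φ_unc(k).  The full profile is emitted so
  any printed (E, N) pair can be matched by lookup.
- **Hubs** are nodes with degree above mean + 1 SD.

### Null networks

The edge-sampling null draws node pairs uniformly and redraws self-pairs
and duplicates, holding the edge count exactly fixed — i.e. a uniform
G(n, m) random graph.  A raw-collision variant (duplicates collapse, edge
count may fall short) is exposed behind a flag for sensitivity.  A
Watts–Strogatz mode rewires a ring lattice of even degree nearest 2E/N;
the rewiring probability is not dictated by the analysis being reproduced,
so the default is 0.1 (the classic small-world regime).  Observed C and L
are located as quantiles (fraction of replicates at or below the observed
value) within the null distribution; σ is reported both as raw C/L and as
the ratio of the null-quantile positions, without forcing an
interpretation of either.

All graph metrics are validated against independent naive implementations
(explicit triangle enumeration, Floyd–Warshall distances, per-k subgraph
reconstruction) on 100 random graphs per test run.

## Cluster ordering

Measures are clustered on Euclidean distances between their rg-row
profiles (the unit self-correlation entry included, matching
profile-distance behavior of standard heatmap routines), with complete
linkage by default (average/single selectable).  Raw rg profiles — not
|rg| — feed the distance.  Missing entries are imputed to 0 for clustering
only, with a logged count.  Ties in merge heights follow the
nearest-neighbor-chain order of the linkage implementation, which is
deterministic for a given input ordering (not the smallest-original-index
rule); label-order invariance holds up to this tie rule.

## Pipeline and reproducibility

`run_pipeline` chains simulate/load → validate → residualize → univariate
fits with the shared-environment screen → all pairwise bivariate fits →
cluster ordering → network metrics per subset (all/CT/SA) with null
distributions and sparsity sweeps.  Every stochastic stage consumes a named
sub-seed derived from the master seed by hashing (seed, stage-name), and
the manifest records stage seeds, timings and SHA-256 hashes of every
output, so any stage can be reproduced in isolation.  The
shared-environment screen mirrors the published modeling decision: if no
phenotype shows a significant C component at α = 0.05, bivariate models
drop C (AE); otherwise a warning records that the simplification may not
hold.

### Problem sizes

Default test and demo sizes are chosen to exercise every code path at
interactive cost: the demo panel uses 6 bilateral measures at 300 pairs
per zygosity; parameter-recovery checks use 2000 pairs per zygosity (where
the ML estimator's sampling SD for a² is about 0.02); the type-I
calibration uses 500 replicates at the 100 MZ + 70 DZ cohort scale; null
distributions default to 1000 replicates (200 in the demo).  The
48-measure, 1128-pair configuration runs through the same code path and is
exposed via `plan_parcellation_panel()`.

## Known limitations

- The FIML mean model is a single grand mean per phenotype (no
  means-by-zygosity or covariates-in-means options); covariates are
  handled by prior residualization.
- No dominance component, sex-limitation or heterogeneity models.
- Profile CIs re-optimize per bisection step and are therefore the most
  expensive routine; they are off by default in batch fitting.
- The genetic correlation matrix is assembled from pairwise fits, so it is
  not guaranteed positive semidefinite as a whole — a known property of
  pairwise rg assembly, and the reason it feeds clustering and graph
  analysis rather than confirmatory factor models.
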