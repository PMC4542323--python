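"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: likelihoods
are evaluated with scipy's multivariate normal on explicitly assembled
family covariances, and graph metrics are computed by explicit triangle
enumeration and Floyd-Warshall distances on dense matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def stacked_family_loglik(y, means, V_A, V_C, V_E, zygosity):
    """Log density of a family's observed phenotypes, assembled explicitly.

    ``y`` is (2, P) with NaN for missing entries/members.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    P = y.shape[1]
    r = 1.0 if zygosity == "MZ" else 0.5
    within = V_A + V_C + V_E
    cross = r * V_A + V_C
    sigma = np.zeros((2 * P, 2 * P))
    sigma[:P, :P] = within
    sigma[P:, P:] = within
    sigma[:P, P:] = cross
    sigma[P:, :P] = cross
    mu = np.concatenate([means, means])
    stacked = y.reshape(-1)
    obs = ~np.isnan(stacked)
    return multivariate_normal.logpdf(stacked[obs], mean=mu[obs],
                                      cov=sigma[np.ix_(obs, obs)])


def cohort_m2ll(cohort, phenotypes, means, V_A, V_C, V_E):
    """-2 lnL of a whole cohort by per-family scipy evaluation."""
    total = 0.0
    df = cohort.data
    for _, fam in df.groupby("family_id"):
        zyg = fam["zygosity"].iloc[0]
        y = np.full((2, len(phenotypes)), np.nan)
        for _, row in fam.iterrows():
            y[int(row["member_index"]) - 1] = [row[p] for p in phenotypes]
        total += stacked_family_loglik(y, means, V_A, V_C, V_E, zyg)
    return -2.0 * total


# ---------------------------------------------------------------------------
# graph metrics
# ---------------------------------------------------------------------------

def clustering_coefficient(adj):
    """Mean nodal clustering by explicit triangle enumeration."""
    a = np.asarray(adj, dtype=bool)
    n = len(a)
    cs = []
    for i in range(n):
        nbrs = np.where(a[i])[0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = 0
        for x in range(k):
            for y in range(x + 1, k):
                if a[nbrs[x], nbrs[y]]:
                    links += 1
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs)) if n else float("nan")


def floyd_warshall(adj):
    a = np.asarray(adj, dtype=bool)
    n = len(a)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def path_length_and_efficiency(adj):
    """(L over reachable ordered pairs, global efficiency, unreachable count)."""
    d = floyd_warshall(adj)
    n = len(d)
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    reach = np.isfinite(vals)
    L = float(vals[reach].mean()) if reach.any() else float("nan")
    inv = np.where(np.isfinite(vals), 1.0 / np.where(vals == 0, np.inf, vals), 0.0)
    geff = float(inv.sum() / (n * (n - 1))) if n > 1 else float("nan")
    return L, geff, int((~reach).sum())


def local_efficiency(adj):
    a = np.asarray(adj, dtype=bool)
    n = len(a)
    effs = []
    for i in range(n):
        nbrs = np.where(a[i])[0]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        _, geff, _ = path_length_and_efficiency(sub)
        effs.append(geff)
    return float(np.mean(effs)) if n else float("nan")


def rich_club_profile(adj):
    """Per-k (k, N_gt_k, E_gt_k, phi_k) by explicit subgraph construction."""
    a = np.asarray(adj, dtype=bool)
    deg = a.sum(axis=1)
    k_max = int(deg.max()) if len(deg) else 0
    rows = []
    for k in range(k_max):
        members = np.where(deg > k)[0]
        sub = a[np.ix_(members, members)]
        n_gt = len(members)
        e_gt = int(sub.sum()) // 2
        phi = (2.0 * e_gt / (n_gt * (n_gt - 1))) if n_gt >= 2 else float("nan")
        rows.append((k, n_gt, e_gt, phi))
    return rows


def naive_complete_linkage_cophenetic(dist):
    """Cophenetic distance matrix from a naive O(n^3) complete-linkage
    agglomeration on a condensed-style square distance matrix."""
    d = np.asarray(dist, dtype=float).copy()
    n = len(d)
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    active = list(range(len(clusters)))
    while len(active) > 1:
        best = (np.inf, None, None)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                h = max(d[x, y] for x in clusters[a] for y in clusters[b])
                if h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        for x in clusters[a]:
            for y in clusters[b]:
                coph[x, y] = coph[y, x] = h
        clusters.append(clusters[a] + clusters[b])
        active = [c for c in active if c not in (a, b)] + [len(clusters) - 1]
    return coph
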