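"""Binary genetic-correlation networks: small-world, efficiency, rich club.

Edges connect measure pairs whose genetic correlation is significant at the
chosen alpha (0.05 by default, uncorrected — the analyses are exploratory);
edges are binarized, giving an undirected unweighted graph, with the rg sign
retained for reporting.  Whole-graph statistics (clustering coefficient C,
characteristic path length L, sigma = C/L, local/global efficiency) are
referenced against simulated null networks with matched node and edge
counts, and rich-club organization is profiled over the full degree range.

Two mean-degree conventions are carried side by side: ``paper`` (E/N, used
for the small-world estimability comparison against ln N) and ``standard``
(2E/N, the graph-theoretic mean degree).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from twingraph.synthetic_twins import parse_label

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class BinaryNetwork:
    """Undirected unweighted thresholded network over measure labels."""

    labels: list[str]
    adjacency: np.ndarray          # symmetric bool, zero diagonal
    edge_signs: dict[tuple[str, str], int]
    alpha: float

    def __post_init__(self) -> None:
        a = self.adjacency
        if a.shape != (len(self.labels), len(self.labels)):
            raise ValueError("adjacency shape does not match labels")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        idx = np.argwhere(np.triu(self.adjacency, k=1))
        g.add_edges_from((self.labels[i], self.labels[j]) for i, j in idx)
        return g

    def signed_edge_list(self, rg_lookup=None) -> pd.DataFrame:
        rows = []
        for (i, j), sign in sorted(self.edge_signs.items()):
            row = {"source": i, "target": j, "sign": sign}
            if rg_lookup is not None:
                row["rg"] = rg_lookup(i, j)
            rows.append(row)
        return pd.DataFrame(rows, columns=["source", "target", "sign"] +
                            (["rg"] if rg_lookup is not None else []))


def _subset_labels(labels: list[str], subset: str) -> list[str]:
    if subset == "all":
        return list(labels)
    if subset not in ("CT", "SA"):
        raise ValueError("subset must be 'all', 'CT' or 'SA'")
    picked = []
    for lab in labels:
        try:
            _, _, measure = parse_label(lab)
        except ValueError:
            continue
        if measure == subset:
            picked.append(lab)
    return picked


def build_network(edge_table: pd.DataFrame, alpha: float = 0.05,
                  subset: str = "all") -> BinaryNetwork:
    """Threshold the long-format edge table into a binary network.

    An edge is present iff its rg is defined and its p-value is below
    ``alpha``; each unordered pair counts once.  ``subset`` restricts the
    node set to CT or SA measures (labels must follow the panel scheme for
    subsetting).  An empty subset yields a valid empty network.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    all_labels = sorted(set(edge_table["label_i"]) | set(edge_table["label_j"]))
    labels = sorted(_subset_labels(all_labels, subset))
    if not labels:
        logger.warning("subset %r selects no labels; empty network", subset)
        return BinaryNetwork([], np.zeros((0, 0), dtype=bool), {}, alpha)
    pos = {lab: k for k, lab in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=bool)
    signs: dict[tuple[str, str], int] = {}
    for _, row in edge_table.iterrows():
        i, j = row["label_i"], row["label_j"]
        if i not in pos or j not in pos:
            continue
        rg, p = row["rg"], row["p"]
        if np.isnan(rg) or np.isnan(p):
            continue
        if p < alpha:
            a, b = pos[i], pos[j]
            adj[a, b] = adj[b, a] = True
            signs[tuple(sorted((i, j)))] = 1 if rg >= 0 else -1
    return BinaryNetwork(labels, adj, signs, alpha)


# ---------------------------------------------------------------------------
# whole-graph metrics
# ---------------------------------------------------------------------------

@dataclass
class GraphMetrics:
    """Whole-graph statistics of a binary network.

    ``mean_degree_paper`` is E/N and ``mean_degree_standard`` is 2E/N; the
    former is the convention compared against ln(N) in the small-world
    estimability check.  ``L`` averages shortest-path lengths over reachable
    ordered pairs only; ``n_unreachable_pairs`` counts the excluded ordered
    pairs.  ``sigma`` is the raw C/L ratio.
    """

    n_nodes: int
    n_edges: int
    mean_degree_paper: float
    mean_degree_standard: float
    ln_n_nodes: float
    sparsity: float
    C: float
    L: float
    sigma: float
    degrees: pd.Series = field(repr=False)
    local_efficiency: float = float("nan")
    global_efficiency: float = float("nan")
    n_unreachable_pairs: int = 0


def graph_metrics(net: BinaryNetwork) -> GraphMetrics:
    """Clustering, path length, efficiency and degree statistics.

    Nodal clustering is 2*triangles_i / (k_i (k_i - 1)), zero for degree < 2,
    and C is the unweighted mean over all nodes.  L is the mean shortest-path
    length over reachable ordered pairs; unreachable pairs are excluded and
    counted.  Global efficiency averages 1/d over distinct pairs (1/inf = 0);
    local efficiency averages, over nodes, the global efficiency of each
    node's neighbor-induced subgraph.
    """
    g = net.graph
    n, m = net.n_nodes, net.n_edges
    degrees = pd.Series({lab: d for lab, d in g.degree()},
                        name="degree").reindex(net.labels)
    C = float(nx.average_clustering(g)) if n > 0 else float("nan")

    tot_dist = 0.0
    n_reach = 0
    inv_sum = 0.0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                tot_dist += d
                n_reach += 1
                inv_sum += 1.0 / d
    n_ordered = n * (n - 1)
    L = tot_dist / n_reach if n_reach else float("nan")
    global_eff = inv_sum / n_ordered if n_ordered else float("nan")
    local_eff = float(nx.local_efficiency(g)) if n > 0 else float("nan")

    sparsity = m / (n * (n - 1) / 2) if n > 1 else float("nan")
    sigma = C / L if (n_reach and L > 0) else float("nan")
    return GraphMetrics(
        n_nodes=n, n_edges=m,
        mean_degree_paper=m / n if n else float("nan"),
        mean_degree_standard=2 * m / n if n else float("nan"),
        ln_n_nodes=math.log(n) if n else float("nan"),
        sparsity=sparsity, C=C, L=L, sigma=sigma,
        degrees=degrees,
        local_efficiency=local_eff, global_efficiency=global_eff,
        n_unreachable_pairs=n_ordered - n_reach,
    )


def sparsity_from_counts(n_edges: int, n_nodes: int) -> float:
    """Edge count as a fraction of possible unordered pairs."""
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


def mean_degree_from_counts(n_edges: int, n_nodes: int,
                            convention: str = "paper") -> float:
    """Mean degree under either convention: E/N ('paper') or 2E/N."""
    if convention == "paper":
        return n_edges / n_nodes
    if convention == "standard":
        return 2 * n_edges / n_nodes
    raise ValueError("convention must be 'paper' or 'standard'")


@dataclass
class SmallWorldDecision:
    estimable: bool
    mean_degree: float
    ln_n: float
    convention: str


def small_world_estimability(metrics: GraphMetrics,
                             convention: str = "paper") -> SmallWorldDecision:
    """Small-world statistics are considered estimable when the mean degree
    (under the chosen convention) exceeds ln(N)."""
    md = (metrics.mean_degree_paper if convention == "paper"
          else metrics.mean_degree_standard)
    if convention not in ("paper", "standard"):
        raise ValueError("convention must be 'paper' or 'standard'")
    return SmallWorldDecision(bool(md > metrics.ln_n_nodes), md,
                              metrics.ln_n_nodes, convention)


def sigma_ratio(C_quantity: float, L_quantity: float) -> float:
    """Ratio of a clustering quantity to a path-length quantity.

    Applied both to raw metrics and to null-referenced quantities; a zero
    denominator yields NaN (undefined)."""
    if L_quantity == 0 or np.isnan(L_quantity):
        logger.warning("sigma undefined: zero or NaN denominator")
        return float("nan")
    return float(C_quantity / L_quantity)


# ---------------------------------------------------------------------------
# null networks
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Per-replicate C and L for simulated matched-size null networks."""

    reps: int
    seed: int
    mode: str
    C_values: np.ndarray
    L_values: np.ndarray
    observed_quantile_C: float | None = None
    observed_quantile_L: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"replicate": np.arange(self.reps),
                             "C": self.C_values, "L": self.L_values})


def _sample_edges(n_nodes: int, n_edges: int,
                  rng: np.random.Generator,
                  allow_collisions: bool) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    if allow_collisions:
        # raw recipe: node pairs drawn with replacement; self-pairs and
        # duplicates silently collapse, so the realized edge count may drop
        for _ in range(n_edges):
            u, v = rng.integers(0, n_nodes, size=2)
            if u != v:
                g.add_edge(int(u), int(v))
        return g
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_edges:
        u, v = rng.integers(0, n_nodes, size=2)
        if u == v:
            continue
        chosen.add((min(u, v), max(u, v)))
    g.add_edges_from(chosen)
    return g


def random_network(n_nodes: int, n_edges: int, seed: int = 0,
                   allow_collisions: bool = False) -> BinaryNetwork:
    """One uniformly sampled simple network with the given size (the
    single-replicate building block of the edge-sampling null)."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not allow_collisions and n_edges > max_edges:
        raise ValueError(f"cannot place {n_edges} simple-graph edges on "
                         f"{n_nodes} nodes (max {max_edges})")
    rng = np.random.default_rng(seed)
    g = _sample_edges(n_nodes, n_edges, rng, allow_collisions)
    labels = [f"n{u:02d}" for u in range(n_nodes)]
    adj = np.zeros((n_nodes, n_nodes), dtype=bool)
    for u, v in g.edges():
        adj[u, v] = adj[v, u] = True
    return BinaryNetwork(labels, adj, {}, alpha=1.0)


def simulate_null(n_nodes: int, n_edges: int, reps: int = 1000,
                  seed: int = 0, mode: str = "edge_sampling",
                  observed_C: float | None = None,
                  observed_L: float | None = None,
                  ws_rewire_p: float = 0.1,
                  allow_collisions: bool = False) -> NullDistribution:
    """Simulate matched-size null networks and collect C and L.

    ``edge_sampling`` draws node pairs uniformly (with replacement) and
    redraws self-pairs and duplicate edges so every replicate is a simple
    graph with exactly ``n_edges`` edges; ``allow_collisions=True`` exposes
    the raw variant in which collisions are kept and the edge count can fall
    short.  ``watts_strogatz`` rewires a ring lattice with even degree
    nearest to 2E/N and rewiring probability ``ws_rewire_p``.  Observed
    quantiles locate the observed C and L within the simulated
    distributions (fraction of replicates at or below the observed value).
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not allow_collisions and n_edges > max_edges:
        raise ValueError(f"cannot place {n_edges} simple-graph edges on "
                         f"{n_nodes} nodes (max {max_edges})")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    Cs = np.empty(reps)
    Ls = np.empty(reps)
    for r in range(reps):
        if mode == "edge_sampling":
            g = _sample_edges(n_nodes, n_edges, rng, allow_collisions)
        elif mode == "watts_strogatz":
            k = max(2, int(round(2 * n_edges / n_nodes / 2) * 2))
            g = nx.watts_strogatz_graph(n_nodes, k, ws_rewire_p,
                                        seed=int(rng.integers(0, 2 ** 31)))
        else:
            raise ValueError("mode must be 'edge_sampling' or 'watts_strogatz'")
        labels = [str(u) for u in range(n_nodes)]
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        for u, v in g.edges():
            adj[u, v] = adj[v, u] = True
        net = BinaryNetwork(labels, adj, {}, alpha=1.0)
        met = graph_metrics(net)
        Cs[r] = met.C
        Ls[r] = met.L
    qc = float(np.mean(Cs <= observed_C)) if observed_C is not None else None
    ql = None
    if observed_L is not None:
        finite = Ls[np.isfinite(Ls)]
        ql = float(np.mean(finite <= observed_L)) if len(finite) else None
    return NullDistribution(reps, seed, mode, Cs, Ls, qc, ql)


# ---------------------------------------------------------------------------
# rich club
# ---------------------------------------------------------------------------

def rich_club_coefficient(n_edges_gt_k: int, n_nodes_gt_k: int) -> float:
    """Rich-club density among nodes of degree > k: 2E / (N (N - 1)).

    Undefined (NaN) for fewer than two qualifying nodes."""
    if n_nodes_gt_k < 2:
        return float("nan")
    return 2.0 * n_edges_gt_k / (n_nodes_gt_k * (n_nodes_gt_k - 1))


@dataclass
class RichClubProfile:
    """Per-degree-threshold rich-club quantities.

    ``table`` columns: k, N_gt_k, E_gt_k, phi_k, phi_unc_k, rho_unc_k.
    ``phi_unc_k`` is the asymptotic uncorrelated reference k^2 / (<k> N)
    with <k> = 2E/N over the whole graph, and rho_unc_k = phi_k / phi_unc_k
    (values above 1 suggest rich-club organization)."""

    table: pd.DataFrame
    k_max: int
    mean_degree: float     # <k> = 2E/N

    def at_counts(self, n_edges_gt_k: int, n_nodes_gt_k: int) -> pd.DataFrame:
        """Rows of the profile matching a given (E_gt_k, N_gt_k) pair."""
        t = self.table
        return t[(t["E_gt_k"] == n_edges_gt_k) & (t["N_gt_k"] == n_nodes_gt_k)]


def rich_club(net: BinaryNetwork) -> RichClubProfile:
    """Rich-club profile over all k in [0, k_max - 1].

    For each k the graph is restricted to nodes of degree > k; phi_k is the
    edge density of that induced subgraph (NaN when fewer than two nodes
    qualify)."""
    g = net.graph
    deg = dict(g.degree())
    k_max = max(deg.values()) if deg else 0
    n = net.n_nodes
    mean_deg = 2 * net.n_edges / n if n else float("nan")
    rows = []
    for k in range(k_max):
        members = [u for u, d in deg.items() if d > k]
        sub = g.subgraph(members)
        n_gt, e_gt = sub.number_of_nodes(), sub.number_of_edges()
        phi = rich_club_coefficient(e_gt, n_gt)
        phi_unc = (k ** 2 / (mean_deg * n)) if (k > 0 and mean_deg > 0) else float("nan")
        rho = phi / phi_unc if (phi_unc and not np.isnan(phi_unc) and phi_unc > 0
                                and not np.isnan(phi)) else float("nan")
        rows.append({"k": k, "N_gt_k": n_gt, "E_gt_k": e_gt,
                     "phi_k": phi, "phi_unc_k": phi_unc, "rho_unc_k": rho})
    table = pd.DataFrame(rows, columns=["k", "N_gt_k", "E_gt_k",
                                        "phi_k", "phi_unc_k", "rho_unc_k"])
    return RichClubProfile(table, k_max, mean_deg)


# ---------------------------------------------------------------------------
# hubs and threshold sweeps
# ---------------------------------------------------------------------------

def hub_nodes(metrics: GraphMetrics, n_sd: float = 1.0) -> pd.DataFrame:
    """Nodes whose degree exceeds mean + n_sd * SD, sorted descending.

    Returns the full degree table with a boolean ``hub`` column; degenerate
    (zero-variance) degree distributions produce no hubs."""
    if metrics.n_nodes < 2:
        raise ValueError("need at least two nodes")
    deg = metrics.degrees
    mu, sd = float(deg.mean()), float(deg.std(ddof=0))
    threshold = mu + n_sd * sd
    table = deg.sort_values(ascending=False).to_frame()
    table["hub"] = (table["degree"] > threshold) if sd > 0 else False
    return table


def sparsity_sweep(edge_table: pd.DataFrame,
                   alpha_grid: list[float],
                   subset: str = "all") -> pd.DataFrame:
    """Network metrics as a function of the p-value threshold.

    One row per alpha: edge count, sparsity, C, L and both efficiencies.
    Edge sets are nested across thresholds by construction."""
    if not alpha_grid:
        raise ValueError("alpha grid must be nonempty")
    for a in alpha_grid:
        if not 0 < a <= 1:
            raise ValueError("each alpha must be in (0, 1]")
    rows = []
    for a in sorted(alpha_grid):
        net = build_network(edge_table, alpha=a, subset=subset)
        met = graph_metrics(net)
        rows.append({"alpha": a, "n_edges": met.n_edges,
                     "sparsity": met.sparsity, "C": met.C, "L": met.L,
                     "local_efficiency": met.local_efficiency,
                     "global_efficiency": met.global_efficiency})
    return pd.DataFrame(rows)
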