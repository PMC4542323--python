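"""Hierarchical clustering of the genetic correlation matrix.

Measures are clustered on the Euclidean distance between their rg-row
profiles (the self-correlation entry included), with agglomerative linkage;
the dendrogram leaf order supplies the row/column permutation for heatmap
rendering.  A bilateral-homologue summary reports the genetic correlation of
each left/right pair of the same region and measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from twingraph.synthetic_twins import parse_label

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("complete", "average", "single")


@dataclass
class ClusterResult:
    """Agglomerative clustering of measure profiles.

    ``linkage_tree`` is the standard (n-1) x 4 linkage matrix (children,
    merge height, cluster size); ``leaf_order`` the dendrogram leaf
    permutation of the input labels."""

    labels: list[str]
    linkage_tree: np.ndarray
    leaf_order: list[str]
    distance_metric: str
    linkage_method: str

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage_tree,
                            columns=["child_a", "child_b", "height", "size"])


def cluster_matrix(rg_matrix: pd.DataFrame,
                   linkage_method: str = "complete") -> ClusterResult:
    """Cluster the rg matrix rows and emit the dendrogram leaf order.

    Missing entries are imputed to 0 (count logged) before computing
    pairwise Euclidean distances between row profiles.  Ties in merge
    heights follow the nearest-neighbor-chain order of the linkage
    algorithm, which is deterministic for a given input ordering.
    """
    if linkage_method not in LINKAGE_METHODS:
        raise ValueError(f"linkage_method must be one of {LINKAGE_METHODS}")
    if rg_matrix.shape[0] != rg_matrix.shape[1]:
        raise ValueError("rg matrix must be square")
    if list(rg_matrix.index) != list(rg_matrix.columns):
        raise ValueError("rg matrix index and columns must match")
    vals = rg_matrix.to_numpy(dtype=float)
    if not np.allclose(np.nan_to_num(vals), np.nan_to_num(vals.T), atol=1e-10):
        raise ValueError("rg matrix must be symmetric")
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.warning("imputing %d missing rg entries to 0 for clustering",
                       n_missing)
        vals = np.nan_to_num(vals)
    labels = list(rg_matrix.index)
    dist = pdist(vals, metric="euclidean")
    Z = hierarchy.linkage(dist, method=linkage_method)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(labels, Z, order, "euclidean", linkage_method)


def bilateral_homologue_check(rg_matrix: pd.DataFrame) -> dict:
    """Genetic correlations of left/right homologue pairs vs all other pairs.

    Labels must follow the panel scheme and every measure must have its
    opposite-hemisphere homologue present.  Returns the per-pair table, the
    fraction of homologue rg values that are positive, and the same
    fraction among non-homologue pairs for comparison.
    """
    labels = list(rg_matrix.index)
    parsed = {}
    unmatched = []
    for lab in labels:
        try:
            parsed[lab] = parse_label(lab)
        except ValueError:
            unmatched.append(lab)
    if unmatched:
        raise ValueError(f"labels without hemisphere tags: {unmatched}")
    pairs = []
    for lab, (hemi, region, measure) in parsed.items():
        if hemi != "L":
            continue
        partner = f"R-{region}-{measure}"
        if partner not in parsed:
            unmatched.append(lab)
            continue
        pairs.append((lab, partner))
    missing_partner = [l for l, (h, r, m) in parsed.items()
                       if h == "R" and f"L-{r}-{m}" not in parsed]
    if unmatched or missing_partner:
        raise ValueError(
            f"labels without a homologue: {sorted(set(unmatched + missing_partner))}")

    rows = [{"left": l, "right": r, "rg": float(rg_matrix.loc[l, r])}
            for l, r in pairs]
    table = pd.DataFrame(rows)
    homologue_set = {tuple(sorted(p)) for p in pairs}
    off_vals = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if tuple(sorted((a, b))) not in homologue_set:
                off_vals.append(rg_matrix.loc[a, b])
    off_vals = np.asarray(off_vals, dtype=float)
    off_vals = off_vals[~np.isnan(off_vals)]
    hom_vals = table["rg"].to_numpy()
    hom_vals = hom_vals[~np.isnan(hom_vals)]
    return {
        "pairs": table,
        "fraction_positive_homologue":
            float(np.mean(hom_vals > 0)) if len(hom_vals) else float("nan"),
        "fraction_positive_other":
            float(np.mean(off_vals > 0)) if len(off_vals) else float("nan"),
    }
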