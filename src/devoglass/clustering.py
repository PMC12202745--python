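"""Pupal-trajectory clustering and cross-species cluster pairing.

Genes are clustered on their pupal-stage expression vectors with
average-linkage hierarchical agglomeration under the Spearman correlation
distance (1 - rho), the tree cut to a fixed k.  The two species are
clustered independently; clusters are then matched one-to-one by the
number of shared one-to-one orthologs (optimal assignment), sorted by
descending shared count and renamed to common labels so that "cluster i"
means the same trajectory family in both species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

__all__ = [
    "ClusterSolution",
    "ClusterPairing",
    "cluster_genes",
    "shared_count_matrix",
    "pair_clusters",
    "cluster_overlap_matrix",
]


@dataclass
class ClusterSolution:
    """A flat clustering of one species' genes with median trajectories."""

    species: str
    labels: pd.Series            # gene id -> cluster id in 1..k
    k: int
    median_trajectories: pd.DataFrame  # clusters x all stages

    def members(self, cluster_id: int) -> pd.Index:
        return self.labels.index[self.labels == cluster_id]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(range(1, self.k + 1), fill_value=0)


@dataclass
class ClusterPairing:
    """One-to-one matching of cluster ids across the two species."""

    pairs: pd.DataFrame  # cluster_a, cluster_b, shared, overlap, new_id
    renaming_a: dict[int, int]
    renaming_b: dict[int, int]


def cluster_genes(stage_expr: pd.DataFrame, pupal_stages: list[str],
                  k: int = 8, species: str = "", linkage_method: str = "average"
                  ) -> ClusterSolution:
    """Cut an average-linkage Spearman-distance tree into exactly k clusters.

    ``stage_expr`` is genes x all ordered stages; only ``pupal_stages``
    enter the distance, but median trajectories are reported over all
    stages.  Genes with zero variance over the pupal stages must be
    removed beforehand (rank correlation is undefined for them).
    """
    if len(pupal_stages) < 3:
        raise ValueError("need at least 3 pupal stages")
    missing = [s for s in pupal_stages if s not in stage_expr.columns]
    if missing:
        raise KeyError(f"pupal stages absent from matrix: {missing}")
    if k > stage_expr.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({stage_expr.shape[0]})")
    x = stage_expr[pupal_stages].to_numpy(dtype=float)
    if np.any(x.std(axis=1) == 0):
        raise ValueError("zero-variance gene(s) over pupal stages; filter first")
    ranks = np.apply_along_axis(rankdata, 1, x)
    # pdist 'correlation' on the ranks is exactly 1 - Spearman rho
    dist = pdist(ranks, metric="correlation")
    tree = linkage(dist, method=linkage_method)
    labels = fcluster(tree, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise RuntimeError(f"tree cut produced {len(np.unique(labels))} clusters, not {k}")
    labels = pd.Series(labels, index=stage_expr.index, name="cluster")
    medians = stage_expr.groupby(labels).median()
    medians.index.name = "cluster"
    return ClusterSolution(species, labels, k, medians)


def shared_count_matrix(sol_a: ClusterSolution, sol_b: ClusterSolution,
                        orthologs: pd.DataFrame) -> np.ndarray:
    """k x k matrix of ortholog pairs shared between cluster i (A) and j (B)."""
    la = sol_a.labels.reindex(orthologs["gene_a"]).to_numpy()
    lb = sol_b.labels.reindex(orthologs["gene_b"]).to_numpy()
    keep = ~(pd.isna(la) | pd.isna(lb))
    la, lb = la[keep].astype(int), lb[keep].astype(int)
    shared = np.zeros((sol_a.k, sol_b.k), dtype=np.int64)
    np.add.at(shared, (la - 1, lb - 1), 1)
    return shared


def pair_clusters(sol_a: ClusterSolution, sol_b: ClusterSolution,
                  orthologs: pd.DataFrame) -> ClusterPairing:
    """Match clusters across species, maximising total shared orthologs.

    The optimal assignment over the shared-count matrix gives the
    bijection; pairs are then sorted by descending shared count (ties by
    the smaller original species-A id) and renamed 1..k.
    """
    if sol_a.k != sol_b.k:
        raise ValueError(f"cluster counts differ: {sol_a.k} vs {sol_b.k}")
    shared = shared_count_matrix(sol_a, sol_b, orthologs)
    rows, cols = linear_sum_assignment(shared, maximize=True)
    sizes_a, sizes_b = sol_a.sizes(), sol_b.sizes()
    records = []
    for i, j in zip(rows, cols):
        s = int(shared[i, j])
        denom = min(sizes_a[i + 1], sizes_b[j + 1])
        records.append((i + 1, j + 1, s, s / denom if denom else 0.0))
    records.sort(key=lambda r: (-r[2], r[0]))
    pairs = pd.DataFrame(records, columns=["cluster_a", "cluster_b", "shared", "overlap"])
    pairs["new_id"] = np.arange(1, len(pairs) + 1)
    return ClusterPairing(
        pairs,
        renaming_a=dict(zip(pairs["cluster_a"], pairs["new_id"])),
        renaming_b=dict(zip(pairs["cluster_b"], pairs["new_id"])),
    )


def cluster_overlap_matrix(sol_a: ClusterSolution, sol_b: ClusterSolution,
                           orthologs: pd.DataFrame,
                           denominator: str = "min") -> pd.DataFrame:
    """Fraction of shared orthologs per cluster pair.

    ``denominator`` is "min" (shared / min cluster size, the default) or
    "jaccard" (shared / union size).  Empty clusters give fraction 0.
    """
    shared = shared_count_matrix(sol_a, sol_b, orthologs)
    sizes_a = sol_a.sizes().to_numpy()
    sizes_b = sol_b.sizes().to_numpy()
    if denominator == "min":
        denom = np.minimum(sizes_a[:, None], sizes_b[None, :])
    elif denominator == "jaccard":
        denom = sizes_a[:, None] + sizes_b[None, :] - shared
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom > 0, shared / np.maximum(denom, 1), 0.0)
    return pd.DataFrame(frac, index=pd.RangeIndex(1, sol_a.k + 1, name="cluster_a"),
                        columns=pd.RangeIndex(1, sol_b.k + 1, name="cluster_b"))
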