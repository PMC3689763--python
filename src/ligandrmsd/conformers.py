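"""Clustering the bound conformers of a drug across crystal structures.

A flexible drug shows up in the PDB in several distinct shapes.  To count
them, all bound copies of a drug are compared pairwise by their optimal
superposition RMSD — minimized over the enumerated symmetry mappings, so an
arbitrary labeling of equivalent atoms never inflates a distance — and the
resulting distance matrix is clustered by average-linkage agglomeration.
Cutting the dendrogram at 1.4 Å (inclusive) yields the conformer clusters;
the cut stays well below the 2.5 Å still accepted as "same pose" in
docking, so members of a cluster really are the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .molgraph import best_superposition, build_graph, enumerate_mappings, name_correspondence
from .pdb_io import LigandInstance

__all__ = [
    "ConformerClustering",
    "conformer_distance",
    "cluster_conformers",
    "conformer_stats",
    "to_newick",
]

DEFAULT_CUT = 1.4  # Å


def conformer_distance(a: LigandInstance, b: LigandInstance) -> float:
    """Symmetry-corrected optimal superposition RMSD of two conformers.

    The minimum over all enumerated candidate atom mappings of the Kabsch
    RMSD; taking the lowest value over alternative correspondences guards
    against a suboptimal atom assignment.
    """
    gA, gB = build_graph(a), build_graph(b)
    nm = name_correspondence(a, b)
    candidates, source = enumerate_mappings(gA, gB, name_map=None)
    # the name correspondence is one more candidate, not a shortcut:
    # symmetry mates may score lower
    if nm is not None and len(nm) >= 3:
        extra = tuple(sorted(nm))
        if extra not in candidates:
            candidates = list(candidates) + [extra]
    _mapping, sup = best_superposition(a.coords, b.coords, candidates, source)
    return sup.rmsd


@dataclass
class ConformerClustering:
    drug: str
    instances: list[LigandInstance]
    distance_matrix: np.ndarray  # symmetric, zero diagonal, Å
    cut_height: float
    labels: np.ndarray  # cluster index per instance, 0-based, canonical order

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def clusters(self) -> list[list[int]]:
        return [
            [i for i, l in enumerate(self.labels) if l == c]
            for c in range(self.n_clusters)
        ]

    @property
    def cluster_sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def stats(self) -> tuple[int, int, float, int]:
        """(cluster count, min members, mean members, max members)."""
        sizes = self.cluster_sizes
        return (len(sizes), min(sizes), float(np.mean(sizes)), max(sizes))

    #: linkage matrix, populated for n >= 2 (scipy format)
    linkage_: np.ndarray | None = None


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Renumber clusters by smallest member index (deterministic)."""
    order: dict[int, int] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order)
    return np.array([order[lab] for lab in raw], dtype=int)


def cluster_conformers(
    instances: Sequence[LigandInstance],
    cut: float = DEFAULT_CUT,
    distance_matrix: np.ndarray | None = None,
) -> ConformerClustering:
    """Average-linkage clustering of conformers, cut at ``cut`` Å (inclusive).

    Merges at height <= ``cut`` are retained, so two conformers at exactly
    the cut height end up in one cluster.  A precomputed distance matrix may
    be supplied; otherwise :func:`conformer_distance` fills it.
    """
    instances = list(instances)
    if not instances:
        raise ValueError("no conformer instances")
    drug = instances[0].chem_comp_id
    n = len(instances)
    if distance_matrix is None:
        distance_matrix = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = conformer_distance(instances[i], instances[j])
                distance_matrix[i, j] = distance_matrix[j, i] = d
    else:
        distance_matrix = np.asarray(distance_matrix, dtype=float)
        if distance_matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match instances")
        if not np.allclose(distance_matrix, distance_matrix.T):
            raise ValueError("distance matrix must be symmetric")
    if n == 1:
        return ConformerClustering(drug, instances, distance_matrix, cut, np.zeros(1, int))
    Z = linkage(squareform(distance_matrix, checks=False), method="average")
    raw = fcluster(Z, t=cut, criterion="distance")
    clustering = ConformerClustering(
        drug, instances, distance_matrix, cut, _canonical_labels(raw)
    )
    clustering.linkage_ = Z
    return clustering


def conformer_stats(
    clusterings: Mapping[str, ConformerClustering] | Sequence[ConformerClustering],
) -> pd.DataFrame:
    """Per-drug flexibility table: cluster count and membership summary."""
    if isinstance(clusterings, Mapping):
        items = list(clusterings.values())
    else:
        items = list(clusterings)
    rows = []
    for cl in items:
        count, mn, mean, mx = cl.stats
        rows.append(
            {
                "drug": cl.drug,
                "n_instances": len(cl.instances),
                "n_conformer_clusters": count,
                "min_members": mn,
                "mean_members": round(mean, 2),
                "max_members": mx,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "drug",
            "n_instances",
            "n_conformer_clusters",
            "min_members",
            "mean_members",
            "max_members",
        ],
    )
    return df.sort_values(
        ["n_conformer_clusters", "drug"], ascending=[False, True]
    ).reset_index(drop=True)


def to_newick(clustering: ConformerClustering) -> str:
    """Dendrogram in Newick format (leaf names = instance indices)."""
    if clustering.linkage_ is None:
        return "(0);" if len(clustering.instances) == 1 else ";"
    tree = to_tree(clustering.linkage_)

    def rec(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{node.id}:{length:.4f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.4f}"

    return rec(tree, tree.dist) + ";"
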