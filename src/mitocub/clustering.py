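"""RSCU-based species relationship dendrogram.

Species-level RSCU profiles are standardized to Z-scores per codon, pairwise
Euclidean distances are taken, and a UPGMA tree (size-weighted average
linkage, merge height = distance / 2, deterministic lexicographic
tie-breaking) is built and written as Newick via scikit-bio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)


def species_rscu_features(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Z-score a species x codon RSCU matrix column-wise.

    Sample standard deviation (ddof=1) by default, matching common
    statistics-package behaviour. Zero-variance columns are dropped with a
    warning (they carry no between-species signal).
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 species to standardize")
    sd = matrix.std(axis=0, ddof=ddof)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d zero-variance codon columns", int((~keep).sum()))
    m = matrix.loc[:, keep]
    return (m - m.mean(axis=0)) / m.std(axis=0, ddof=ddof)


def euclidean_distances(features: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix over feature rows."""
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    sq = (x ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=features.index, columns=features.index)


@dataclass
class ClusterTree:
    """Rooted ultrametric UPGMA tree plus its merge heights."""

    tree: TreeNode
    heights: dict[frozenset, float]  # merged leaf-set -> merge height

    def cophenetic(self) -> pd.DataFrame:
        """Leaf-pair cophenetic distances (= full merge distance, 2 x height)."""
        tips = sorted(t.name for t in self.tree.tips())
        d = pd.DataFrame(0.0, index=tips, columns=tips)
        tip_index = {t.name: t for t in self.tree.tips()}
        for a, b in combinations(tips, 2):
            lca = self.tree.lowest_common_ancestor([tip_index[a], tip_index[b]])
            h = _node_height(lca)
            d.loc[a, b] = d.loc[b, a] = 2.0 * h
        return d


def _node_height(node: TreeNode) -> float:
    """Distance from a node down to any tip (tree is ultrametric)."""
    h = 0.0
    while node.children:
        child = node.children[0]
        h += child.length or 0.0
        node = child
    return h


def upgma(d: pd.DataFrame) -> ClusterTree:
    """Unweighted pair-group (arithmetic-mean) agglomeration.

    Closest pair merges at height d/2; the distance from a new cluster to
    any other is the size-weighted mean of its members' distances. Ties are
    broken by the lexicographically smallest leaf label in each cluster, so
    the output is independent of input ordering.
    """
    labels = list(d.index)
    if len(labels) < 2:
        raise ValueError("UPGMA needs >= 2 leaves")
    arr = d.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    # cluster state: key -> (members, size, height, node)
    clusters: dict[str, tuple[frozenset, int, float, TreeNode]] = {
        lab: (frozenset([lab]), 1, 0.0, TreeNode(name=lab)) for lab in labels
    }
    dist: dict[frozenset, float] = {
        frozenset((a, b)): float(d.loc[a, b]) for a, b in combinations(labels, 2)
    }
    heights: dict[frozenset, float] = {}

    while len(clusters) > 1:
        # rep label of a cluster is its smallest leaf; tie-break on rep pair
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(min(c) for c in _split(kv[0], clusters)))),
        )
        pair, dmin = best
        ka, kb = sorted(_split(pair, clusters), key=min)
        a_members, a_size, a_h, a_node = clusters.pop(min(ka))
        b_members, b_size, b_h, b_node = clusters.pop(min(kb))
        height = dmin / 2.0
        a_node.length = height - a_h
        b_node.length = height - b_h
        new_node = TreeNode(children=[a_node, b_node])
        members = a_members | b_members
        heights[members] = height
        new_key = min(members)

        for other_key, (o_members, o_size, _, _) in clusters.items():
            da = dist.pop(frozenset((min(a_members), other_key)))
            db = dist.pop(frozenset((min(b_members), other_key)))
            dist[frozenset((new_key, other_key))] = (
                (a_size * da + b_size * db) / (a_size + b_size)
            )
        dist.pop(pair, None)
        clusters[new_key] = (members, a_size + b_size, height, new_node)

    (_, _, _, root) = next(iter(clusters.values()))
    return ClusterTree(tree=root, heights=heights)


def _split(pair_key: frozenset, clusters: dict) -> tuple[frozenset, frozenset]:
    a, b = sorted(pair_key)
    return clusters[a][0], clusters[b][0]


def write_newick(tree: ClusterTree | TreeNode, path) -> None:
    """Write standard Newick with branch lengths (labels auto-quoted)."""
    node = tree.tree if isinstance(tree, ClusterTree) else tree
    node.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def bipartition(tree: ClusterTree) -> tuple[frozenset, frozenset]:
    """Leaf sets of the two children of the root (the deepest split)."""
    root = tree.tree
    sides = [frozenset(t.name for t in child.tips()) if child.children
             else frozenset([child.name]) for child in root.children]
    if len(sides) != 2:
        raise ValueError("root is not binary")
    return sides[0], sides[1]
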