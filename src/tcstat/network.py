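"""Anatomical network summaries of significant clusters.

After inference, the anatomical structure is filtered to connections
whose endpoints both survived correction; the filtered high-resolution
matrix can be downsampled to an atlas (binary region adjacency), and
the connectivity between major spatially contiguous clusters can be
summarized as a weighted graph -- edge weight = product of the two
clusters' maximum absolute effect sizes -- and pruned to a maximum
spanning tree (Kruskal, deterministic tie-breaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse.csgraph import connected_components

from .sparse import SparseSymmetricMatrix

__all__ = [
    "AtlasLabeling",
    "ClusterGraph",
    "filter_connectome_to_significant",
    "downsample_to_atlas",
    "major_spatial_clusters",
    "cluster_graph",
    "maximum_spanning_tree",
]


@dataclass
class AtlasLabeling:
    """Per-node region assignment (1..R) with optional region names."""

    region_id: np.ndarray
    region_name: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.region_id = np.asarray(self.region_id, dtype=np.int64)
        if self.region_id.min() < 1:
            raise ValueError("region ids must be >= 1 (every node labeled)")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.region_name is not None and len(self.region_name) != self.n_regions:
            raise ValueError("one name per region required")

    @property
    def n_regions(self):
        return int(self.region_id.max())


def filter_connectome_to_significant(C_dist, significant):
    """Keep only edges whose endpoints both survived correction."""
    significant = np.asarray(significant, dtype=bool)
    if significant.size != C_dist.n_nodes:
        raise ValueError("mask / connectome dimension mismatch")
    row, col, w = C_dist.edges()
    keep = significant[row] & significant[col]
    return SparseSymmetricMatrix(C_dist.n_nodes, row[keep], col[keep], w[keep],
                                 binary=C_dist.binary)


def downsample_to_atlas(filtered, atlas):
    """Binary region-by-region adjacency: 1 iff any high-resolution edge
    joins the two regions (intra-region edges are suppressed)."""
    if atlas.region_id.size != filtered.n_nodes:
        raise ValueError("atlas does not cover all nodes")
    row, col, _ = filtered.edges()
    ra = atlas.region_id[row] - 1
    rb = atlas.region_id[col] - 1
    keep = ra != rb
    return SparseSymmetricMatrix(atlas.n_regions, ra[keep], rb[keep], binary=True)


def major_spatial_clusters(significant, S, min_fraction=0.01):
    """Spatially contiguous significant components of relative size >= 1%.

    Components of the significant node set under the spatial structure
    ``S`` alone; components smaller than ``min_fraction`` of the largest
    are discarded.  Returns a list of node-index arrays, largest first.
    """
    significant = np.asarray(significant, dtype=bool)
    if significant.size != S.n_nodes:
        raise ValueError("mask / spatial structure dimension mismatch")
    idx = np.flatnonzero(significant)
    if idx.size == 0:
        return []
    sub = S.to_csr()[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    comps = [idx[labels == lab] for lab in range(labels.max() + 1)]
    comps.sort(key=lambda c: (-c.size, c.min()))
    cutoff = min_fraction * comps[0].size
    return [c for c in comps if c.size >= cutoff]


@dataclass
class ClusterGraph:
    """Weighted graph over major spatial clusters.

    ``edges`` holds ``(a, b, weight)`` with ``a < b`` cluster indices;
    the weight is the product of the two clusters' maximum |effect|.
    ``tree_edges`` is the maximum-spanning forest subset.
    """

    clusters: List[np.ndarray]
    edges: List[Tuple[int, int, float]]
    tree_edges: List[Tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_clusters(self):
        return len(self.clusters)


def cluster_graph(filtered, clusters, effect):
    """Build the cluster graph from the filtered anatomical matrix.

    Clusters must be disjoint node sets; an edge joins clusters a, b iff
    at least one filtered anatomical edge joins them, weighted by
    ``max_{i in a}|d(i)| * max_{j in b}|d(j)|``.
    """
    effect = np.asarray(effect, dtype=float)
    member = -np.ones(filtered.n_nodes, dtype=np.int64)
    for k, nodes in enumerate(clusters):
        if np.any(member[nodes] >= 0):
            raise ValueError("clusters overlap")
        member[nodes] = k
    peak = np.array([np.abs(effect[nodes]).max() for nodes in clusters]) \
        if clusters else np.empty(0)
    row, col, _ = filtered.edges()
    ca, cb = member[row], member[col]
    keep = (ca >= 0) & (cb >= 0) & (ca != cb)
    pairs = {(min(a, b), max(a, b)) for a, b in zip(ca[keep], cb[keep])}
    edges = [(a, b, float(peak[a] * peak[b])) for a, b in sorted(pairs)]
    return ClusterGraph(clusters=list(clusters), edges=edges)


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(graph):
    """Maximum-weight spanning forest via Kruskal.

    Edges are scanned by (weight desc, then (a, b) asc) so ties resolve
    deterministically; per connected component the result is a maximum
    spanning tree.  The forest is stored on ``graph.tree_edges`` and
    also returned.
    """
    if graph.n_clusters < 1:
        raise ValueError("graph must have at least one node")
    uf = _UnionFind(graph.n_clusters)
    tree = []
    for a, b, w in sorted(graph.edges, key=lambda e: (-e[2], e[0], e[1])):
        if uf.union(a, b):
            tree.append((a, b, w))
    graph.tree_edges = tree
    return tree
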