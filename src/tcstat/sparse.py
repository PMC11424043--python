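"""Sparse symmetric matrices over brain nodes.

Every graph-like object in the pipeline -- an individual streamline-count
connectome ``A_s``, the group consensus ``C``, its distance-normalized form
``C_n``, the binarized anatomical structure ``C_dist``, the spatial
adjacency ``S`` and the clustering topology ``T`` -- is an undirected
matrix with a zero diagonal.  Only the strict upper triangle is stored;
queries are symmetric.  Binary matrices carry all weights exactly 1.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["SparseSymmetricMatrix"]


class SparseSymmetricMatrix:
    """Undirected weighted or binary matrix stored as its upper triangle.

    Parameters
    ----------
    n_nodes : int
        Number of nodes (matrix dimension).
    row, col : array-like of int
        Edge endpoints; entries are canonicalized to ``row < col``.
        Diagonal entries are rejected.
    weight : array-like of float, optional
        Edge weights.  Ignored (forced to 1) when ``binary=True``.
    binary : bool
        Whether the matrix is a binary adjacency structure.
    """

    __slots__ = ("n_nodes", "row", "col", "weight", "binary", "_csr")

    def __init__(self, n_nodes, row=None, col=None, weight=None, *, binary=False):
        n_nodes = int(n_nodes)
        if n_nodes <= 0:
            raise ValueError("n_nodes must be positive")
        row = np.asarray([] if row is None else row, dtype=np.int64).ravel()
        col = np.asarray([] if col is None else col, dtype=np.int64).ravel()
        if row.shape != col.shape:
            raise ValueError("row and col must have the same length")
        if row.size and (row.min() < 0 or col.min() < 0 or
                         row.max() >= n_nodes or col.max() >= n_nodes):
            raise ValueError("edge index out of range")
        if np.any(row == col):
            raise ValueError("self-edges (diagonal entries) are not allowed")
        if binary or weight is None:
            weight = np.ones(row.size, dtype=np.float64)
        else:
            weight = np.asarray(weight, dtype=np.float64).ravel()
            if weight.shape != row.shape:
                raise ValueError("weight length mismatch")
        # canonical orientation i < j, then lexicographic order
        swap = row > col
        row2 = np.where(swap, col, row)
        col2 = np.where(swap, row, col)
        order = np.lexsort((col2, row2))
        row2, col2, weight = row2[order], col2[order], weight[order]
        if row2.size:
            key = row2 * n_nodes + col2
            dup = np.flatnonzero(np.diff(key) == 0)
            if dup.size:
                if not np.allclose(weight[dup], weight[dup + 1]):
                    raise ValueError("conflicting duplicate entries for the same edge")
                keep = np.ones(row2.size, dtype=bool)
                keep[dup + 1] = False
                row2, col2, weight = row2[keep], col2[keep], weight[keep]
        if binary:
            weight = np.ones(row2.size, dtype=np.float64)
        self.n_nodes = n_nodes
        self.row = row2
        self.col = col2
        self.weight = weight
        self.binary = bool(binary)
        self._csr = None

    # ------------------------------------------------------------------
    # constructors
    @classmethod
    def from_scipy(cls, mat, *, binary=False, atol=0.0):
        """Build from any scipy sparse / dense square matrix.

        The matrix must be symmetric (within ``atol``); the diagonal is
        ignored only if it is exactly zero.
        """
        A = sp.coo_matrix(mat)
        if A.shape[0] != A.shape[1]:
            raise ValueError("matrix must be square")
        if (abs(A - A.T) > atol).nnz:
            raise ValueError("matrix is not symmetric")
        A = sp.triu(A, k=1).tocoo()
        return cls(A.shape[0], A.row, A.col, A.data, binary=binary)

    @classmethod
    def from_dense(cls, arr, *, binary=False, atol=0.0):
        arr = np.asarray(arr, dtype=float)
        if np.any(np.diag(arr) != 0):
            raise ValueError("nonzero diagonal")
        return cls.from_scipy(sp.coo_matrix(arr), binary=binary, atol=atol)

    @classmethod
    def empty(cls, n_nodes, *, binary=True):
        return cls(n_nodes, binary=binary)

    # ------------------------------------------------------------------
    # basic properties
    @property
    def n_edges(self):
        return int(self.row.size)

    @property
    def density(self):
        """Fraction of possible undirected node pairs that carry an entry."""
        pairs = self.n_nodes * (self.n_nodes - 1) / 2
        return self.n_edges / pairs if pairs else 0.0

    def edges(self):
        """(row, col, weight) arrays of the stored upper triangle."""
        return self.row, self.col, self.weight

    def edge_set(self):
        return set(zip(self.row.tolist(), self.col.tolist()))

    def degrees(self):
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.row, 1)
        np.add.at(deg, self.col, 1)
        return deg

    # ------------------------------------------------------------------
    # conversions
    def to_csr(self):
        """Full symmetric CSR view (cached)."""
        if self._csr is None:
            r = np.concatenate([self.row, self.col])
            c = np.concatenate([self.col, self.row])
            w = np.concatenate([self.weight, self.weight])
            self._csr = sp.csr_matrix((w, (r, c)), shape=(self.n_nodes, self.n_nodes))
        return self._csr

    def to_coo_upper(self):
        return sp.coo_matrix((self.weight, (self.row, self.col)),
                             shape=(self.n_nodes, self.n_nodes))

    def to_dense(self):
        return self.to_csr().toarray()

    def copy(self):
        out = SparseSymmetricMatrix(self.n_nodes, self.row.copy(), self.col.copy(),
                                    self.weight.copy(), binary=self.binary)
        return out

    # ------------------------------------------------------------------
    # algebra
    def binarized(self):
        """Binary matrix with the same sparsity pattern (nonzero entries)."""
        keep = self.weight != 0
        return SparseSymmetricMatrix(self.n_nodes, self.row[keep], self.col[keep],
                                     binary=True)

    def union(self, other):
        """Elementwise OR of two binary matrices of equal size."""
        if not isinstance(other, SparseSymmetricMatrix):
            raise TypeError("expected SparseSymmetricMatrix")
        if self.n_nodes != other.n_nodes:
            raise ValueError("dimension mismatch: %d vs %d" % (self.n_nodes, other.n_nodes))
        if not (self.binary and other.binary):
            raise ValueError("union is defined for binary matrices")
        row = np.concatenate([self.row, other.row])
        col = np.concatenate([self.col, other.col])
        return SparseSymmetricMatrix(self.n_nodes, row, col, binary=True)

    def __eq__(self, other):
        if not isinstance(other, SparseSymmetricMatrix):
            return NotImplemented
        return (self.n_nodes == other.n_nodes
                and self.binary == other.binary
                and np.array_equal(self.row, other.row)
                and np.array_equal(self.col, other.col)
                and np.array_equal(self.weight, other.weight))

    def __hash__(self):  # mutable-free container; identity hash is fine
        return id(self)

    def __repr__(self):
        kind = "binary" if self.binary else "weighted"
        return (f"<SparseSymmetricMatrix {kind} n_nodes={self.n_nodes} "
                f"n_edges={self.n_edges} density={self.density:.4g}>")
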