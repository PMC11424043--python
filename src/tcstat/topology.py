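"""Construction of the binary clustering topology ``T``.

The topology combines two sources of node-to-node structure:

* a *spatial* adjacency ``S`` (triangle-mesh neighbors on a surface,
  26-neighborhood in a voxel grid, or a lattice for phantoms), and
* an *anatomical* structure ``C_dist`` distilled from individual
  streamline-count connectomes.

The anatomical branch proceeds as: consensus (fraction of subjects in
whom each connection is observed), distance-dependent normalization
(standardizing each connection's consistency against the mean/sd of
equally distant connections, fitted per connection class with cubic
splines over distance bins), kernel smoothing ``F C_n F^T`` with a
row-stochastic Gaussian kernel, thresholding to the average density of
an individual connectome, and binarization.  ``T`` is the elementwise OR
of ``C_dist`` and ``S``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .geometry import NodeGeometry
from .sparse import SparseSymmetricMatrix

__all__ = [
    "DistanceModel",
    "SmoothingKernel",
    "build_surface_adjacency",
    "build_volume_adjacency",
    "volume_node_coordinates",
    "compute_consensus",
    "average_individual_density",
    "fit_distance_model",
    "normalize_consistency",
    "build_smoothing_kernel",
    "smooth_connectome",
    "threshold_to_density",
    "combine_topology",
    "build_topology",
]

SIGMA_FLOOR = 1e-6


# ----------------------------------------------------------------------
# spatial structure
def build_surface_adjacency(triangles, n_vertices):
    """Binary adjacency of a triangle mesh: vertices sharing a triangle edge.

    Parameters
    ----------
    triangles : iterable of (i, j, k) vertex index triples
    n_vertices : int
    """
    tris = np.asarray(list(triangles), dtype=np.int64).reshape(-1, 3)
    if tris.size == 0:
        warnings.warn("empty triangle list: edgeless spatial structure")
        return SparseSymmetricMatrix.empty(n_vertices)
    if tris.min() < 0 or tris.max() >= n_vertices:
        raise ValueError("triangle vertex index out of range")
    if np.any((tris[:, 0] == tris[:, 1]) | (tris[:, 1] == tris[:, 2])
              | (tris[:, 0] == tris[:, 2])):
        raise ValueError("degenerate triangle (repeated vertex)")
    row = np.concatenate([tris[:, 0], tris[:, 0], tris[:, 1]])
    col = np.concatenate([tris[:, 1], tris[:, 2], tris[:, 2]])
    return SparseSymmetricMatrix(n_vertices, row, col, binary=True)


_NEIGHBOR_OFFSETS = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)


def volume_node_coordinates(mask):
    """Voxel (x, y, z) integer coordinates of in-mask voxels in C-order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    return np.argwhere(mask)  # argwhere scans in C order


def build_volume_adjacency(mask):
    """26-neighborhood adjacency over in-mask voxels of a 3D grid.

    Nodes are the in-mask voxels enumerated in C order (last axis
    fastest); two voxels are adjacent iff their Chebyshev distance is 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("empty mask")
    flat_index = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    flat_index[tuple(coords.T)] = np.arange(coords.shape[0])
    rows, cols = [], []
    shape = np.array(mask.shape)
    for off in _NEIGHBOR_OFFSETS:
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        src = np.flatnonzero(ok)
        tgt = flat_index[tuple(nb[ok].T)]
        hit = tgt >= 0
        rows.append(src[hit])
        cols.append(tgt[hit])
    row = np.concatenate(rows)
    col = np.concatenate(cols)
    keep = row < col  # each neighbor pair appears in both directions
    return SparseSymmetricMatrix(coords.shape[0], row[keep], col[keep], binary=True)


# ----------------------------------------------------------------------
# consensus
def _check_connectomes(connectomes):
    connectomes = list(connectomes)
    if not connectomes:
        raise ValueError("empty connectome list")
    n = connectomes[0].n_nodes
    for c in connectomes:
        if c.n_nodes != n:
            raise ValueError("connectomes disagree on n_nodes")
    return connectomes, n


def compute_consensus(connectomes):
    """Connection consistency: fraction of subjects with a nonzero edge.

    ``C(i, j) = (1/S) * #{s : A_s(i, j) > 0}``; the sparsity pattern is
    the union of the individual patterns and weights lie in (0, 1].
    """
    connectomes, n = _check_connectomes(connectomes)
    acc = None
    for c in connectomes:
        b = c.binarized().to_coo_upper().tocsr()
        acc = b if acc is None else acc + b
    acc = (acc / len(connectomes)).tocoo()
    return SparseSymmetricMatrix(n, acc.row, acc.col, acc.data)


def average_individual_density(connectomes):
    """Mean nonzero fraction of the off-diagonal upper triangle."""
    connectomes, _ = _check_connectomes(connectomes)
    return float(np.mean([c.binarized().density for c in connectomes]))


# ----------------------------------------------------------------------
# distance-dependent normalization
@dataclass
class DistanceModel:
    """Cubic-spline fits of consistency mean and sd versus distance.

    Fitted from equal-count distance bins of one connection class.
    ``mu``/``sigma`` evaluate the fits with inputs clamped to the fitted
    distance range; ``sigma`` is floored at ``sigma_floor``.
    """

    connection_class: str
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    mean_fit: CubicSpline
    sd_fit: CubicSpline
    sigma_floor: float = SIGMA_FLOOR
    residual_mu: float = 0.0
    residual_sigma: float = 0.0

    def _clamp(self, d):
        return np.clip(np.asarray(d, dtype=float),
                       self.bin_centers[0], self.bin_centers[-1])

    def mu(self, d):
        return self.mean_fit(self._clamp(d))

    def sigma(self, d):
        return np.maximum(self.sd_fit(self._clamp(d)), self.sigma_floor)


def fit_distance_model(C, geometry, n_bins=100, connection_class=None,
                       sigma_floor=SIGMA_FLOOR):
    """Fit the distance trend of consistency for one connection class.

    The class's observed edges are split into ``n_bins`` equal-count
    distance bins; per-bin mean and sd of the consistency index are
    computed, and interpolating cubic splines are fitted through
    (bin center, mean) and (bin center, sd).

    Parameters
    ----------
    C : SparseSymmetricMatrix (weighted consensus)
    geometry : NodeGeometry
    n_bins : int, >= 4
    connection_class : str or None
        One of the three classes; ``None`` uses all edges (single-class
        data such as 2D phantoms).
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    row, col, w = C.edges()
    if connection_class is not None:
        cls = geometry.connection_class(row, col)
        keep = cls == connection_class
        row, col, w = row[keep], col[keep], w[keep]
    label = connection_class or "all"
    if row.size < n_bins:
        raise ValueError(
            f"too few edges ({row.size}) in connection class '{label}' "
            f"for {n_bins} bins")
    d = geometry.distance(row, col)
    order = np.argsort(d, kind="stable")
    groups = np.array_split(order, n_bins)
    centers, means, sds = [], [], []
    for g in groups:
        if g.size == 0:
            continue
        centers.append(d[g].mean())
        means.append(w[g].mean())
        sds.append(w[g].std())
    centers = np.asarray(centers)
    means = np.asarray(means)
    sds = np.asarray(sds)
    # merge bins whose centers coincide (ties in distance)
    uniq, inv = np.unique(centers, return_inverse=True)
    if uniq.size < centers.size:
        means = np.bincount(inv, weights=means) / np.bincount(inv)
        sds = np.bincount(inv, weights=sds) / np.bincount(inv)
        centers = uniq
    if uniq.size < 2:
        raise ValueError("degenerate distance distribution: all edges equidistant")
    if np.any(sds <= sigma_floor):
        warnings.warn(f"zero-variance distance bin in class '{label}'; "
                      "sd floored")
    mean_fit = CubicSpline(centers, means, bc_type="not-a-knot")
    sd_fit = CubicSpline(centers, np.maximum(sds, sigma_floor), bc_type="not-a-knot")
    edges = np.concatenate([[d.min()], (centers[:-1] + centers[1:]) / 2, [d.max()]])
    return DistanceModel(
        connection_class=label,
        bin_edges=edges,
        bin_centers=centers,
        bin_mean=means,
        bin_sd=sds,
        mean_fit=mean_fit,
        sd_fit=sd_fit,
        sigma_floor=sigma_floor,
        residual_mu=float(np.sqrt(np.mean((mean_fit(centers) - means) ** 2))),
        residual_sigma=float(np.sqrt(np.mean((sd_fit(centers) - np.maximum(sds, sigma_floor)) ** 2))),
    )


def fit_distance_models(C, geometry, n_bins=100, sigma_floor=SIGMA_FLOOR):
    """One DistanceModel per connection class present in ``C``."""
    row, col, _ = C.edges()
    present = np.unique(geometry.connection_class(row, col))
    return {c: fit_distance_model(C, geometry, n_bins, c, sigma_floor)
            for c in present}


def normalize_consistency(C, geometry, models):
    """Distance-normalized consistency ``C_n``.

    ``C_n(i,j) = (C(i,j) - f_mu(ED(i,j))) / f_sigma(ED(i,j))`` with the
    model of the edge's connection class; the sparsity pattern of ``C``
    is preserved (explicit zeros are kept).

    Parameters
    ----------
    models : DistanceModel or dict class -> DistanceModel
    """
    row, col, w = C.edges()
    d = geometry.distance(row, col)
    out = np.empty_like(w)
    if isinstance(models, DistanceModel):
        out = (w - models.mu(d)) / models.sigma(d)
    else:
        cls = geometry.connection_class(row, col)
        done = np.zeros(w.size, dtype=bool)
        for name, model in models.items():
            m = cls == name
            out[m] = (w[m] - model.mu(d[m])) / model.sigma(d[m])
            done |= m
        if not done.all():
            missing = sorted(set(np.unique(cls[~done])))
            raise ValueError(f"no DistanceModel for connection class(es) {missing}")
    return SparseSymmetricMatrix(C.n_nodes, row, col, out)


# ----------------------------------------------------------------------
# connectome spatial smoothing
@dataclass
class SmoothingKernel:
    """Row-stochastic truncated Gaussian smoothing kernel.

    ``matrix`` is sparse node x node with non-negative entries and unit
    row sums; weights follow ``exp(-ED^2 / (2 sigma^2))`` with
    ``sigma = fwhm / (2 sqrt(2 ln 2))``, truncated beyond
    ``truncation_radius``.
    """

    matrix: sp.csr_matrix
    fwhm: float
    sigma: float
    truncation_radius: float


def build_smoothing_kernel(geometry, fwhm=6.0, truncation_radius=None,
                           weight_floor=1e-6):
    """Gaussian kernel over Euclidean node distances.

    ``truncation_radius`` defaults to the distance at which the Gaussian
    weight falls to ``weight_floor`` of its peak.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    if truncation_radius is None:
        truncation_radius = sigma * math.sqrt(-2.0 * math.log(weight_floor))
    tree = cKDTree(geometry.coordinates)
    pairs = tree.query_pairs(truncation_radius, output_type="ndarray")
    n = geometry.n_nodes
    if pairs.size:
        d = geometry.distance(pairs[:, 0], pairs[:, 1])
        w = np.exp(-d ** 2 / (2.0 * sigma ** 2))
        row = np.concatenate([pairs[:, 0], pairs[:, 1], np.arange(n)])
        col = np.concatenate([pairs[:, 1], pairs[:, 0], np.arange(n)])
        val = np.concatenate([w, w, np.ones(n)])
    else:
        row = col = np.arange(n)
        val = np.ones(n)
    F = sp.csr_matrix((val, (row, col)), shape=(n, n))
    rowsum = np.asarray(F.sum(axis=1)).ravel()
    F = sp.diags(1.0 / rowsum) @ F
    return SmoothingKernel(matrix=F.tocsr(), fwhm=float(fwhm), sigma=sigma,
                           truncation_radius=float(truncation_radius))


def smooth_connectome(C_n, kernel):
    """Kernel-smoothed matrix ``F C_n F^T``, re-symmetrized.

    Accepts a SmoothingKernel or a raw sparse row-stochastic matrix.
    """
    F = kernel.matrix if isinstance(kernel, SmoothingKernel) else sp.csr_matrix(kernel)
    if F.shape != (C_n.n_nodes, C_n.n_nodes):
        raise ValueError("kernel / matrix dimension mismatch")
    W = F @ C_n.to_csr() @ F.T
    W = (W + W.T) * 0.5  # absorb floating-point asymmetry
    W = sp.triu(W.tocoo(), k=1).tocoo()
    return SparseSymmetricMatrix(C_n.n_nodes, W.row, W.col, W.data)


# ----------------------------------------------------------------------
# thresholding and union
def threshold_to_density(W, target_density):
    """Binarize by keeping the ``k`` largest-weight edges.

    ``k = round(target_density * n(n-1)/2)``.  Ties at the cut are broken
    deterministically by (weight desc, then lexicographic (i, j)).
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    if target_density > W.density + 1e-12:
        raise ValueError(
            f"target density {target_density:.6g} exceeds current density "
            f"{W.density:.6g}")
    pairs = W.n_nodes * (W.n_nodes - 1) / 2
    k = int(round(target_density * pairs))
    row, col, w = W.edges()
    order = np.lexsort((col, row, -w))  # weight desc, then (i, j) asc
    keep = order[:k]
    return SparseSymmetricMatrix(W.n_nodes, row[keep], col[keep], binary=True)


def combine_topology(C_dist, S):
    """Topology ``T``: nodes are linked if spatially OR anatomically linked."""
    return C_dist.union(S)


# ----------------------------------------------------------------------
# pipeline
def build_topology(connectomes, geometry, spatial, *, fwhm=6.0,
                   target_density=None, n_bins=100, by_class=True,
                   sigma_floor=SIGMA_FLOOR):
    """Full anatomical-topology pipeline from individual connectomes.

    Returns a dict with all intermediates: ``consensus``, ``models``,
    ``normalized``, ``kernel``, ``smoothed``, ``c_dist``, ``topology``.
    ``target_density`` defaults to the average individual density.
    """
    connectomes, n = _check_connectomes(connectomes)
    if geometry.n_nodes != n or spatial.n_nodes != n:
        raise ValueError("geometry/spatial dimension mismatch with connectomes")
    C = compute_consensus(connectomes)
    if target_density is None:
        target_density = average_individual_density(connectomes)
    if by_class:
        models = fit_distance_models(C, geometry, n_bins, sigma_floor)
    else:
        models = fit_distance_model(C, geometry, n_bins, None, sigma_floor)
    C_n = normalize_consistency(C, geometry, models)
    kernel = build_smoothing_kernel(geometry, fwhm=fwhm)
    smoothed = smooth_connectome(C_n, kernel)
    C_dist = threshold_to_density(smoothed, target_density)
    T = combine_topology(C_dist, spatial)
    return {
        "consensus": C,
        "models": models,
        "normalized": C_n,
        "kernel": kernel,
        "smoothed": smoothed,
        "c_dist": C_dist,
        "topology": T,
        "target_density": target_density,
    }
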