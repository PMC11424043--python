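import itertools

import numpy as np
import pytest

from tcstat import (NodeGeometry, SparseSymmetricMatrix,
                    average_individual_density, build_smoothing_kernel,
                    build_surface_adjacency, build_volume_adjacency,
                    combine_topology, compute_consensus, fit_distance_model,
                    normalize_consistency, smooth_connectome,
                    threshold_to_density)

ICOSAHEDRON_FACES = [
    (0, 1, 2), (0, 2, 3), (0, 3, 4), (0, 4, 5), (0, 5, 1),
    (1, 6, 2), (2, 6, 7), (2, 7, 3), (3, 7, 8), (3, 8, 4),
    (4, 8, 9), (4, 9, 5), (5, 9, 10), (5, 10, 1), (1, 10, 6),
    (6, 11, 7), (7, 11, 8), (8, 11, 9), (9, 11, 10), (10, 11, 6),
]


# ----------------------------------------------------------------------
# spatial adjacency
def test_surface_adjacency_single_and_shared_triangles():
    m = build_surface_adjacency([(0, 1, 2)], 3)
    assert m.edge_set() == {(0, 1), (0, 2), (1, 2)}
    assert list(m.degrees()) == [2, 2, 2]
    m2 = build_surface_adjacency([(0, 1, 2), (1, 2, 3)], 4)
    assert m2.n_edges == 5  # shared edge (1,2) counted once


def test_surface_adjacency_icosahedron_degrees():
    # brute-force oracle: vertex neighbors from pairwise triangle membership
    neighbors = {v: set() for v in range(12)}
    for tri in ICOSAHEDRON_FACES:
        for a, b in itertools.combinations(tri, 2):
            neighbors[a].add(b)
            neighbors[b].add(a)
    m = build_surface_adjacency(ICOSAHEDRON_FACES, 12)
    assert np.array_equal(m.degrees(), [len(neighbors[v]) for v in range(12)])
    assert np.all(m.degrees() == 5)


def test_surface_adjacency_errors():
    with pytest.raises(ValueError, match="out of range"):
        build_surface_adjacency([(0, 1, 5)], 3)
    with pytest.raises(ValueError, match="degenerate"):
        build_surface_adjacency([(0, 1, 1)], 3)
    with pytest.warns(UserWarning, match="empty"):
        m = build_surface_adjacency([], 3)
    assert m.n_edges == 0


def test_volume_adjacency_26_neighborhood():
    mask = np.ones((3, 3, 3), dtype=bool)
    m = build_volume_adjacency(mask)
    deg = m.degrees()
    center = 13  # C-order index of voxel (1,1,1)
    assert deg[center] == 26
    # corner oracle: enumerate offsets staying inside the grid
    corner_deg = sum(
        1 for off in itertools.product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0) and all(0 <= c < 3 for c in off))
    assert corner_deg == 7
    assert deg[0] == corner_deg


def test_volume_adjacency_chebyshev_two_no_edge():
    mask = np.zeros((5, 1, 1), dtype=bool)
    mask[0, 0, 0] = mask[2, 0, 0] = True
    assert build_volume_adjacency(mask).n_edges == 0
    with pytest.raises(ValueError, match="empty"):
        build_volume_adjacency(np.zeros((2, 2, 2), dtype=bool))


# ----------------------------------------------------------------------
# consensus
def _random_connectome(rng, n, p=0.3):
    dense = np.triu(rng.random((n, n)) < p, k=1) * rng.integers(1, 9, (n, n))
    return SparseSymmetricMatrix.from_dense(dense + dense.T)


def test_consensus_fractions():
    a = SparseSymmetricMatrix(3, [0], [1], [5.0])
    b = SparseSymmetricMatrix(3, [0, 1], [1, 2], [1.0, 2.0])
    c = SparseSymmetricMatrix(3, [0], [1], [9.0])
    C = compute_consensus([a, b, c])
    dense = C.to_dense()
    assert dense[0, 1] == pytest.approx(1.0)      # present in all subjects
    assert dense[1, 2] == pytest.approx(1 / 3)    # present in 1 of 3
    assert dense[0, 2] == 0                        # absent everywhere
    with pytest.raises(ValueError, match="empty"):
        compute_consensus([])
    with pytest.raises(ValueError, match="n_nodes"):
        compute_consensus([a, SparseSymmetricMatrix(4)])


def test_consensus_invariant_to_subject_order():
    rng = np.random.default_rng(7)
    mats = [_random_connectome(rng, 12) for _ in range(5)]
    C1 = compute_consensus(mats)
    C2 = compute_consensus(mats[::-1])
    assert C1 == C2


def test_average_density_brute_force():
    rng = np.random.default_rng(3)
    mats = [_random_connectome(rng, 10) for _ in range(3)]
    expected = np.mean([np.count_nonzero(np.triu(m.to_dense(), 1)) / 45
                        for m in mats])
    assert average_individual_density(mats) == pytest.approx(expected)
    assert average_individual_density([mats[0]]) == pytest.approx(mats[0].density)


# ----------------------------------------------------------------------
# distance model
def _grid_geometry(n, rng, ndim=2, scale=50.0):
    return NodeGeometry(coordinates=rng.random((n, ndim)) * scale,
                        group_label=np.repeat("left", n))


def _full_graph_consensus(geom, weight_fn, rng, noise=0.0):
    n = geom.n_nodes
    row, col = np.triu_indices(n, k=1)
    d = geom.distance(row, col)
    w = weight_fn(d) + (rng.normal(0, noise, d.size) if noise else 0.0)
    return SparseSymmetricMatrix(n, row, col, w), d


def test_distance_model_recovers_generating_mean():
    rng = np.random.default_rng(0)
    geom = _grid_geometry(80, rng)
    C, _ = _full_graph_consensus(geom, lambda d: np.exp(-d / 10), rng, noise=0.02)
    model = fit_distance_model(C, geom, n_bins=20)
    centers = model.bin_centers
    assert np.allclose(model.mu(centers), np.exp(-centers / 10), atol=0.05)
    # spline interpolates the empirical bin means exactly at centers
    assert np.allclose(model.mean_fit(centers), model.bin_mean, atol=1e-10)


def test_distance_model_constant_consistency():
    rng = np.random.default_rng(1)
    geom = _grid_geometry(40, rng)
    C, _ = _full_graph_consensus(geom, lambda d: np.full_like(d, 0.5), rng)
    with pytest.warns(UserWarning, match="zero-variance"):
        model = fit_distance_model(C, geom, n_bins=8)
    assert np.allclose(model.mu(model.bin_centers), 0.5)
    assert np.all(model.sigma(model.bin_centers) == model.sigma_floor)
    # constant consistency normalizes to (numerically) zero everywhere
    Cn = normalize_consistency(C, geom, model)
    assert np.allclose(Cn.weight, 0.0, atol=1e-6)


def test_distance_model_errors():
    rng = np.random.default_rng(2)
    geom = _grid_geometry(6, rng)
    C, _ = _full_graph_consensus(geom, lambda d: d, rng)
    with pytest.raises(ValueError, match="n_bins"):
        fit_distance_model(C, geom, n_bins=3)
    with pytest.raises(ValueError, match="too few edges"):
        fit_distance_model(C, geom, n_bins=100)


def test_normalization_standardizes_binned_moments():
    rng = np.random.default_rng(4)
    geom = _grid_geometry(300, rng)
    mu = lambda d: 0.6 * np.exp(-d / 25)
    sd = lambda d: 0.15 + 0.001 * d
    n = geom.n_nodes
    row, col = np.triu_indices(n, k=1)
    d = geom.distance(row, col)
    w = mu(d) + sd(d) * rng.normal(size=d.size)
    C = SparseSymmetricMatrix(n, row, col, w)
    model = fit_distance_model(C, geom, n_bins=40)
    Cn = normalize_consistency(C, geom, model)
    # per fitting bin: mean ~ 0, sd ~ 1
    order = np.argsort(d, kind="stable")
    for g in np.array_split(order, 40):
        assert abs(Cn.weight[g].mean()) < 0.1
        assert abs(Cn.weight[g].std() - 1.0) < 0.15
    # an edge exactly on the fitted mean curve maps to 0
    i, j = int(row[0]), int(col[0])
    dij = geom.distance(i, j)
    C2 = SparseSymmetricMatrix(n, row, col,
                               np.where(np.arange(w.size) == 0, model.mu(dij), w))
    Cn2 = normalize_consistency(C2, geom, model)
    assert Cn2.weight[0] == pytest.approx(0.0, abs=1e-12)


def test_normalization_requires_class_models():
    rng = np.random.default_rng(5)
    coords = rng.random((30, 2)) * 50
    labels = np.array(["left"] * 15 + ["right"] * 15)
    geom = NodeGeometry(coords, labels)
    row, col = np.triu_indices(30, k=1)
    C = SparseSymmetricMatrix(30, row, col, rng.random(row.size))
    model = fit_distance_model(C, geom, n_bins=5,
                               connection_class="intrahemispheric")
    with pytest.raises(ValueError, match="interhemispheric"):
        normalize_consistency(C, geom, {"intrahemispheric": model})


# ----------------------------------------------------------------------
# smoothing kernel
def test_kernel_rows_stochastic_and_gaussian_ratio():
    rng = np.random.default_rng(6)
    geom = _grid_geometry(50, rng, scale=30.0)
    k = build_smoothing_kernel(geom, fwhm=6.0)
    rowsums = np.asarray(k.matrix.sum(axis=1)).ravel()
    assert np.allclose(rowsums, 1.0, atol=1e-9)
    assert k.matrix.min() >= 0
    # two isolated nodes: off/diagonal weight ratio is the closed form
    d = 3.0
    g2 = NodeGeometry(np.array([[0.0, 0.0], [d, 0.0]]), np.array(["left"] * 2))
    k2 = build_smoothing_kernel(g2, fwhm=6.0)
    F = k2.matrix.toarray()
    assert F[0, 1] / F[0, 0] == pytest.approx(np.exp(-d ** 2 / (2 * k2.sigma ** 2)))


def test_kernel_identity_limit_and_errors():
    geom = NodeGeometry(np.array([[0.0, 0], [10, 0], [0, 10]]),
                        np.array(["left"] * 3))
    k = build_smoothing_kernel(geom, fwhm=1e-3)
    assert np.allclose(k.matrix.toarray(), np.eye(3))
    with pytest.raises(ValueError, match="fwhm"):
        build_smoothing_kernel(geom, fwhm=0)


def test_smoothing_matches_dense_triple_product():
    rng = np.random.default_rng(8)
    for n in (5, 20, 50):
        geom = _grid_geometry(n, rng, scale=20.0)
        C = _random_connectome(rng, n, p=0.4)
        k = build_smoothing_kernel(geom, fwhm=6.0)
        out = smooth_connectome(C, k)
        F = k.matrix.toarray()
        expected = F @ C.to_dense() @ F.T
        expected = (expected + expected.T) / 2
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(out.to_dense(), expected, atol=1e-10)


def test_smoothing_identity_kernel():
    C = SparseSymmetricMatrix(4, [0, 2], [1, 3], [1.0, 2.0])
    import scipy.sparse as sp
    out = smooth_connectome(C, sp.eye(4).tocsr())
    assert np.allclose(out.to_dense(), C.to_dense())
    with pytest.raises(ValueError, match="dimension"):
        smooth_connectome(C, sp.eye(5).tocsr())


# ----------------------------------------------------------------------
# density thresholding and union
def test_threshold_keeps_largest_edges():
    w = {(0, 1): 5.0, (0, 2): 4.0, (1, 2): 3.0, (2, 3): 2.0, (3, 4): 1.0}
    rows, cols, ws = zip(*[(i, j, v) for (i, j), v in w.items()])
    W = SparseSymmetricMatrix(5, rows, cols, ws)
    target = 2 / 10
    out = threshold_to_density(W, target)
    assert out.binary
    assert out.edge_set() == {(0, 1), (0, 2)}  # sort-based oracle: two heaviest


def test_threshold_identity_at_current_density():
    rng = np.random.default_rng(9)
    W = _random_connectome(rng, 10)
    out = threshold_to_density(W, W.density)
    assert out.edge_set() == W.edge_set()
    with pytest.raises(ValueError, match="exceeds"):
        threshold_to_density(W, min(1.0, W.density * 2))


def test_threshold_tie_breaking_deterministic():
    W = SparseSymmetricMatrix(4, [0, 0, 1, 2], [1, 2, 3, 3],
                              [1.0, 1.0, 1.0, 2.0])
    out = threshold_to_density(W, 2 / 6)
    # (2,3) heaviest; tie among the rest broken lexicographically -> (0,1)
    assert out.edge_set() == {(0, 1), (2, 3)}
    assert threshold_to_density(W, 2 / 6).edge_set() == out.edge_set()


def test_threshold_density_within_one_edge():
    rng = np.random.default_rng(10)
    W = _random_connectome(rng, 30, p=0.5)
    for target in (0.1, 0.2, W.density):
        out = threshold_to_density(W, target)
        pairs = 30 * 29 / 2
        assert abs(out.n_edges - target * pairs) <= 1


def test_combine_topology_properties():
    rng = np.random.default_rng(11)
    mats = [_random_connectome(rng, 6, p=0.4).binarized() for _ in range(3)]
    a, b, c = mats
    # brute-force set union oracle
    assert combine_topology(a, b).edge_set() == a.edge_set() | b.edge_set()
    assert combine_topology(a, b) == combine_topology(b, a)
    assert (combine_topology(combine_topology(a, b), c)
            == combine_topology(a, combine_topology(b, c)))
    assert combine_topology(a, a) == a
    empty = SparseSymmetricMatrix(6, binary=True)
    assert combine_topology(empty, a) == a
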