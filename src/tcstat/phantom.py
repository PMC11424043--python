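"""Synthetic 2D ribbon phantom for end-to-end testing of TCS.

An 80 x 80 grid (an idealized axial slice) is masked by a circular
ribbon of "gray matter" pixels, partitioned into 11 atlas regions: five
per hemisphere plus one brain-stem sector at the bottom.  A binary
ground-truth activation (peak 1, background 0) spans three regions of
distinct spatial extents.  Long-range "white matter" fibers of three
classes are laid on top of the 4-neighborhood lattice:

* association -- short-range links between angularly adjacent regions
  of the same hemisphere,
* projection  -- links from the brain stem to every cortical region,
* commissural -- homotopic links between mirror-symmetric left/right
  pixels.

The smallest active region is the mirror image of a patch of the
largest one and is homotopically fiber-connected to it, so it can only
join a large significant cluster through the anatomical topology --
the configuration that distinguishes TCS from purely spatial
cluster-extent inference.

Noisy observations add Gaussian white noise (sd 2 by default) to the
signal and smooth the sum with a truncated Gaussian filter
(sigma 0.5), renormalized inside the ribbon at its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import NodeGeometry
from .inference import SubjectSample
from .sparse import SparseSymmetricMatrix

__all__ = [
    "RibbonSpec",
    "PhantomDataset",
    "make_ribbon_phantom",
    "make_phantom_topology",
    "simulate_noisy_map",
    "simulate_subject_sample",
]

ASSOCIATION = "association"
COMMISSURAL = "commissural"
PROJECTION = "projection"


@dataclass(frozen=True)
class RibbonSpec:
    """Geometry and wiring parameters of the ribbon phantom."""

    grid_shape: Tuple[int, int] = (80, 80)
    inner_frac: float = 0.55        # inner ribbon radius / half-grid
    outer_frac: float = 0.95        # outer ribbon radius / half-grid
    stem_half_angle_deg: float = 15.0
    n_regions_per_hemi: int = 5
    # wiring
    n_homotopic_per_pair: int = 10
    n_projection_per_region: int = 3
    n_association_per_pair: int = 3
    # activation layout
    large_region: int = 4           # right-hemisphere sector, fully active
    medium_region: int = 8          # left-hemisphere sector, partially active
    medium_fraction: float = 0.4
    small_patch_shape: Tuple[int, int] = (2, 3)  # mirrored into region 9


@dataclass
class PhantomDataset:
    """Ribbon geometry, atlas labels, ground truth and fiber wiring."""

    spec: RibbonSpec
    ribbon_mask: np.ndarray           # (H, W) bool
    region_label_grid: np.ndarray     # (H, W) int, 0 outside ribbon
    node_pixels: np.ndarray           # (n_nodes, 2) int (row, col), C order
    region_label: np.ndarray          # per-node int in 1..11
    ground_truth: np.ndarray          # per-node float in [0, 1]
    active_regions: List[np.ndarray]  # 3 node-index sets (large, medium, small)
    fiber_edges: List[Tuple[int, int, str]]
    geometry: NodeGeometry
    seed: int

    @property
    def n_nodes(self):
        return self.node_pixels.shape[0]

    @property
    def n_regions(self):
        return int(self.region_label.max())

    def grid_from_nodes(self, values, fill=0.0):
        """Scatter a per-node vector back onto the full grid."""
        g = np.full(self.ribbon_mask.shape, fill, dtype=float)
        g[self.ribbon_mask] = values
        return g


def _region_of_angle(phi_deg, spec):
    """Atlas label from the angle (degrees) measured from straight down.

    1 = brain stem (|phi| <= stem half-angle); right hemisphere sectors
    2..6 for increasing positive phi; left sectors 7..11 mirror them.
    """
    half = spec.stem_half_angle_deg
    width = (180.0 - half) / spec.n_regions_per_hemi
    a = np.abs(phi_deg)
    sector = np.minimum(((a - half) / width).astype(int), spec.n_regions_per_hemi - 1)
    label = np.where(a <= half, 1,
                     np.where(phi_deg > 0, 2 + sector, 7 + sector))
    return label


def make_ribbon_phantom(spec=None, seed=0):
    """Build the deterministic ribbon phantom for a given spec and seed.

    Geometry, atlas and ground truth depend only on ``spec``; the seed
    controls the sampling of homotopic and projection fiber endpoints.
    """
    spec = spec or RibbonSpec()
    H, W = spec.grid_shape
    if H < 20 or W < 20:
        raise ValueError("grid must be at least 20x20")
    if not 0 < spec.inner_frac < spec.outer_frac <= 1:
        raise ValueError("need 0 < inner_frac < outer_frac <= 1")
    R = min(H, W) / 2.0
    r_in, r_out = spec.inner_frac * R, spec.outer_frac * R
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    rr, cc = np.mgrid[0:H, 0:W]
    dy = rr - cy   # positive downward
    dx = cc - cx   # positive rightward
    dist = np.sqrt(dy ** 2 + dx ** 2)
    ribbon = (dist >= r_in) & (dist <= r_out)
    phi = np.degrees(np.arctan2(dx, dy))  # 0 = straight down, + to the right
    labels = np.where(ribbon, _region_of_angle(phi, spec), 0)

    node_pixels = np.argwhere(ribbon)  # C order
    n_nodes = node_pixels.shape[0]
    pixel_to_node = -np.ones((H, W), dtype=np.int64)
    pixel_to_node[tuple(node_pixels.T)] = np.arange(n_nodes)
    region = labels[tuple(node_pixels.T)]
    phi_node = phi[tuple(node_pixels.T)]

    group = np.where(region == 1, "subcortical",
                     np.where(region <= 1 + spec.n_regions_per_hemi, "right", "left"))
    geometry = NodeGeometry(coordinates=node_pixels.astype(float), group_label=group)

    def mirror_node(nodes):
        px = node_pixels[nodes].copy()
        px[:, 1] = W - 1 - px[:, 1]
        return pixel_to_node[tuple(px.T)]

    # --- activation layout -------------------------------------------
    large = np.flatnonzero(region == spec.large_region)
    med_all = np.flatnonzero(region == spec.medium_region)
    order = np.argsort(np.abs(phi_node[med_all]), kind="stable")
    medium = med_all[order[: max(1, int(round(spec.medium_fraction * med_all.size)))]]
    # small region: mirror of a compact patch of the large sector
    centroid = node_pixels[large].mean(axis=0)
    seed_node = large[np.argmin(np.linalg.norm(node_pixels[large] - centroid, axis=1))]
    r0, c0 = node_pixels[seed_node]
    ph, pw = spec.small_patch_shape
    in_patch = ((node_pixels[large][:, 0] >= r0) & (node_pixels[large][:, 0] < r0 + ph)
                & (node_pixels[large][:, 1] >= c0) & (node_pixels[large][:, 1] < c0 + pw))
    patch = large[in_patch]
    small = mirror_node(patch)
    small = small[small >= 0]
    ground_truth = np.zeros(n_nodes)
    for nodes in (large, medium, small):
        ground_truth[nodes] = 1.0

    # --- fibers -------------------------------------------------------
    rng = np.random.default_rng(seed)
    fibers = set()

    def add(i, j, klass):
        a, b = (int(i), int(j)) if i < j else (int(j), int(i))
        if a != b:
            fibers.add((a, b, klass))

    n_hemi = spec.n_regions_per_hemi
    # commissural: homotopic mirror pairs, sampled per right-hemisphere region
    for reg in range(2, 2 + n_hemi):
        members = np.flatnonzero(region == reg)
        take = min(spec.n_homotopic_per_pair, members.size)
        chosen = rng.choice(members, size=take, replace=False)
        mirrored = mirror_node(chosen)
        for i, j in zip(chosen, mirrored):
            if j >= 0:
                add(i, j, COMMISSURAL)
    # guarantee the small/large homotopic linkage
    for i, j in zip(patch, mirror_node(patch)):
        if j >= 0:
            add(i, j, COMMISSURAL)
    # projection: brain stem to each cortical region
    stem = np.flatnonzero(region == 1)
    for reg in range(2, 2 + 2 * n_hemi):
        members = np.flatnonzero(region == reg)
        take = min(spec.n_projection_per_region, members.size, stem.size)
        src = rng.choice(stem, size=take, replace=False)
        tgt = rng.choice(members, size=take, replace=False)
        for i, j in zip(src, tgt):
            add(i, j, PROJECTION)
    # association: adjacent same-hemisphere sectors, endpoints nearest the
    # shared boundary angle (deterministic)
    half = spec.stem_half_angle_deg
    width = (180.0 - half) / n_hemi
    for base, sgn in ((2, 1.0), (7, -1.0)):
        for k in range(n_hemi - 1):
            ra, rb = base + k, base + k + 1
            boundary = sgn * (half + (k + 1) * width)
            for reg_pair in ((ra, rb),):
                a_members = np.flatnonzero(region == reg_pair[0])
                b_members = np.flatnonzero(region == reg_pair[1])
                na = np.argsort(np.abs(phi_node[a_members] - boundary),
                                kind="stable")[: spec.n_association_per_pair]
                nb = np.argsort(np.abs(phi_node[b_members] - boundary),
                                kind="stable")[: spec.n_association_per_pair]
                for i, j in zip(a_members[na], b_members[nb]):
                    add(i, j, ASSOCIATION)

    return PhantomDataset(
        spec=spec, ribbon_mask=ribbon, region_label_grid=labels,
        node_pixels=node_pixels, region_label=region,
        ground_truth=ground_truth,
        active_regions=[large, medium, small],
        fiber_edges=sorted(fibers), geometry=geometry, seed=int(seed),
    )


def make_phantom_topology(phantom):
    """Spatial lattice ``S`` and fiber-augmented topology ``T``.

    ``S`` connects each ribbon pixel to its 4-neighborhood; ``T`` is the
    union of ``S`` with the phantom's long-range fibers.
    """
    H, W = phantom.ribbon_mask.shape
    pix = phantom.node_pixels
    idx = -np.ones((H, W), dtype=np.int64)
    idx[tuple(pix.T)] = np.arange(phantom.n_nodes)
    rows, cols = [], []
    for off in ((0, 1), (1, 0)):
        nb = pix + off
        ok = (nb[:, 0] < H) & (nb[:, 1] < W)
        src = np.flatnonzero(ok)
        tgt = idx[tuple(nb[ok].T)]
        hit = tgt >= 0
        rows.append(src[hit])
        cols.append(tgt[hit])
    S = SparseSymmetricMatrix(phantom.n_nodes, np.concatenate(rows),
                              np.concatenate(cols), binary=True)
    if phantom.fiber_edges:
        fr = np.array([e[0] for e in phantom.fiber_edges])
        fc = np.array([e[1] for e in phantom.fiber_edges])
        F = SparseSymmetricMatrix(phantom.n_nodes, fr, fc, binary=True)
        T = S.union(F)
    else:
        T = S.copy()
    return S, T


def _smooth_in_ribbon(grid_values, mask, sigma):
    """Gaussian smoothing restricted to the ribbon, kernel renormalized
    at the ribbon boundary (smooth(x*m)/smooth(m))."""
    if sigma <= 0:
        return grid_values[mask]
    num = gaussian_filter(np.where(mask, grid_values, 0.0), sigma, truncate=4.0)
    den = gaussian_filter(mask.astype(float), sigma, truncate=4.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    return sm[mask]


def simulate_noisy_map(phantom, noise_sd=2.0, smooth_sigma=0.5, seed=None,
                       effect_scale=1.0, rng=None):
    """One noisy observation: smooth(scale * truth + white noise) on the ribbon."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    grid = phantom.grid_from_nodes(effect_scale * phantom.ground_truth)
    if noise_sd > 0:
        noise = np.zeros_like(grid)
        noise[phantom.ribbon_mask] = rng.normal(0.0, noise_sd, phantom.n_nodes)
        grid = grid + noise
    return _smooth_in_ribbon(grid, phantom.ribbon_mask, smooth_sigma)


def simulate_subject_sample(phantom, n_subjects=40, effect_scale=1.0,
                            noise_sd=2.0, smooth_sigma=0.5, seed=None):
    """Multi-subject sample: shared scaled truth plus independent noise.

    ``effect_scale = 0`` yields a pure-null sample for false-positive
    calibration.
    """
    if n_subjects < 2:
        raise ValueError("at least 2 subjects required")
    rng = np.random.default_rng(seed)
    maps = np.stack([
        simulate_noisy_map(phantom, noise_sd, smooth_sigma,
                           effect_scale=effect_scale, rng=rng)
        for _ in range(n_subjects)
    ])
    return SubjectSample(maps)
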