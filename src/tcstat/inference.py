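"""Cluster-extent inference over a clustering topology.

One-sample two-sided group inference: per-node t statistics are
thresholded at a cluster-defining threshold (CDT), suprathreshold nodes
of equal sign are grouped into connected components of the topology
``T``, and each cluster's extent (node count) is tested against the
null distribution of the maximum extent under sign-flip permutations.
With ``T`` equal to the plain spatial adjacency this reduces exactly to
conventional spatial cluster-extent inference; with a topology that also
carries anatomical connections, spatially disjoint but anatomically
linked activations form a single cluster.

The public surface follows the statsmodels convention: build a
:class:`TopologicalClusterModel` from data and a topology, call
``fit()`` and obtain a :class:`TopologicalClusterResults` carrying the
cluster table, the permutation null and corrected p-values.  The
underlying steps (:func:`group_t_statistic`, :func:`threshold_map`,
:func:`label_clusters`, :func:`permutation_null`, :func:`fwer_pvalues`,
:func:`run_inference`) are exported for direct use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

from .sparse import SparseSymmetricMatrix

__all__ = [
    "SubjectSample",
    "StatMap",
    "SuprathresholdMask",
    "InferenceResult",
    "group_t_statistic",
    "threshold_map",
    "label_clusters",
    "permutation_null",
    "fwer_pvalues",
    "run_inference",
    "sign_flip_matrix",
    "TopologicalClusterModel",
    "TopologicalClusterResults",
    "cdt_z_for_p",
]


def cdt_z_for_p(p_two_sided):
    """z value whose two-sided normal tail probability equals ``p``."""
    if not 0 < p_two_sided < 1:
        raise ValueError("p must be in (0, 1)")
    return float(stats.norm.isf(p_two_sided / 2.0))


# ----------------------------------------------------------------------
@dataclass
class SubjectSample:
    """Stack of per-node contrast values for a group of subjects."""

    values: np.ndarray  # (n_subjects, n_nodes)
    subject_ids: Optional[Sequence] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_subjects, n_nodes)")
        if self.values.shape[0] < 2:
            raise ValueError("at least 2 subjects required")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.values.shape[0])]
        elif len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per row required")

    @property
    def n_subjects(self):
        return self.values.shape[0]

    @property
    def n_nodes(self):
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df):
        """Nodes-by-subjects DataFrame (columns = subjects)."""
        return cls(df.to_numpy().T, subject_ids=list(df.columns))


@dataclass
class StatMap:
    """Per-node one-sample statistics.

    ``z`` is the z-equivalent of ``t`` (matched tail probabilities) --
    the scale on which the CDT is expressed by default.  ``d = t / sqrt(n)``
    is Cohen's d.  Zero-variance nodes are marked ``missing`` and carry NaN.
    """

    t: np.ndarray
    z: np.ndarray
    d: np.ndarray
    n: int
    missing: np.ndarray

    @property
    def df(self):
        return self.n - 1


def _t_to_z(t, df):
    """Sign-symmetric, tail-stable map of t values to z-equivalents."""
    t = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        pos = t >= 0
        z = np.empty_like(t)
        z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
        z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
        z[np.isnan(t)] = np.nan
    return z


def group_t_statistic(sample):
    """One-sample t statistic per node; zero-variance nodes marked missing."""
    X = sample.values
    n = sample.n_subjects
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    missing = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[missing] = np.nan
    d = t / np.sqrt(n)
    return StatMap(t=t, z=_t_to_z(t, n - 1), d=d, n=n, missing=missing)


@dataclass
class SuprathresholdMask:
    """Signed suprathreshold indicator per node: -1, 0 or +1."""

    sign: np.ndarray

    @property
    def n_nodes(self):
        return self.sign.size


def _cdt_on_t_scale(cdt, df, scale):
    """Equivalent t threshold for a CDT given on the ``scale`` scale."""
    if scale == "z":
        return float(stats.t.isf(stats.norm.sf(cdt), df))
    if scale == "t":
        return float(cdt)
    raise ValueError("cdt scale must be 'z' or 't'")


def threshold_map(stat, cdt, scale="z"):
    """Signed mask of nodes at or beyond the cluster-defining threshold."""
    if cdt <= 0:
        raise ValueError("cdt must be positive")
    tc = _cdt_on_t_scale(cdt, stat.df, scale)
    t = stat.t
    sign = np.zeros(t.size, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        sign[t >= tc] = 1
        sign[t <= -tc] = -1
    sign[stat.missing] = 0
    return SuprathresholdMask(sign=sign)


# ----------------------------------------------------------------------
def _components_of_sign(idx, T_csr):
    """Connected components of ``T`` restricted to node subset ``idx``."""
    if idx.size == 0:
        return []
    sub = T_csr[idx][:, idx]
    _, labels = connected_components(sub, directed=False)
    comps = []
    for lab in range(labels.max() + 1):
        comps.append(idx[labels == lab])
    return comps


def label_clusters(mask, T):
    """Group same-sign suprathreshold nodes into topology components.

    Returns ``(cluster_id, cluster_sign, extent)``: per-node integer
    labels (0 = background), per-cluster sign and extent.  Cluster ids
    are dense, ordered by decreasing extent, ties by smallest member node.
    """
    if mask.n_nodes != T.n_nodes:
        raise ValueError("mask / topology dimension mismatch")
    T_csr = T.to_csr()
    comps = []
    for s in (1, -1):
        idx = np.flatnonzero(mask.sign == s)
        for nodes in _components_of_sign(idx, T_csr):
            comps.append((s, nodes))
    comps.sort(key=lambda c: (-c[1].size, c[1].min()))
    cluster_id = np.zeros(mask.n_nodes, dtype=np.int64)
    cluster_sign = np.empty(len(comps), dtype=np.int8)
    extent = np.empty(len(comps), dtype=np.int64)
    for k, (s, nodes) in enumerate(comps):
        cluster_id[nodes] = k + 1
        cluster_sign[k] = s
        extent[k] = nodes.size
    return cluster_id, cluster_sign, extent


def _max_extent(pos_idx, neg_idx, T_csr):
    best = 0
    for idx in (pos_idx, neg_idx):
        for nodes in _components_of_sign(idx, T_csr):
            if nodes.size > best:
                best = nodes.size
    return best


# ----------------------------------------------------------------------
def sign_flip_matrix(n_subjects, n_perm, seed=None, exhaustive=False):
    """Matrix of +/-1 subject sign flips, one row per permutation.

    Row 0 is always the identity (all +1).  In exhaustive mode all
    ``2**n_subjects`` patterns are enumerated exactly once (in binary
    counting order, so the identity comes first); otherwise flips are
    drawn from ``numpy.random.default_rng(seed)`` as one
    ``(n_perm - 1, n_subjects)`` block of independent fair signs.
    """
    if exhaustive:
        if n_subjects > 20:
            raise ValueError("exhaustive enumeration limited to 20 subjects")
        k = np.arange(2 ** n_subjects)[:, None]
        bits = (k >> np.arange(n_subjects)[None, :]) & 1
        return 1 - 2 * bits.astype(np.int8)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm - 1, n_subjects)).astype(np.int8) * 2 - 1
    return np.vstack([np.ones((1, n_subjects), dtype=np.int8), flips])


def _permuted_t(values, flips):
    """t statistics of all sign-flipped samples at once.

    Squared values are flip-invariant, so only the flipped means need a
    matmul: ``var = (sum x^2 - n mean^2) / (n - 1)``.
    """
    n = values.shape[0]
    means = (flips.astype(float) @ values) / n
    sumsq = np.einsum("ij,ij->j", values, values)
    var = (sumsq - n * means ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[:, var[0] == 0] = np.nan  # columns zero-variance in any flip are so in all
    return t


def permutation_null(sample, T, cdt, n_perm=1000, seed=None, *,
                     cdt_scale="z", exhaustive=False, flips=None):
    """Null distribution of the maximum cluster extent under sign flips.

    For each permutation every subject's map is multiplied by an
    independent +/-1, the t-map is recomputed, thresholded and labeled,
    and the maximum extent across both signs recorded.  Permutation 0 is
    the identity.
    """
    if flips is None:
        flips = sign_flip_matrix(sample.n_subjects, n_perm, seed, exhaustive)
    tc = _cdt_on_t_scale(cdt, sample.n_subjects - 1, cdt_scale)
    t = _permuted_t(sample.values, flips)
    T_csr = T.to_csr()
    null = np.empty(flips.shape[0], dtype=np.int64)
    with np.errstate(invalid="ignore"):
        pos = t >= tc
        neg = t <= -tc
    for p in range(flips.shape[0]):
        null[p] = _max_extent(np.flatnonzero(pos[p]), np.flatnonzero(neg[p]), T_csr)
    return null


def fwer_pvalues(observed_extents, null_max_extents):
    """FWER-corrected p per cluster: fraction of null maxima >= extent.

    The identity permutation is part of the null, so the smallest
    attainable p is ``1 / n_perm``.
    """
    null = np.asarray(null_max_extents)
    if null.size == 0:
        raise ValueError("empty permutation null")
    obs = np.asarray(observed_extents)
    return (null[None, :] >= obs[:, None]).mean(axis=1)


# ----------------------------------------------------------------------
@dataclass
class InferenceResult:
    """Signed clusters, extents, corrected p-values and provenance."""

    cluster_id: np.ndarray        # per-node, 0 = background
    cluster_sign: np.ndarray      # per-cluster
    extent: np.ndarray            # per-cluster
    p_fwer: np.ndarray            # per-cluster
    significant: np.ndarray       # per-node bool
    null_max_extents: np.ndarray
    stat: StatMap
    seed: Optional[int]
    n_perm: int
    cdt: float
    cdt_scale: str
    alpha: float

    @property
    def n_clusters(self):
        return self.extent.size

    def predicted_sign(self):
        """Per-node {-1, 0, +1}: cluster sign where significant, else 0."""
        out = np.zeros(self.cluster_id.size, dtype=np.int8)
        sig = self.significant
        out[sig] = self.cluster_sign[self.cluster_id[sig] - 1]
        return out

    def cluster_table(self):
        return pd.DataFrame({
            "cluster_id": np.arange(1, self.n_clusters + 1),
            "sign": self.cluster_sign,
            "extent": self.extent,
            "p_fwer": self.p_fwer,
            "significant": self.p_fwer < self.alpha,
        })

    def node_table(self):
        node_p = np.full(self.cluster_id.size, np.nan)
        in_cluster = self.cluster_id > 0
        if self.n_clusters:
            node_p[in_cluster] = self.p_fwer[self.cluster_id[in_cluster] - 1]
        return pd.DataFrame({
            "node_id": np.arange(self.cluster_id.size),
            "t": self.stat.t,
            "d": self.stat.d,
            "cluster_id": self.cluster_id,
            "sign": self.predicted_sign(),
            "p_fwer": node_p,
            "significant": self.significant,
        })


def run_inference(sample, T, cdt=3.3, alpha=0.05, n_perm=1000, seed=None, *,
                  cdt_scale="z", exhaustive=False):
    """Full TCS pipeline: t-map, CDT, topology clustering, sign-flip FWER."""
    if sample.n_nodes != T.n_nodes:
        raise ValueError("sample / topology dimension mismatch")
    stat = group_t_statistic(sample)
    mask = threshold_map(stat, cdt, cdt_scale)
    cluster_id, cluster_sign, extent = label_clusters(mask, T)
    null = permutation_null(sample, T, cdt, n_perm, seed,
                            cdt_scale=cdt_scale, exhaustive=exhaustive)
    p = fwer_pvalues(extent, null) if extent.size else np.empty(0)
    significant = np.zeros(sample.n_nodes, dtype=bool)
    if extent.size:
        sig_clusters = np.flatnonzero(p < alpha) + 1
        significant = np.isin(cluster_id, sig_clusters)
    return InferenceResult(
        cluster_id=cluster_id, cluster_sign=cluster_sign, extent=extent,
        p_fwer=p, significant=significant, null_max_extents=null, stat=stat,
        seed=seed, n_perm=int(null.size), cdt=float(cdt),
        cdt_scale=cdt_scale, alpha=float(alpha),
    )


# ----------------------------------------------------------------------
class TopologicalClusterModel:
    """One-sample cluster-extent model over a clustering topology.

    Parameters
    ----------
    sample : SubjectSample or (n_subjects, n_nodes) array
    topology : SparseSymmetricMatrix (binary)
        Spatial adjacency, optionally augmented with anatomical links.
    cdt : float
        Cluster-defining threshold (default 3.3, i.e. two-sided p=0.001
        on the z scale).
    cdt_scale : {'z', 't'}
    """

    def __init__(self, sample, topology, cdt=3.3, cdt_scale="z"):
        if not isinstance(sample, SubjectSample):
            sample = SubjectSample(np.asarray(sample))
        if not isinstance(topology, SparseSymmetricMatrix):
            topology = SparseSymmetricMatrix.from_scipy(sp.csr_matrix(topology),
                                                        binary=True)
        if sample.n_nodes != topology.n_nodes:
            raise ValueError("sample / topology dimension mismatch")
        self.sample = sample
        self.topology = topology
        self.cdt = float(cdt)
        self.cdt_scale = cdt_scale

    @classmethod
    def from_dataframe(cls, df, topology, **kwargs):
        """Build from a nodes-by-subjects DataFrame."""
        return cls(SubjectSample.from_dataframe(df), topology, **kwargs)

    def stat_map(self):
        return group_t_statistic(self.sample)

    def fit(self, alpha=0.05, n_perm=1000, seed=None, exhaustive=False):
        res = run_inference(self.sample, self.topology, self.cdt, alpha,
                            n_perm, seed, cdt_scale=self.cdt_scale,
                            exhaustive=exhaustive)
        return TopologicalClusterResults(self, res)


class TopologicalClusterResults:
    """Results wrapper: cluster table, significance mask, null, summary."""

    def __init__(self, model, result):
        self.model = model
        self._result = result

    def __getattr__(self, name):
        return getattr(self._result, name)

    @property
    def result(self):
        return self._result

    def summary(self):
        r = self._result
        lines = [
            "Topological cluster statistic (one-sample, two-sided)",
            "=" * 56,
            f"nodes: {self.model.sample.n_nodes}   subjects: {self.model.sample.n_subjects}",
            f"CDT: {r.cdt} ({r.cdt_scale} scale)   alpha: {r.alpha}   permutations: {r.n_perm}",
            f"clusters: {r.n_clusters}   significant: {int((r.p_fwer < r.alpha).sum())}",
            "-" * 56,
        ]
        tab = r.cluster_table()
        lines.append(tab.to_string(index=False) if len(tab) else "(no suprathreshold clusters)")
        return "\n".join(lines)

    def plot_null_distribution(self, ax=None):
        """Histogram of the permutation null of the max cluster extent."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self._result.null_max_extents, bins=30, color="steelblue")
        ax.set_xlabel("max cluster extent under sign flips")
        ax.set_ylabel("permutations")
        return ax
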