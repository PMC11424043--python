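"""Readers and writers: Matrix Market, TSV maps/geometry, result files.

On-disk sparse matrices use Matrix Market coordinate format with
1-based indices (symmetric header on write); node tables are TSV with
an explicit ``node_id`` column so row order never matters.  Every
pipeline output can carry a JSON provenance sidecar with the effective
configuration, seed and package versions.  Optional CIFTI/GIFTI readers
are thin nibabel wrappers imported lazily.
"""

from __future__ import annotations

import glob as globmod
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .geometry import NodeGeometry
from .inference import SubjectSample
from .sparse import SparseSymmetricMatrix

__all__ = [
    "RunConfig",
    "read_sparse_matrix",
    "write_sparse_matrix",
    "read_geometry",
    "write_geometry",
    "read_maps",
    "write_map",
    "read_atlas",
    "write_inference_result",
    "write_provenance",
    "read_surface_gifti",
    "read_dscalar_cifti",
]


# ----------------------------------------------------------------------
# run configuration
@dataclass
class RunConfig:
    """Effective pipeline configuration, serialized into provenance.

    Defaults are the standard analysis settings: CDT z = 3.3 (two-sided
    p = 0.001), alpha 0.05, 1,000 permutations, 6 mm FWHM smoothing,
    100 distance bins, binarization-threshold grid over 0.06-0.16.
    """

    maps: str = ""
    topology: str = ""
    geometry: str = ""
    atlas: str = ""
    cdt: float = 3.3
    cdt_scale: str = "z"
    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    fwhm: float = 6.0
    target_density: float | None = None
    n_bins: int = 100
    threshold_lo: float = 0.06
    threshold_hi: float = 0.16
    n_thresholds: int = 21
    window: float = 0.05

    def to_dict(self):
        return asdict(self)


# ----------------------------------------------------------------------
# Matrix Market
def write_sparse_matrix(matrix, path, comment=""):
    """Write as Matrix Market coordinate format with a symmetric header."""
    # scipy keeps the lower triangle for symmetric output, so store (j, i)
    coo = sp.coo_matrix(
        (matrix.weight, (matrix.col, matrix.row)),
        shape=(matrix.n_nodes, matrix.n_nodes),
    )
    sio.mmwrite(str(path), coo, comment=comment, symmetry="symmetric")


def read_sparse_matrix(path, binary=None):
    """Read a Matrix Market file into a SparseSymmetricMatrix.

    Symmetric-header files are expanded; general-header files must be
    symmetric (matching (i, j)/(j, i) weights) or an error is raised.
    ``binary`` defaults to auto-detection (all weights exactly 1).
    """
    try:
        A = sio.mmread(str(path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValueError(f"{path}: malformed Matrix Market file ({exc})") from exc
    A = sp.coo_matrix(A)
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    if (abs(A - A.T) > 0).nnz:
        raise ValueError(f"{path}: general-header file is not symmetric")
    up = sp.triu(A, k=1).tocoo()
    if binary is None:
        binary = up.nnz > 0 and bool(np.all(up.data == 1))
    return SparseSymmetricMatrix(A.shape[0], up.row, up.col, up.data, binary=binary)


# ----------------------------------------------------------------------
# geometry / atlas TSV
def write_geometry(geometry, path):
    coords = geometry.coordinates
    cols = {"node_id": np.arange(geometry.n_nodes)}
    for k, name in enumerate("xyz"[: coords.shape[1]]):
        cols[name] = coords[:, k]
    cols["group_label"] = geometry.group_label
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_geometry(path):
    df = pd.read_csv(path, sep="\t")
    if "node_id" not in df.columns:
        raise ValueError(f"{path}: missing node_id column")
    df = df.sort_values("node_id")
    axes = [a for a in "xyz" if a in df.columns]
    return NodeGeometry(coordinates=df[axes].to_numpy(float),
                        group_label=df["group_label"].to_numpy())


def read_atlas(path):
    """TSV with node_id, region_id (and optional region metadata file)."""
    from .network import AtlasLabeling

    df = pd.read_csv(path, sep="\t").sort_values("node_id")
    return AtlasLabeling(region_id=df["region_id"].to_numpy())


# ----------------------------------------------------------------------
# subject maps
def write_map(values, path, columns=None):
    """Per-node map(s) as TSV: node_id plus one column per map."""
    values = np.atleast_2d(np.asarray(values, dtype=float))  # (n_maps, n_nodes)
    if columns is None:
        columns = [f"map_{i}" for i in range(values.shape[0])]
    df = pd.DataFrame({"node_id": np.arange(values.shape[1])})
    for name, row in zip(columns, values):
        df[name] = row
    df.to_csv(path, sep="\t", index=False)


def _read_one_map_file(path):
    df = pd.read_csv(path, sep="\t")
    if "node_id" not in df.columns:
        raise ValueError(f"{path}: missing node_id column")
    return df.set_index("node_id").sort_index()


def read_maps(path_or_glob):
    """Read subject maps from one TSV or a glob of per-subject TSVs.

    A single file holds node_id plus one column per subject; multiple
    files hold one value column each.  Node sets must agree exactly
    across subjects, otherwise an alignment error lists the offenders.
    """
    paths = sorted(globmod.glob(str(path_or_glob))) \
        if any(ch in str(path_or_glob) for ch in "*?[") else [str(path_or_glob)]
    if not paths:
        raise FileNotFoundError(f"no files match {path_or_glob}")
    frames = [_read_one_map_file(p) for p in paths]
    ref = frames[0].index
    bad = [p for p, f in zip(paths, frames) if not f.index.equals(ref)]
    if bad:
        raise ValueError("subject maps disagree on node ids: " + ", ".join(bad))
    if len(frames) == 1:
        df = frames[0]
        return SubjectSample(df.to_numpy(float).T, subject_ids=list(df.columns))
    values = np.stack([f.iloc[:, 0].to_numpy(float) for f in frames])
    return SubjectSample(values, subject_ids=[Path(p).stem for p in paths])


# ----------------------------------------------------------------------
# inference results
def write_inference_result(result, prefix, config=None):
    """Per-node TSV + JSON sidecar (cluster table, null, provenance)."""
    result.node_table().to_csv(f"{prefix}_nodes.tsv", sep="\t", index=False)
    sidecar = {
        "clusters": result.cluster_table().to_dict(orient="records"),
        "null_max_extents": result.null_max_extents.tolist(),
        "provenance": provenance_dict(
            dict(config or {}), seed=result.seed, n_perm=result.n_perm,
            cdt=result.cdt, cdt_scale=result.cdt_scale, alpha=result.alpha),
    }
    with open(f"{prefix}_clusters.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def provenance_dict(config, **extra):
    import numpy
    import scipy

    from . import __version__

    cfg = dict(config)
    cfg.update(extra)
    return {
        "config": cfg,
        "versions": {
            "tcstat": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }


def write_provenance(path, config, **extra):
    with open(path, "w") as fh:
        json.dump(provenance_dict(config, **extra), fh, indent=1, default=_jsonify)


# ----------------------------------------------------------------------
# optional neuroimaging formats (lazy nibabel)
def read_surface_gifti(path):
    """Triangles and vertex count of a GIFTI surface (.surf.gii)."""
    import nibabel as nib

    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return tris.astype(np.int64), coords.shape[0]


def read_dscalar_cifti(path):
    """Dense scalar maps of a CIFTI-2 .dscalar.nii as (n_maps, n_nodes)."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata())
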