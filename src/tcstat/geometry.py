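"""Node geometry: coordinates, hemisphere/structure labels, distances.

Connection classes follow the convention used for distance-dependent
consensus connectome construction: an edge touching a subcortical node is
"subcortical"; otherwise it is "interhemispheric" when its endpoints lie
in different cortical hemispheres and "intrahemispheric" when they share
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NodeGeometry",
    "INTERHEMISPHERIC",
    "INTRAHEMISPHERIC",
    "SUBCORTICAL",
    "CONNECTION_CLASSES",
]

INTERHEMISPHERIC = "interhemispheric"
INTRAHEMISPHERIC = "intrahemispheric"
SUBCORTICAL = "subcortical"
CONNECTION_CLASSES = (INTERHEMISPHERIC, INTRAHEMISPHERIC, SUBCORTICAL)


@dataclass
class NodeGeometry:
    """Per-node positions (mm or grid units) and group labels.

    Parameters
    ----------
    coordinates : (n_nodes, ndim) float array, ndim in {2, 3}
    group_label : (n_nodes,) array of str
        Typically ``"left"``, ``"right"`` or ``"subcortical"``; any label
        listed in ``subcortical_labels`` is treated as subcortical, all
        other labels as cortical hemispheres.
    """

    coordinates: np.ndarray
    group_label: np.ndarray
    subcortical_labels: frozenset = field(default_factory=lambda: frozenset({SUBCORTICAL}))

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.group_label = np.asarray(self.group_label)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] not in (2, 3):
            raise ValueError("coordinates must be (n_nodes, 2|3)")
        if self.group_label.shape != (self.coordinates.shape[0],):
            raise ValueError("one group label per node required")

    @property
    def n_nodes(self):
        return self.coordinates.shape[0]

    def distance(self, i, j):
        """Euclidean distance between node arrays ``i`` and ``j``."""
        d = self.coordinates[np.asarray(i)] - self.coordinates[np.asarray(j)]
        return np.sqrt(np.einsum("...k,...k->...", d, d))

    def connection_class(self, i, j):
        """Connection class per edge: subcortical beats inter/intra."""
        i = np.asarray(i)
        j = np.asarray(j)
        li = self.group_label[i]
        lj = self.group_label[j]
        sub = np.isin(li, list(self.subcortical_labels)) | np.isin(lj, list(self.subcortical_labels))
        out = np.where(sub, SUBCORTICAL,
                       np.where(li == lj, INTRAHEMISPHERIC, INTERHEMISPHERIC))
        return out
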