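"""Node-to-subnetwork partitions and edge classification.

The Power-264 parcellation groups 264 functional regions into 14 subnetworks
(default mode, salience, frontoparietal task control, cingulo-opercular task
control, sensory/somatomotor hand, visual, ...).  An edge is *within* a
subnetwork when both endpoints carry the same label and *cross*-subnetwork
otherwise.  This module holds the partition, classifies edges, and formats the
cross/within proportions the analysis reports.

No atlas table ships with the package: any user-supplied partition CSV is
accepted, and the synthetic module generates fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "POWER264_SUBNETWORKS",
    "AtlasPartition",
    "edge_pair_label",
    "cross_within_counts",
    "CrossWithinCounts",
    "percent_2dp",
]

#: The 14 Power-264 subnetwork abbreviations: uncertain, sensory/somatomotor
#: hand, sensory/somatomotor mouth, cingulo-opercular task control, auditory,
#: default mode, memory retrieval, ventral attention, visual, frontoparietal
#: task control, salience, subcortical, cerebellar, dorsal attention.
POWER264_SUBNETWORKS = (
    "U", "SH", "SM", "CT", "Au", "DM", "MR",
    "VT", "V", "FT", "Sa", "Su", "Ce", "DA",
)


@dataclass(frozen=True)
class AtlasPartition:
    """Assignment of every node to exactly one subnetwork label.

    Node ids are 0-based and contiguous (``0 .. N-1``); ``labels[i]`` is the
    subnetwork of node ``i``.  MNI coordinates are optional metadata.
    """

    labels: np.ndarray
    coords: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("partition needs a non-empty 1-D label array")
        object.__setattr__(self, "labels", labels)
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (labels.size, 3):
                raise ValueError("coords must be (n_nodes, 3) MNI mm")
            object.__setattr__(self, "coords", coords)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def subnetworks(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def label_of(self, node: int) -> str:
        if not 0 <= node < self.n_nodes:
            raise ValueError(f"node id {node} outside partition of {self.n_nodes} nodes")
        return str(self.labels[node])


def edge_pair_label(edge: tuple[int, int], partition: AtlasPartition) -> tuple[str, str]:
    """Unordered subnetwork pair of an edge, as a sorted label tuple.

    ``("DM", "Sa")`` and ``("Sa", "DM")`` canonicalize to the same value; a
    pair ``("DM", "DM")`` marks a within-subnetwork edge.
    """
    i, j = edge
    if i == j:
        raise ValueError(f"self-edge ({i}, {j}) is not a valid edge")
    a, b = partition.label_of(int(i)), partition.label_of(int(j))
    return (a, b) if a <= b else (b, a)


def percent_2dp(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-up to 2 decimal places.

    Half-up (13.636... -> 13.64) matches the reporting convention used for
    the cross-subnetwork proportions; Python's built-in round() is half-even
    and would disagree on exact halves.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CrossWithinCounts:
    """Cross- vs within-subnetwork composition of an edge set."""

    cross: int
    within: int
    cross_pct: float
    within_pct: float

    @property
    def total(self) -> int:
        return self.cross + self.within


def cross_within_counts(
    edges, partition: AtlasPartition
) -> CrossWithinCounts:
    """Count cross- and within-subnetwork edges and their percentages.

    Parameters
    ----------
    edges : iterable of (i, j) pairs or (n_edges, 2) array
        Node-pair edges; order within a pair does not matter.
    partition : AtlasPartition

    Raises
    ------
    ValueError
        If the edge set is empty (the proportion is undefined).
    """
    arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges)
    if arr.size == 0:
        raise ValueError("cross/within proportion is undefined for an empty edge set")
    arr = arr.reshape(-1, 2).astype(int)
    lab = partition.labels
    if arr.min() < 0 or arr.max() >= partition.n_nodes:
        raise ValueError("edge endpoint outside partition")
    cross = int(np.sum(lab[arr[:, 0]] != lab[arr[:, 1]]))
    within = arr.shape[0] - cross
    return CrossWithinCounts(
        cross=cross,
        within=within,
        cross_pct=percent_2dp(cross, arr.shape[0]),
        within_pct=percent_2dp(within, arr.shape[0]),
    )
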