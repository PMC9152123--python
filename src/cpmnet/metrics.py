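"""Strength summaries of consensus networks.

For a fixed edge set (a consensus network) and one subject's connectome:
*network strength* is the sum of Fisher-z weights over the set, *pair
strength* restricts the sum to edges whose endpoints form a given unordered
subnetwork pair, and *node strength* sums the weights of the edges incident
to each node.  Sums are signed — negative z weights subtract; pass
``absolute=True`` for the sensitivity variant.  Summation always follows the
canonical edge order, so the handshake identity (node strengths summing to
twice the total) and the pair-partition identity (pair strengths summing to
the total) hold exactly in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasPartition, percent_2dp
from .connectome import edge_keys

__all__ = [
    "network_strength",
    "pair_strength",
    "node_strength",
    "edge_pair_labels",
    "SubnetworkSummary",
    "subnetwork_summary",
]


def _edge_values(connectome: np.ndarray, edges: np.ndarray):
    """Weights of the listed edges, given either a matrix or an edge vector."""
    m = np.asarray(connectome, dtype=float)
    edges = np.asarray(edges, dtype=int)
    if m.ndim == 2:  # square matrix; edges as (k, 2) node pairs or flat indices
        if edges.ndim == 2:
            return m[edges[:, 0], edges[:, 1]], edges
        keys = edge_keys(m.shape[0])[edges]
        return m[keys[:, 0], keys[:, 1]], keys
    if edges.ndim != 1:
        raise ValueError("edge-vector input needs flat edge indices")
    return m[edges], None


def network_strength(
    connectome: np.ndarray, edges: np.ndarray, absolute: bool = False
) -> float:
    """Sum of edge weights over ``edges`` for one subject; empty set -> 0."""
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        return 0.0
    vals, _ = _edge_values(connectome, edges)
    return float(np.abs(vals).sum() if absolute else vals.sum())


def edge_pair_labels(
    edges: np.ndarray, partition: AtlasPartition, n_nodes: int | None = None
) -> list[tuple[str, str]]:
    """Canonical (sorted) subnetwork-pair label of each edge."""
    edges = np.asarray(edges, dtype=int)
    if edges.ndim == 1:
        if n_nodes is None:
            n_nodes = partition.n_nodes
        edges = edge_keys(n_nodes)[edges]
    lab = partition.labels
    return [tuple(sorted((str(lab[i]), str(lab[j])))) for i, j in edges]


def pair_strength(
    connectome: np.ndarray,
    edges: np.ndarray,
    partition: AtlasPartition,
    pair: tuple[str, str],
    absolute: bool = False,
) -> float:
    """Strength restricted to edges whose endpoint labels form ``pair``."""
    known = set(partition.subnetworks)
    for lab in pair:
        if lab not in known:
            raise ValueError(f"unknown subnetwork label {lab!r}")
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        return 0.0
    target = tuple(sorted(pair))
    labels = edge_pair_labels(edges, partition)
    mask = np.array([l == target for l in labels])
    sub = edges[mask] if edges.ndim == 1 else edges[mask, :]
    return network_strength(connectome, sub, absolute=absolute)


def node_strength(
    connectome: np.ndarray,
    edges: np.ndarray,
    n_nodes: int | None = None,
    absolute: bool = False,
) -> np.ndarray:
    """Per-node strength: sum of incident edge weights; isolated nodes get 0."""
    m = np.asarray(connectome, dtype=float)
    if n_nodes is None:
        if m.ndim != 2:
            raise ValueError("n_nodes required when connectome is an edge vector")
        n_nodes = m.shape[0]
    out = np.zeros(n_nodes)
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        return out
    vals, keys = _edge_values(m, edges)
    if keys is None:
        keys = edge_keys(n_nodes)[edges]
    if absolute:
        vals = np.abs(vals)
    np.add.at(out, keys[:, 0], vals)
    np.add.at(out, keys[:, 1], vals)
    return out


@dataclass(frozen=True)
class SubnetworkSummary:
    """Composition and per-subject strength of a network by subnetwork pair.

    ``pair_counts``: edge count and percentage per unordered pair (within
    pairs appear as ``A-A``).  ``pair_strengths``: one row per subject x pair
    with the summed strength.  Percentages are rounded half-up to 2 dp and
    sum to 100 up to rounding.
    """

    pair_counts: pd.DataFrame
    pair_strengths: pd.DataFrame
    cross: int
    within: int
    cross_pct: float
    within_pct: float

    @property
    def total_edges(self) -> int:
        return self.cross + self.within


def subnetwork_summary(
    edge_matrix: np.ndarray,
    edges: np.ndarray,
    partition: AtlasPartition,
    subject_ids=None,
    absolute: bool = False,
) -> SubnetworkSummary:
    """Summarize a consensus edge set by subnetwork pair.

    Parameters
    ----------
    edge_matrix : (n_subjects, n_edges) array
        Edge vectors for all subjects (canonical order).
    edges : flat edge indices of the network
    partition : AtlasPartition
    subject_ids : optional sequence for the strength table index
    """
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        raise ValueError("cannot summarize an empty edge set")
    x = np.asarray(edge_matrix, dtype=float)
    if subject_ids is None:
        subject_ids = list(range(x.shape[0]))

    labels = edge_pair_labels(edges, partition)
    pairs = sorted(set(labels))
    total = edges.size
    count_rows = []
    strength_rows = []
    vals = x[:, edges]
    if absolute:
        vals = np.abs(vals)
    for pair in pairs:
        mask = np.array([l == pair for l in labels])
        cnt = int(mask.sum())
        count_rows.append(
            {
                "subnetwork_a": pair[0],
                "subnetwork_b": pair[1],
                "within": pair[0] == pair[1],
                "n_edges": cnt,
                "pct": percent_2dp(cnt, total),
            }
        )
        per_subject = vals[:, mask].sum(axis=1)
        for sid, s in zip(subject_ids, per_subject):
            strength_rows.append(
                {
                    "subject_id": sid,
                    "pair": f"{pair[0]}-{pair[1]}",
                    "strength": float(s),
                }
            )
    counts = pd.DataFrame(count_rows)
    cross = int(counts.loc[~counts["within"], "n_edges"].sum())
    within = total - cross
    return SubnetworkSummary(
        pair_counts=counts,
        pair_strengths=pd.DataFrame(strength_rows),
        cross=cross,
        within=within,
        cross_pct=percent_2dp(cross, total),
        within_pct=percent_2dp(within, total),
    )
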