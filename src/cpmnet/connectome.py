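"""Fisher-z connectivity matrices and the canonical edge-vector mapping.

A connectome here is a symmetric ``N x N`` matrix of Fisher z-transformed
Pearson correlations between regional time series, with an exactly zero
diagonal.  All modules share one canonical flattening of the upper triangle
(row-major over ``i < j``), so that edge index ``k`` means the same node pair
everywhere — fold-wise selections can then be intersected by index.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "R_CLIP",
    "compute_connectome",
    "validate_connectome",
    "n_edges",
    "edge_keys",
    "vectorize",
    "devectorize",
]

#: Pearson correlations are clipped to ``+/- (1 - R_CLIP)`` before atanh so a
#: perfectly correlated pair of regions still yields a finite edge weight.
R_CLIP = 1e-7


def n_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, ``N (N - 1) / 2``."""
    return n_nodes * (n_nodes - 1) // 2


def edge_keys(n_nodes: int) -> np.ndarray:
    """Canonical edge order: ``(n_edges, 2)`` array of node pairs ``i < j``.

    Row-major over the upper triangle: ``(0,1), (0,2), ..., (0,N-1), (1,2), ...``
    """
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def compute_connectome(timeseries: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of regional time series, Fisher z-transformed.

    Parameters
    ----------
    timeseries : (T, N) array
        ``T`` time points for ``N`` regions, one column per region.

    Returns
    -------
    (N, N) array
        Symmetric matrix of ``atanh(r)`` values with zero diagonal.  ``|r|`` is
        clipped at ``1 - R_CLIP`` so the output is always finite.

    Raises
    ------
    ValueError
        If ``T < 3`` or any region has a constant time series (zero variance).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError(f"expected a 2-D time-series matrix, got shape {ts.shape}")
    t, n = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time series for region(s) {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    np.clip(r, -(1.0 - R_CLIP), 1.0 - R_CLIP, out=r)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    # corrcoef is symmetric up to floating point; enforce it exactly
    z = (z + z.T) / 2.0
    return z


def validate_connectome(values: np.ndarray) -> np.ndarray:
    """Check symmetry, finiteness and zero diagonal; return as float array."""
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"connectome must be square, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("connectome contains non-finite values")
    if not np.array_equal(m, m.T):
        raise ValueError("connectome is not symmetric")
    if np.any(np.diagonal(m) != 0):
        raise ValueError("connectome diagonal is not zero")
    return m


def vectorize(connectome: np.ndarray) -> np.ndarray:
    """Flatten the upper triangle (``i < j``) in canonical row-major order."""
    m = np.asarray(connectome, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"connectome must be square, got shape {m.shape}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def devectorize(edge_vector: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric zero-diagonal matrix."""
    v = np.asarray(edge_vector, dtype=float)
    expected = n_edges(n_nodes)
    if v.ndim != 1 or v.size != expected:
        raise ValueError(
            f"edge vector has length {v.size}, expected {expected} for N={n_nodes}"
        )
    m = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    m[iu] = v
    m += m.T
    return m
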