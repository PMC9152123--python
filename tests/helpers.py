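"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit loops, scipy reference
routines) and shares no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def naive_connectome(timeseries: np.ndarray) -> np.ndarray:
    """Double-loop Pearson + atanh, no clipping (use away from |r| = 1)."""
    t, n = timeseries.shape
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                r, _ = stats.pearsonr(timeseries[:, i], timeseries[:, j])
                out[i, j] = np.arctanh(r)
    return out


def naive_loocv_predictions(
    edge_matrix: np.ndarray, scores: np.ndarray, threshold: float
) -> np.ndarray:
    """From-scratch leave-one-out CPM: per-edge scipy pearsonr screening,
    normal-equations bivariate fit, no shared code with cpmnet.cpm."""
    n, n_edge = edge_matrix.shape
    pred = np.empty(n)
    for k in range(n):
        tr = [s for s in range(n) if s != k]
        x = edge_matrix[tr]
        y = scores[tr]
        pos, neg = [], []
        for e in range(n_edge):
            if np.ptp(x[:, e]) == 0:
                continue
            r, p = stats.pearsonr(x[:, e], y)
            if p < threshold:
                (pos if r > 0 else neg).append(e)
        feats = [np.ones(len(tr))]
        use_pos = pos and np.ptp(x[:, pos].sum(axis=1)) > 0
        use_neg = neg and np.ptp(x[:, neg].sum(axis=1)) > 0
        if use_pos:
            feats.append(x[:, pos].sum(axis=1))
        if use_neg:
            feats.append(x[:, neg].sum(axis=1))
        a = np.column_stack(feats)
        beta = np.linalg.solve(a.T @ a, a.T @ y)
        row = [1.0]
        if use_pos:
            row.append(edge_matrix[k, pos].sum())
        if use_neg:
            row.append(edge_matrix[k, neg].sum())
        pred[k] = np.asarray(row) @ beta
    return pred


def anova_f_from_summary(means, sds, ns) -> float:
    """One-way ANOVA F from per-group means, SDs (ddof=1) and sizes."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    k = len(ns)
    return (ss_between / (k - 1)) / (ss_within / (ns.sum() - k))


def bh_reject(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg by its step-up definition: largest k with
    p_(k) <= k q / m; reject the k smallest."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ranked <= thresh)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing.max() + 1]] = True
    return reject
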