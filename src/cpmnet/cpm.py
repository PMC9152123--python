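"""Connectome-based predictive modeling (CPM).

The procedure, per leave-one-out fold: correlate every connectivity edge with
the symptom score over the training subjects; keep edges with two-sided
``p < threshold``, split by correlation sign; sum each subject's weights over
the positive set and over the negative set; regress the score on the two sums
by ordinary least squares; predict the held-out subject from its own sums
under the *training* selection.  Model accuracy is the Pearson correlation of
out-of-fold predictions with observed scores, and its significance comes from
an empirical null built by re-running the whole cross-validated procedure on
permuted scores.

Edges selected with the same sign in every fold form the consensus positive
and negative networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_THRESHOLD_GRID",
    "EdgeSelection",
    "FoldModel",
    "CPMFit",
    "PermutationResult",
    "ConsensusNetworks",
    "correlate_edges",
    "select_edges",
    "summed_strength",
    "fit_model",
    "predict",
    "loocv",
    "permutation_test",
    "threshold_sweep",
    "consensus_networks",
    "consensus_union",
]

#: Edge-screening p-value cutoff used for the main model.
DEFAULT_THRESHOLD = 0.01

#: The screening-threshold sweep: 0.005 to 0.05 in steps of 0.005, 10 models.
DEFAULT_THRESHOLD_GRID = tuple(round(0.005 * k, 3) for k in range(1, 11))


# ---------------------------------------------------------------------------
# edge screening
# ---------------------------------------------------------------------------

def correlate_edges(edge_matrix: np.ndarray, scores: np.ndarray):
    """Per-edge Pearson correlation with the score, and its two-sided p.

    Parameters
    ----------
    edge_matrix : (n_subjects, n_edges) array
    scores : (n_subjects,) array

    Returns
    -------
    r, p : (n_edges,) arrays
        ``p`` is from the t transform ``t = r sqrt((n-2)/(1-r^2))`` with
        ``n - 2`` degrees of freedom.  Constant edges get ``r = 0, p = 1``;
        ``|r| = 1`` gives ``p = 0``.

    Raises
    ------
    ValueError
        Fewer than 4 subjects, or constant scores.
    """
    x = np.asarray(edge_matrix, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValueError("edge_matrix must be (n_subjects, n_edges)")
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 subjects to screen edges, got {n}")
    if y.shape != (n,):
        raise ValueError("scores length does not match edge_matrix rows")
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        raise ValueError("scores are constant; edge screening is undefined")

    xc = x - x.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", xc, xc)
    num = yc @ xc
    constant = np.ptp(x, axis=0) == 0.0  # exact test on the raw column
    denom = np.sqrt(ss_x * ss_y)
    denom[constant] = 1.0  # avoid 0/0; overwritten below
    r = num / denom
    np.clip(r, -1.0, 1.0, out=r)
    r[constant] = 0.0

    df = n - 2
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = np.where(np.isinf(t), 0.0, 2.0 * special.stdtr(df, -np.abs(t)))
    p[constant] = 1.0
    return r, p


@dataclass(frozen=True)
class EdgeSelection:
    """Edges surviving the screen at ``threshold``, split by correlation sign.

    ``positive`` / ``negative`` are sorted indices into the canonical edge
    vector; ``r`` and ``p`` are the full per-edge statistics the selection was
    made from.
    """

    positive: np.ndarray
    negative: np.ndarray
    r: np.ndarray
    p: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        if np.intersect1d(self.positive, self.negative).size:
            raise ValueError("positive and negative selections overlap")

    @property
    def n_selected(self) -> tuple[int, int]:
        return self.positive.size, self.negative.size


def select_edges(r: np.ndarray, p: np.ndarray, threshold: float) -> EdgeSelection:
    """Select edges with strictly ``p < threshold``, partitioned by sign of r.

    Ties at the threshold are excluded (strict inequality), which makes the
    selections nested across increasing thresholds.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise ValueError("r and p must have the same length")
    hit = p < threshold
    return EdgeSelection(
        positive=np.flatnonzero(hit & (r > 0)),
        negative=np.flatnonzero(hit & (r < 0)),
        r=r,
        p=p,
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# features and the linear model
# ---------------------------------------------------------------------------

def summed_strength(subject_edges: np.ndarray, selection: EdgeSelection):
    """Sum a subject's edge weights over the positive and negative selections.

    ``subject_edges`` may be one edge vector ``(n_edges,)`` or a stack
    ``(n_subjects, n_edges)``; empty selections sum to 0.
    """
    v = np.asarray(subject_edges, dtype=float)
    pos = v[..., selection.positive].sum(axis=-1)
    neg = v[..., selection.negative].sum(axis=-1)
    return pos, neg


@dataclass(frozen=True)
class FoldModel:
    """OLS fit of score on the summed strengths, for one training set.

    A feature that is constant across training subjects is dropped and its
    slope recorded as None.  If no usable feature remains the model falls back
    to the training-mean intercept (``fallback_mean``).
    """

    intercept: float
    b_pos: float | None
    b_neg: float | None
    fallback_mean: bool = False


def fit_model(
    pos_sums: np.ndarray, neg_sums: np.ndarray, scores: np.ndarray
) -> FoldModel:
    """Ordinary least squares: ``score ~ 1 + pos_sum + neg_sum``."""
    pos = np.asarray(pos_sums, dtype=float)
    neg = np.asarray(neg_sums, dtype=float)
    y = np.asarray(scores, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError(f"need at least 4 training subjects, got {n}")

    use_pos = np.ptp(pos) > 0
    use_neg = np.ptp(neg) > 0
    cols = [np.ones(n)]
    if use_pos:
        cols.append(pos)
    if use_neg:
        cols.append(neg)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)

    if not (use_pos or use_neg):
        return FoldModel(intercept=float(y.mean()), b_pos=None, b_neg=None,
                         fallback_mean=True)
    it = iter(beta[1:])
    return FoldModel(
        intercept=float(beta[0]),
        b_pos=float(next(it)) if use_pos else None,
        b_neg=float(next(it)) if use_neg else None,
    )


def predict(model: FoldModel, pos_sum, neg_sum):
    """Apply a fold model to (scalar or vector) summed strengths."""
    out = np.asarray(pos_sum, dtype=float) * 0.0 + model.intercept
    if model.b_pos is not None:
        out = out + model.b_pos * np.asarray(pos_sum, dtype=float)
    if model.b_neg is not None:
        out = out + model.b_neg * np.asarray(neg_sum, dtype=float)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPMFit:
    """Result of one cross-validated CPM run.

    One fold per subject; ``predicted_scores[k]`` is the out-of-fold
    prediction for subject ``k`` under the model trained without it.  In
    ``mode="separate"`` two univariate models are fitted per fold and
    ``predicted_scores`` holds the positive-network model's predictions,
    with the negative model's in ``predicted_scores_neg``.
    """

    threshold: float
    mode: str
    fold_selections: list[EdgeSelection]
    fold_models: list
    predicted_scores: np.ndarray
    observed_scores: np.ndarray
    accuracy_r: float
    predicted_scores_neg: np.ndarray | None = None
    accuracy_r_neg: float | None = None

    @property
    def n_folds(self) -> int:
        return len(self.fold_selections)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt(float(ac @ ac) * float(bc @ bc))
    if denom == 0.0:
        return float("nan")
    return float(ac @ bc / denom)


def _as_edge_matrix(connectomes: np.ndarray) -> np.ndarray:
    arr = np.asarray(connectomes, dtype=float)
    if arr.ndim == 3:
        iu = np.triu_indices(arr.shape[1], k=1)
        return arr[:, iu[0], iu[1]]
    if arr.ndim == 2:
        return arr
    raise ValueError("connectomes must be (n, N, N) matrices or (n, E) edge vectors")


def loocv(
    connectomes: np.ndarray,
    scores: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "joint",
) -> CPMFit:
    """Leave-one-out cross-validated CPM.

    Parameters
    ----------
    connectomes : (n, N, N) stack of connectomes or (n, n_edges) edge matrix
    scores : (n,) observed symptom scores
    threshold : edge-screening p cutoff
    mode : {"joint", "separate"}
        ``"joint"`` enters both summed strengths into one bivariate linear
        model (the default).  ``"separate"`` fits the classic variant: one
        univariate model per network sign.

    Each fold screens edges on its own n-1 training subjects only — the
    held-out subject contributes nothing to selection or fit, so its score
    cannot leak into its prediction.
    """
    if mode not in ("joint", "separate"):
        raise ValueError(f"mode must be 'joint' or 'separate', got {mode!r}")
    x = _as_edge_matrix(connectomes)
    y = np.asarray(scores, dtype=float)
    n = x.shape[0]
    if y.shape != (n,):
        raise ValueError("scores length does not match number of subjects")
    if n < 5:
        raise ValueError(f"LOOCV needs at least 5 subjects, got {n}")

    idx = np.arange(n)
    selections: list[EdgeSelection] = []
    models: list = []
    pred = np.empty(n)
    pred_neg = np.empty(n) if mode == "separate" else None

    for k in range(n):
        train = idx != k
        x_tr, y_tr = x[train], y[train]
        if np.ptp(y_tr) == 0:
            raise ValueError(f"training scores are constant in fold {k}")
        r, p = correlate_edges(x_tr, y_tr)
        sel = select_edges(r, p, threshold)
        pos_tr, neg_tr = summed_strength(x_tr, sel)
        pos_te, neg_te = summed_strength(x[k], sel)
        selections.append(sel)
        if mode == "joint":
            model = fit_model(pos_tr, neg_tr, y_tr)
            models.append(model)
            pred[k] = predict(model, pos_te, neg_te)
        else:
            m_pos = fit_model(pos_tr, np.zeros_like(pos_tr), y_tr)
            m_neg = fit_model(np.zeros_like(neg_tr), neg_tr, y_tr)
            models.append((m_pos, m_neg))
            pred[k] = predict(m_pos, pos_te, 0.0)
            pred_neg[k] = predict(m_neg, 0.0, neg_te)

    return CPMFit(
        threshold=float(threshold),
        mode=mode,
        fold_selections=selections,
        fold_models=models,
        predicted_scores=pred,
        observed_scores=y.copy(),
        accuracy_r=_pearson(pred, y),
        predicted_scores_neg=pred_neg,
        accuracy_r_neg=_pearson(pred_neg, y) if pred_neg is not None else None,
    )


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    """Empirical null for the LOOCV accuracy.

    ``p_value`` uses the add-one estimator
    ``(1 + #{null_r >= observed_r}) / (n_perm + 1)``, so it is never exactly
    zero and lies in ``(0, 1]``.
    """

    observed_r: float
    null_r: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def permutation_test(
    connectomes: np.ndarray,
    scores: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "joint",
) -> PermutationResult:
    """Permutation test of the LOOCV accuracy.

    Each permutation randomly reassigns the observed scores to subjects (a
    permutation of the labels, not a resample), reruns the full
    cross-validated procedure, and records the null accuracy.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    x = _as_edge_matrix(connectomes)
    y = np.asarray(scores, dtype=float)
    observed = loocv(x, y, threshold=threshold, mode=mode).accuracy_r
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = rng.permutation(y)
        null[b] = loocv(x, y_perm, threshold=threshold, mode=mode).accuracy_r
    # a null run whose predictions are constant yields nan; count it as >= obs
    # never happening (it carries no evidence of accuracy)
    exceed = int(np.nansum(null >= observed))
    p = (1 + exceed) / (n_perm + 1)
    return PermutationResult(
        observed_r=float(observed),
        null_r=null,
        p_value=float(p),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def threshold_sweep(
    connectomes: np.ndarray,
    scores: np.ndarray,
    thresholds=DEFAULT_THRESHOLD_GRID,
    n_perm: int = 0,
    seed: int = 0,
    mode: str = "joint",
) -> pd.DataFrame:
    """Fit one CPM per screening threshold.

    Returns a table with one row per threshold: ``threshold``, ``accuracy_r``,
    and ``p_value`` (permutation p when ``n_perm > 0``, else NaN).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("duplicate thresholds in sweep grid")
    x = _as_edge_matrix(connectomes)
    rows = []
    for t in thresholds:
        if n_perm > 0:
            res = permutation_test(
                x, scores, threshold=t, n_perm=n_perm, seed=seed, mode=mode
            )
            rows.append((t, res.observed_r, res.p_value))
        else:
            fit = loocv(x, scores, threshold=t, mode=mode)
            rows.append((t, fit.accuracy_r, np.nan))
    return pd.DataFrame(rows, columns=["threshold", "accuracy_r", "p_value"])


# ---------------------------------------------------------------------------
# consensus networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusNetworks:
    """Edges selected with the same sign in every fold, with mean weights.

    ``positive`` / ``negative`` are sorted edge indices; ``*_weights`` are the
    corresponding mean connectome weights over all subjects.
    """

    positive: np.ndarray
    negative: np.ndarray
    positive_weights: np.ndarray
    negative_weights: np.ndarray


def consensus_networks(fit: CPMFit, connectomes: np.ndarray) -> ConsensusNetworks:
    """Intersect the fold-wise selections ("survived in each iteration").

    An edge enters the consensus positive (negative) network iff it is in the
    positive (negative) selection of every fold.  Per-edge weight is the mean
    over subjects of the edge's connectome value.  An empty intersection is
    allowed but warned about.
    """
    if not fit.fold_selections:
        raise ValueError("fit has no folds")
    x = _as_edge_matrix(connectomes)
    pos = fit.fold_selections[0].positive
    neg = fit.fold_selections[0].negative
    for sel in fit.fold_selections[1:]:
        pos = np.intersect1d(pos, sel.positive, assume_unique=True)
        neg = np.intersect1d(neg, sel.negative, assume_unique=True)
    if pos.size == 0 and neg.size == 0:
        warnings.warn("consensus networks are empty (no edge survived all folds)")
    mean_w = x.mean(axis=0)
    return ConsensusNetworks(
        positive=pos,
        negative=neg,
        positive_weights=mean_w[pos],
        negative_weights=mean_w[neg],
    )


def consensus_union(fit: CPMFit, connectomes: np.ndarray) -> ConsensusNetworks:
    """Non-default aggregation: union of fold-wise selections.

    Provided for sensitivity analysis; an edge selected positively in one fold
    and negatively in another is dropped from both unions to keep them
    disjoint.
    """
    if not fit.fold_selections:
        raise ValueError("fit has no folds")
    x = _as_edge_matrix(connectomes)
    pos = np.unique(np.concatenate([s.positive for s in fit.fold_selections]))
    neg = np.unique(np.concatenate([s.negative for s in fit.fold_selections]))
    both = np.intersect1d(pos, neg)
    pos = np.setdiff1d(pos, both, assume_unique=True)
    neg = np.setdiff1d(neg, both, assume_unique=True)
    mean_w = x.mean(axis=0)
    return ConsensusNetworks(
        positive=pos,
        negative=neg,
        positive_weights=mean_w[pos],
        negative_weights=mean_w[neg],
    )
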