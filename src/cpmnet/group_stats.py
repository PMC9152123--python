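"""Covariate-adjusted group comparisons of network measures.

Network and node strengths are compared among the three groups with a general
linear model (strength ~ group + age + gender + education + mean FD): the
group effect is the partial F for the group factor, which for a single
categorical factor equals the Type III F.  Families of such tests are
Bonferroni-corrected; node-level comparisons over all atlas nodes use
Benjamini-Hochberg FDR instead.  Demographics use one-way ANOVA or a Pearson
chi-square, with LSD / Dunnett-T3 style post hoc contrasts.

Gender is coded 0 = female, 1 = male throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "bonferroni",
    "ancova_f",
    "oneway_anova",
    "chi_square_table",
    "paired_compare",
    "pairwise_posthoc",
    "node_group_anova",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical comparison: statistic, df, raw and corrected p."""

    measure: str
    statistic_name: str  # "F", "t" or "chi2"
    statistic: float
    df: tuple
    p_raw: float
    p_adj: float | None = None
    method: str | None = None
    covariates: tuple = field(default_factory=tuple)

    def to_row(self) -> dict:
        return {
            "measure": self.measure,
            "statistic": self.statistic_name,
            "value": self.statistic,
            "df": "/".join(f"{d:g}" for d in self.df),
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "method": self.method,
        }


def bonferroni(p: float, family_size: int) -> float:
    """Bonferroni-corrected p: ``min(1, m * p)``."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, family_size * p)


# ---------------------------------------------------------------------------
# general linear model with covariates
# ---------------------------------------------------------------------------

def _group_dummies(groups: pd.Series) -> pd.DataFrame:
    g = pd.Series(groups).astype(str)
    return pd.get_dummies(g, prefix="group", drop_first=True, dtype=float)


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify columns that do not increase the rank when appended
        aliased = []
        rank = 0
        kept = np.empty((x.shape[0], 0))
        for name, col in zip(design.columns, x.T):
            cand = np.column_stack([kept, col])
            r = np.linalg.matrix_rank(cand)
            if r > rank:
                kept, rank = cand, r
            else:
                aliased.append(str(name))
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def ancova_f(
    values,
    groups,
    covariates: pd.DataFrame | None = None,
    measure: str = "value",
) -> ComparisonResult:
    """F-test for the group factor, adjusting for covariates.

    Fits ``value ~ 1 + group + covariates`` by OLS and compares it against the
    covariates-only model; the resulting partial F (Type III for the group
    factor) has ``(k - 1, N - k - n_cov)`` degrees of freedom.  Zero-variance
    covariate columns are aliased with the intercept and are dropped, so with
    no informative covariates this reduces exactly to the one-way ANOVA F.

    Raises
    ------
    ValueError
        Missing covariate values, or a rank-deficient design (aliased columns
        are listed in the message).
    """
    y = np.asarray(values, dtype=float)
    groups = pd.Series(groups).reset_index(drop=True)
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    if y.shape != (len(groups),):
        raise ValueError("values and groups have different lengths")

    dummies = _group_dummies(groups)
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True).astype(float)
        if cov.isna().any().any():
            missing = cov.columns[cov.isna().any()].tolist()
            raise ValueError(f"missing covariate values in columns {missing}")
        cov = cov.loc[:, cov.nunique() > 1]  # constants alias the intercept
        cov_names = tuple(cov.columns)
    else:
        cov = pd.DataFrame(index=groups.index)
        cov_names = ()

    const = pd.DataFrame({"const": np.ones(len(groups))})
    full = pd.concat([const, dummies, cov], axis=1)
    _check_full_rank(full)
    reduced = pd.concat([const, cov], axis=1)

    fit_full = sm.OLS(y, full.to_numpy(dtype=float)).fit()
    fit_red = sm.OLS(y, reduced.to_numpy(dtype=float)).fit()
    df1 = dummies.shape[1]
    df2 = len(groups) - full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    if np.ptp(y) == 0 or fit_red.ssr - fit_full.ssr <= 0:
        # constant response, or the group factor adds nothing beyond the
        # covariates: no evidence of a group effect
        f, p = 0.0, 1.0
    elif fit_full.ssr == 0.0:  # group + covariates fit perfectly
        f, p = float("inf"), 0.0
    else:
        f = ((fit_red.ssr - fit_full.ssr) / df1) / (fit_full.ssr / df2)
        p = float(stats.f.sf(f, df1, df2))
    return ComparisonResult(
        measure=measure,
        statistic_name="F",
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_raw=p,
        covariates=cov_names,
        method="ancova" if cov_names else "anova",
    )


def oneway_anova(values, groups, measure: str = "value") -> ComparisonResult:
    """Classical one-way ANOVA with ``(k - 1, N - k)`` degrees of freedom."""
    groups = pd.Series(groups).reset_index(drop=True)
    y = np.asarray(values, dtype=float)
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [y[(groups == g).to_numpy()] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    f, p = stats.f_oneway(*samples)
    df = (float(len(levels) - 1), float(len(y) - len(levels)))
    return ComparisonResult(
        measure=measure, statistic_name="F", statistic=float(f), df=df,
        p_raw=float(p), method="anova",
    )


def chi_square_table(table, measure: str = "table") -> ComparisonResult:
    """Pearson chi-square on a contingency table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return ComparisonResult(
        measure=measure, statistic_name="chi2", statistic=float(chi2),
        df=(float(dof),), p_raw=float(p), method="pearson-chi2",
    )


def paired_compare(pos_strengths, neg_strengths, measure: str = "pos_vs_neg") -> ComparisonResult:
    """Two-sided paired t-test of positive vs negative network strength."""
    a = np.asarray(pos_strengths, dtype=float)
    b = np.asarray(neg_strengths, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if np.all(a == b):  # zero differences: t is 0 by convention, not 0/0
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(a, b)
        t, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        measure=measure, statistic_name="t", statistic=t,
        df=(float(a.size - 1),), p_raw=p, method="paired-t",
    )


# ---------------------------------------------------------------------------
# post hoc contrasts
# ---------------------------------------------------------------------------

def pairwise_posthoc(
    values,
    groups,
    pairs,
    method: str = "lsd",
    family_size: int | None = None,
) -> list[ComparisonResult]:
    """Pairwise group contrasts after an omnibus test.

    Methods
    -------
    ``"lsd"``
        Fisher's least significant difference: a t on the ANOVA pooled error
        term with ``N - k`` df, p unadjusted.
    ``"bonferroni"``
        The LSD t with p multiplied by ``family_size`` (defaults to the number
        of pairs tested here; pass the analysis-block family explicitly when
        the block spans several measures).
    ``"dunnett-t3"``
        Welch-type unequal-variance t with Welch-Satterthwaite df, referred to
        the studentized-range distribution over the number of groups
        (Games-Howell style), for use when variance homogeneity fails.
    """
    groups = pd.Series(groups).reset_index(drop=True)
    y = np.asarray(values, dtype=float)
    levels = list(groups.unique())
    by = {g: y[(groups == g).to_numpy()] for g in levels}
    for a, b in pairs:
        if a not in by or b not in by:
            raise ValueError(f"pair ({a}, {b}) uses a group not present in the data")
    if method not in ("lsd", "bonferroni", "dunnett-t3"):
        raise ValueError(f"unknown post hoc method {method!r}")
    if family_size is None:
        family_size = len(pairs)

    # pooled one-way error term for LSD / Bonferroni
    n_total = y.size
    k = len(levels)
    sse = sum(float(((by[g] - by[g].mean()) ** 2).sum()) for g in levels)
    mse = sse / (n_total - k)

    out = []
    for a, b in pairs:
        xa, xb = by[a], by[b]
        na, nb = xa.size, xb.size
        diff = xa.mean() - xb.mean()
        if method in ("lsd", "bonferroni"):
            se = np.sqrt(mse * (1 / na + 1 / nb))
            t = diff / se
            df = float(n_total - k)
            p = 2 * float(stats.t.sf(abs(t), df))
            p_adj = bonferroni(p, family_size) if method == "bonferroni" else p
        else:
            va, vb = xa.var(ddof=1) / na, xb.var(ddof=1) / nb
            se = np.sqrt(va + vb)
            t = diff / se
            df = float((va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1)))
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2), k, df))
            p = p_adj
        out.append(
            ComparisonResult(
                measure=f"{a}_vs_{b}", statistic_name="t", statistic=float(t),
                df=(df,), p_raw=float(p), p_adj=float(min(p_adj, 1.0)),
                method=method,
            )
        )
    return out


# ---------------------------------------------------------------------------
# node-level comparison with FDR
# ---------------------------------------------------------------------------

def node_group_anova(
    node_strengths: np.ndarray,
    groups,
    covariates: pd.DataFrame | None = None,
    q: float = 0.05,
):
    """Per-node covariate-adjusted group F-tests with Benjamini-Hochberg FDR.

    Parameters
    ----------
    node_strengths : (n_subjects, n_nodes) array
    groups, covariates : as in :func:`ancova_f`
    q : FDR level

    Returns
    -------
    significant : np.ndarray of node ids passing BH at level ``q``
    table : DataFrame with per-node F, raw p and BH-adjusted p
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    x = np.asarray(node_strengths, dtype=float)
    n_nodes = x.shape[1]
    results = [
        ancova_f(x[:, v], groups, covariates, measure=f"node_{v}")
        for v in range(n_nodes)
    ]
    p_raw = np.array([r.p_raw for r in results])
    reject, p_adj, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")
    table = pd.DataFrame(
        {
            "node_id": np.arange(n_nodes),
            "F": [r.statistic for r in results],
            "p_raw": p_raw,
            "p_fdr": p_adj,
            "significant": reject,
        }
    )
    return np.flatnonzero(reject), table
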