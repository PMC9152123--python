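"""End-to-end orchestration: CPM fit -> consensus networks -> strength
metrics -> covariate-adjusted group comparisons, with all intermediates
written as plain-text files.

The run is deterministic for a fixed configuration and seed; the report JSON
contains no timestamps, so a rerun is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cpm, group_stats, io, metrics
from .atlas import AtlasPartition

logger = logging.getLogger("cpmnet")

__all__ = ["PipelineConfig", "run_pipeline"]

#: Subnetwork-pair strength measures compared among groups, keyed by network
#: sign: the two pairs the positive network concentrates in and the three the
#: negative network concentrates in.  Together with the two network totals
#: they form the Bonferroni family of 7.
DEFAULT_PAIR_MEASURES = (
    ("positive", "DM", "Sa"),
    ("positive", "DM", "FT"),
    ("negative", "CT", "SH"),
    ("negative", "DM", "DM"),
    ("negative", "V", "V"),
)

COVARIATE_COLUMNS = ("age", "gender", "education_years", "mean_fd")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, thresholds and mode flags for one full pipeline run."""

    conn_dir: str
    phenotype_path: str
    partition_path: str
    out_dir: str
    threshold: float = cpm.DEFAULT_THRESHOLD
    n_perm: int = 1000
    seed: int = 0
    mode: str = "joint"                 # joint | separate linear model
    consensus: str = "intersection"     # intersection | union across folds
    absolute_strength: bool = False
    bonferroni_family: int = 7
    fdr_q: float = 0.05
    one_based_partition: bool = False
    pair_measures: tuple = DEFAULT_PAIR_MEASURES
    predict_group: str = "FES"

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.consensus not in ("intersection", "union"):
            raise ValueError("consensus must be 'intersection' or 'union'")
        for p in (self.conn_dir, self.phenotype_path, self.partition_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _echo_config(config: PipelineConfig) -> dict:
    d = dict(config.__dict__)
    d["pair_measures"] = [list(p) for p in config.pair_measures]
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run report (also written as
    ``report.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pheno = io.read_phenotypes(config.phenotype_path)
    partition = io.read_partition(
        config.partition_path, one_based=config.one_based_partition
    )
    connectomes = io.read_cohort_connectomes(config.conn_dir, pheno["subject_id"])
    n_nodes = connectomes.shape[1]
    if n_nodes != partition.n_nodes:
        raise ValueError(
            f"connectomes have {n_nodes} nodes but partition has {partition.n_nodes}"
        )
    iu = np.triu_indices(n_nodes, k=1)
    edge_matrix = connectomes[:, iu[0], iu[1]]
    logger.info("loaded %d subjects, %d nodes", len(pheno), n_nodes)

    # --- CPM on the symptomatic group -------------------------------------
    mask = (pheno["group"] == config.predict_group).to_numpy()
    if mask.sum() < 5:
        raise ValueError(
            f"group {config.predict_group!r} has {int(mask.sum())} subjects; "
            "need at least 5 for LOOCV"
        )
    scores = pheno.loc[mask, "score"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        bad = pheno.loc[mask & pheno["score"].isna(), "subject_id"].tolist()
        raise ValueError(f"missing symptom scores for subjects {bad}")
    fes_edges = edge_matrix[mask]

    fit = cpm.loocv(fes_edges, scores, threshold=config.threshold, mode=config.mode)
    logger.info("LOOCV accuracy r = %.4f over %d folds", fit.accuracy_r, fit.n_folds)
    perm = cpm.permutation_test(
        fes_edges, scores, threshold=config.threshold,
        n_perm=config.n_perm, seed=config.seed, mode=config.mode,
    )
    aggregate = (
        cpm.consensus_networks if config.consensus == "intersection"
        else cpm.consensus_union
    )
    consensus = aggregate(fit, fes_edges)
    logger.info(
        "consensus networks: %d positive, %d negative edges",
        consensus.positive.size, consensus.negative.size,
    )

    io.write_edge_list(out / "positive_network.tsv", consensus.positive,
                       consensus.positive_weights, partition, n_nodes)
    io.write_edge_list(out / "negative_network.tsv", consensus.negative,
                       consensus.negative_weights, partition, n_nodes)
    np.savetxt(out / "null_accuracy.tsv", perm.null_r, fmt=io.FLOAT_FORMAT)
    pd.DataFrame(
        {
            "subject_id": pheno.loc[mask, "subject_id"].to_numpy(),
            "observed": fit.observed_scores,
            "predicted": fit.predicted_scores,
        }
    ).to_csv(out / "predictions.tsv", sep="\t", index=False,
             float_format=io.FLOAT_FORMAT)

    # --- strength metrics over all subjects -------------------------------
    summaries = {}
    strength_rows = []
    networks = {"positive": consensus.positive, "negative": consensus.negative}
    for sign, edges in networks.items():
        totals = (
            metrics.network_strength(ev, edges, absolute=config.absolute_strength)
            for ev in edge_matrix
        )
        for sid, s in zip(pheno["subject_id"], totals):
            strength_rows.append(
                {"subject_id": sid, "measure": f"total_{sign}", "value": s}
            )
        if edges.size:
            summaries[sign] = metrics.subnetwork_summary(
                edge_matrix, edges, partition,
                subject_ids=pheno["subject_id"].tolist(),
                absolute=config.absolute_strength,
            )
    strengths = pd.DataFrame(strength_rows)
    strengths.to_csv(out / "network_strengths.tsv", sep="\t", index=False,
                     float_format=io.FLOAT_FORMAT)

    # --- group comparisons -------------------------------------------------
    covariates = pheno[list(COVARIATE_COLUMNS)]
    groups = pheno["group"]
    comparisons: list[group_stats.ComparisonResult] = []

    total_by_sign = {
        sign: strengths.query(f"measure == 'total_{sign}'")["value"].to_numpy()
        for sign in networks
    }
    for sign in networks:
        res = group_stats.ancova_f(
            total_by_sign[sign], groups, covariates, measure=f"total_{sign}"
        )
        comparisons.append(_with_bonferroni(res, config.bonferroni_family))

    for sign, a, b in config.pair_measures:
        summary = summaries.get(sign)
        if summary is None:
            continue
        pair_name = f"{sign}:{'-'.join(sorted((a, b)))}"
        tab = summary.pair_strengths
        pair_key = "-".join(sorted((a, b)))
        vals = tab.loc[tab["pair"] == pair_key]
        if vals.empty:  # pair not represented in this consensus network
            continue
        v = vals.set_index("subject_id").loc[pheno["subject_id"], "strength"].to_numpy()
        res = group_stats.ancova_f(v, groups, covariates, measure=pair_name)
        comparisons.append(_with_bonferroni(res, config.bonferroni_family))

    paired = {}
    for g in groups.unique():
        gm = (groups == g).to_numpy()
        res = group_stats.paired_compare(
            total_by_sign["positive"][gm], total_by_sign["negative"][gm],
            measure=f"pos_vs_neg_{g}",
        )
        comparisons.append(res)
        paired[str(g)] = {"t": res.statistic, "p": res.p_raw}

    # demographics, as in the cohort table
    comparisons.append(group_stats.oneway_anova(pheno["age"], groups, measure="age"))
    comparisons.append(
        group_stats.oneway_anova(pheno["education_years"], groups, measure="education_years")
    )
    comparisons.append(
        group_stats.oneway_anova(pheno["mean_fd"], groups, measure="mean_fd")
    )
    gender_table = pd.crosstab(pheno["gender"], groups).to_numpy()
    comparisons.append(group_stats.chi_square_table(gender_table, measure="gender"))

    comp_table = pd.DataFrame([c.to_row() for c in comparisons])
    comp_table.to_csv(out / "group_comparisons.tsv", sep="\t", index=False,
                      float_format=io.FLOAT_FORMAT)

    # node-level comparison on each consensus network
    node_results = {}
    for sign, edges in networks.items():
        if edges.size == 0:
            continue
        ns = np.stack(
            [metrics.node_strength(ev, edges, n_nodes=n_nodes,
                                   absolute=config.absolute_strength)
             for ev in edge_matrix]
        )
        sig, table = group_stats.node_group_anova(
            ns, groups, covariates, q=config.fdr_q
        )
        table.to_csv(out / f"node_anova_{sign}.tsv", sep="\t", index=False,
                     float_format=io.FLOAT_FORMAT)
        node_results[sign] = sig.tolist()

    # --- report ------------------------------------------------------------
    report = {
        "software_version": __version__,
        "seed": config.seed,
        "config": _echo_config(config),
        "n_subjects": int(len(pheno)),
        "n_nodes": int(n_nodes),
        "accuracy_r": fit.accuracy_r,
        "permutation_p": perm.p_value,
        "n_perm": perm.n_perm,
        "consensus_edges": {
            "positive": int(consensus.positive.size),
            "negative": int(consensus.negative.size),
        },
        "cross_within_pct": {
            sign: {"cross_pct": s.cross_pct, "within_pct": s.within_pct,
                   "cross": s.cross, "within": s.within}
            for sign, s in summaries.items()
        },
        "pair_counts": {
            sign: {
                f"{r.subnetwork_a}-{r.subnetwork_b}": {"n_edges": int(r.n_edges),
                                                       "pct": float(r.pct)}
                for r in s.pair_counts.itertuples()
            }
            for sign, s in summaries.items()
        },
        "paired_pos_vs_neg": paired,
        "significant_nodes_fdr": node_results,
    }
    io.write_report(out / "report.json", report)
    return report


def _with_bonferroni(res: group_stats.ComparisonResult, family: int):
    from dataclasses import replace

    return replace(
        res,
        p_adj=group_stats.bonferroni(res.p_raw, family),
        method=f"{res.method}+bonferroni(m={family})",
    )
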