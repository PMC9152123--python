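"""Synthetic cohorts with the statistical structure the CPM analysis assumes.

No resting-state fMRI data are deposited for the study this pipeline
emulates, so every downstream stage is exercised on generated cohorts: three
groups (first-episode schizophrenia FES, genetic high risk GHR, healthy
controls HC) with demographics drawn from the published group summaries, a
positive-symptom score for FES subjects, and per-subject Fisher-z connectomes
in which a small set of *planted* edges is linearly coupled to the symptom
score.  FES subjects additionally receive an additive connectivity deficit on
one designated subnetwork pair, mirroring the reported cingulo-opercular /
somatomotor finding.

The generator does not emulate BOLD time series, spatial autocorrelation or
head-motion artifacts; edges are independent Gaussians apart from the planted
couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import POWER264_SUBNETWORKS, AtlasPartition, edge_pair_label
from .connectome import devectorize, edge_keys, n_edges

__all__ = [
    "SCORE_RANGE",
    "GROUPS",
    "GROUP_REFERENCE",
    "SimulationConfig",
    "SyntheticCohort",
    "draw_scores",
    "generate_partition",
    "generate_cohort",
]

#: Valid range of the positive-symptom subscale total (7 items scored 1-7).
SCORE_RANGE = (7.0, 49.0)

GROUPS = ("FES", "GHR", "HC")

#: Published per-group demographics: (mean, sd) for age / education / mean FD,
#: and the male proportion, in group order FES, GHR, HC.
GROUP_REFERENCE: Mapping[str, Mapping[str, tuple[float, float] | float]] = {
    "FES": {"age": (20.81, 5.66), "education_years": (11.91, 3.00),
            "mean_fd": (0.068, 0.04), "male_prop": 23 / 45},
    "GHR": {"age": (19.95, 4.84), "education_years": (11.73, 3.23),
            "mean_fd": (0.06, 0.04), "male_prop": 23 / 41},
    "HC": {"age": (20.02, 4.67), "education_years": (13.64, 3.05),
           "mean_fd": (0.06, 0.03), "male_prop": 29 / 48},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_nodes : int
        Atlas size; 264 matches the Power-264 parcellation.
    n_per_group : mapping
        Subjects per group; defaults are the published 45/41/48.
    score_mean, score_sd : float
        Positive-symptom score distribution for FES subjects (22.24 +/- 6.86),
        sampled Normal then clipped to the instrument range [7, 49].
    n_signal_pos, n_signal_neg : int
        Planted edges positively / negatively coupled to the score.
    effect_size : float
        Fisher-z shift per SD of symptom score on each planted edge.  With the
        default ``noise_sd`` of 0.3 the default 0.15 yields a per-edge
        population edge-score correlation of about 0.45.
    group_deficit_pair : (str, str)
        Subnetwork pair whose edges receive ``group_deficit_shift`` in FES
        subjects only (default CT-SH, i.e. cingulo-opercular task control to
        sensory/somatomotor hand).
    noise_sd : float
        SD of the independent Gaussian edge noise, Fisher-z units.
    seed : int
        Master seed; see Notes on the substream scheme.

    Notes
    -----
    Randomness is split into per-purpose substreams of one master
    ``numpy.random.SeedSequence``: spawn key ``(0,)`` places the planted
    edges, ``(1,)`` draws the node partition, and ``(2, g, j)`` drives every
    draw belonging to subject ``j`` of group ``g`` (score, covariates, edge
    noise).  Adding subjects to any group therefore never reshuffles draws
    for existing subjects.
    """

    n_nodes: int = 264
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"FES": 45, "GHR": 41, "HC": 48}
    )
    score_mean: float = 22.24
    score_sd: float = 6.86
    n_signal_pos: int = 10
    n_signal_neg: int = 10
    effect_size: float = 0.15
    group_deficit_pair: tuple[str, str] = ("CT", "SH")
    group_deficit_shift: float = -0.12
    noise_sd: float = 0.3
    seed: int = 0
    subnetwork_labels: tuple[str, ...] = POWER264_SUBNETWORKS

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n <= 0:
                raise ValueError(f"group {g} has non-positive size {n}")
        if self.score_sd <= 0:
            raise ValueError("score_sd must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_signal_pos < 0 or self.n_signal_neg < 0:
            raise ValueError("planted edge counts must be non-negative")
        if self.n_signal_pos + self.n_signal_neg > n_edges(self.n_nodes):
            raise ValueError(
                f"{self.n_signal_pos + self.n_signal_neg} planted edges exceed the "
                f"{n_edges(self.n_nodes)} available at N={self.n_nodes}"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort: phenotypes, connectomes, partition and ground truth.

    ``cohort`` rows align with ``connectomes`` (subject ``k`` is row ``k`` and
    ``connectomes[k]``).  ``truth`` records the planted positive/negative edge
    indices (canonical upper-triangle order), the effect size, and the edges
    carrying the FES group deficit.
    """

    cohort: pd.DataFrame
    connectomes: np.ndarray
    partition: AtlasPartition
    truth: dict

    def __post_init__(self) -> None:
        if self.connectomes.shape[0] != len(self.cohort):
            raise ValueError("connectome count does not match cohort rows")

    @property
    def edge_matrix(self) -> np.ndarray:
        """(n_subjects, n_edges) matrix of upper-triangle edge vectors."""
        n = self.connectomes.shape[1]
        iu = np.triu_indices(n, k=1)
        return self.connectomes[:, iu[0], iu[1]]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.cohort["group"] == group).to_numpy()


def draw_scores(
    n: int,
    mean: float,
    sd: float,
    rng: np.random.Generator,
    clip: bool = True,
) -> np.ndarray:
    """Sample symptom scores ``Normal(mean, sd^2)``, optionally clipped to [7, 49]."""
    scores = rng.normal(mean, sd, size=n)
    if clip:
        scores = np.clip(scores, *SCORE_RANGE)
    return scores


def generate_partition(
    n_nodes: int,
    labels=POWER264_SUBNETWORKS,
    proportions=None,
    seed: int | np.random.Generator = 0,
) -> AtlasPartition:
    """Random node-to-subnetwork partition with given label proportions.

    Label counts are the proportions scaled to ``n_nodes`` and rounded by
    largest remainder so they sum exactly to ``n_nodes``; the assignment is
    then shuffled.  Equal proportions by default.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("label list must be non-empty")
    if len(labels) > n_nodes:
        raise ValueError(f"{len(labels)} labels exceed {n_nodes} nodes")
    if proportions is None:
        proportions = np.full(len(labels), 1.0 / len(labels))
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size != len(labels) or np.any(proportions < 0):
        raise ValueError("proportions must be non-negative, one per label")
    if not np.isclose(proportions.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    raw = proportions * n_nodes
    counts = np.floor(raw).astype(int)
    remainder = n_nodes - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    assignment = np.repeat(np.asarray(labels, dtype=object), counts)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rng.shuffle(assignment)
    return AtlasPartition(labels=assignment)


def _subject_rng(seed: int, group_idx: int, j: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(2, group_idx, j))
    )


def generate_cohort(
    config: SimulationConfig,
    partition: AtlasPartition | None = None,
) -> SyntheticCohort:
    """Generate one cohort under ``config``.

    Non-planted edges are independent ``Normal(0, noise_sd^2)`` in Fisher-z
    units (baseline mean 0: the CPM screen is per-edge correlation, so only
    relative structure matters).  For an FES subject with standardized score
    ``z``, a planted edge has weight ``sign * effect_size * z + noise``; the
    coupling is zero for GHR/HC subjects, who have no symptom score.  FES
    subjects additionally receive ``group_deficit_shift`` on every edge of
    ``group_deficit_pair``.
    """
    config.validate()
    n_nodes = config.n_nodes
    n_edge = n_edges(n_nodes)

    place_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    chosen = place_rng.permutation(n_edge)[: config.n_signal_pos + config.n_signal_neg]
    pos_idx = np.sort(chosen[: config.n_signal_pos])
    neg_idx = np.sort(chosen[config.n_signal_pos :])

    if partition is None:
        part_rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(1,))
        )
        partition = generate_partition(
            n_nodes, labels=config.subnetwork_labels, seed=part_rng
        )
    elif partition.n_nodes != n_nodes:
        raise ValueError("partition size does not match n_nodes")

    keys = edge_keys(n_nodes)
    pair = tuple(sorted(config.group_deficit_pair))
    deficit_idx = np.flatnonzero(
        [edge_pair_label((i, j), partition) == pair for i, j in keys]
    )

    rows = []
    matrices = []
    k = 0
    for group_idx, group in enumerate(GROUPS):
        ref = GROUP_REFERENCE[group]
        for j in range(int(config.n_per_group.get(group, 0))):
            rng = _subject_rng(config.seed, group_idx, j)
            score = (
                float(draw_scores(1, config.score_mean, config.score_sd, rng)[0])
                if group == "FES"
                else np.nan
            )
            age = rng.normal(*ref["age"])
            gender = int(rng.random() < ref["male_prop"])
            edu = rng.normal(*ref["education_years"])
            fd = max(rng.normal(*ref["mean_fd"]), 1e-3)  # FD is non-negative

            edge_vec = rng.normal(0.0, config.noise_sd, n_edge)
            if group == "FES":
                z = (score - config.score_mean) / config.score_sd
                edge_vec[pos_idx] += config.effect_size * z
                edge_vec[neg_idx] -= config.effect_size * z
                edge_vec[deficit_idx] += config.group_deficit_shift
            matrices.append(devectorize(edge_vec, n_nodes))
            rows.append(
                {
                    "subject_id": f"{group}{k:03d}",
                    "group": group,
                    "score": score,
                    "age": age,
                    "gender": gender,
                    "education_years": edu,
                    "mean_fd": fd,
                }
            )
            k += 1

    cohort = pd.DataFrame(rows)
    truth = {
        "positive_edges": pos_idx.tolist(),
        "negative_edges": neg_idx.tolist(),
        "effect_size": config.effect_size,
        "group_deficit_pair": list(pair),
        "group_deficit_shift": config.group_deficit_shift,
        "group_deficit_edges": deficit_idx.tolist(),
    }
    return SyntheticCohort(
        cohort=cohort,
        connectomes=np.stack(matrices),
        partition=partition,
        truth=truth,
    )
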