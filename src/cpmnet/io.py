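"""Plain-text readers and writers for every on-disk artifact.

All numeric text is written at 12 significant digits, which round-trips the
values the pipeline compares while keeping diffs stable.  Readers validate
eagerly and report the offending column or line.  No function here mutates
its input files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasPartition
from .connectome import edge_keys, validate_connectome

__all__ = [
    "FLOAT_FORMAT",
    "PHENOTYPE_COLUMNS",
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "read_phenotypes",
    "write_phenotypes",
    "read_partition",
    "write_partition",
    "write_edge_list",
    "write_report",
    "read_report",
    "write_cohort",
    "read_cohort_connectomes",
]

FLOAT_FORMAT = "%.12g"

PHENOTYPE_COLUMNS = (
    "subject_id", "group", "score", "age", "gender", "education_years", "mean_fd",
)


def write_matrix(path, matrix: np.ndarray) -> None:
    """Write a square matrix as TSV at 12 significant digits."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt=FLOAT_FORMAT, delimiter="\t")


def read_matrix(path, validate: bool = True) -> np.ndarray:
    """Read a delimited square matrix; optionally check connectome invariants."""
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    if validate:
        try:
            m = validate_connectome(m)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return m


def read_timeseries(path, header: bool = False) -> np.ndarray:
    """Read a T x N time-series matrix (one region per column)."""
    return np.loadtxt(path, delimiter="\t", skiprows=1 if header else 0, ndmin=2)


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype TSV, checking required columns and types."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table is missing column(s) {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dupes}")
    return df


def write_phenotypes(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_partition(path, one_based: bool = False) -> AtlasPartition:
    """Read a partition CSV (``node_id,subnetwork[,x,y,z]``).

    ``one_based=True`` shifts incoming node ids down by one (the Power-264
    convention numbers nodes from 1).
    """
    df = pd.read_csv(path)
    for col in ("node_id", "subnetwork"):
        if col not in df.columns:
            raise ValueError(f"{path}: partition file is missing column {col!r}")
    ids = df["node_id"].to_numpy(dtype=int) - (1 if one_based else 0)
    n = len(ids)
    if sorted(ids) != list(range(n)):
        raise ValueError(f"{path}: node ids must be 0..{n - 1} with no gaps "
                         f"(use one_based=True for 1-based files)")
    order = np.argsort(ids)
    labels = df["subnetwork"].to_numpy(dtype=object)[order]
    coords = None
    if {"x", "y", "z"} <= set(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)[order]
    return AtlasPartition(labels=labels, coords=coords)


def write_partition(path, partition: AtlasPartition, one_based: bool = False) -> None:
    df = pd.DataFrame(
        {
            "node_id": np.arange(partition.n_nodes) + (1 if one_based else 0),
            "subnetwork": partition.labels,
        }
    )
    if partition.coords is not None:
        df[["x", "y", "z"]] = partition.coords
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_edge_list(
    path,
    edge_indices: np.ndarray,
    weights: np.ndarray,
    partition: AtlasPartition | None,
    n_nodes: int,
) -> None:
    """Write a consensus network as a TSV edge list in canonical order."""
    keys = edge_keys(n_nodes)[np.asarray(edge_indices, dtype=int)]
    df = pd.DataFrame(
        {
            "node_i": keys[:, 0] if len(keys) else [],
            "node_j": keys[:, 1] if len(keys) else [],
        }
    )
    if partition is not None:
        df["subnetwork_i"] = [partition.label_of(i) for i in df["node_i"]]
        df["subnetwork_j"] = [partition.label_of(j) for j in df["node_j"]]
    df["weight"] = np.asarray(weights, dtype=float)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# cohort directory layout
# ---------------------------------------------------------------------------

def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort to a directory.

    Layout: ``<subject_id>.tsv`` square matrices, ``phenotypes.tsv``,
    ``partition.csv`` and ``truth.json`` (planted edges).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, mat in zip(cohort.cohort["subject_id"], cohort.connectomes):
        write_matrix(out / f"{sid}.tsv", mat)
    write_phenotypes(out / "phenotypes.tsv", cohort.cohort)
    write_partition(out / "partition.csv", cohort.partition)
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2) + "\n")
    return out


def read_cohort_connectomes(conn_dir, subject_ids) -> np.ndarray:
    """Load ``<subject_id>.tsv`` matrices for the listed subjects, in order.

    Raises
    ------
    FileNotFoundError
        Listing every subject id with no matrix file.
    """
    conn_dir = Path(conn_dir)
    missing = [sid for sid in subject_ids if not (conn_dir / f"{sid}.tsv").exists()]
    if missing:
        raise FileNotFoundError(
            f"no connectome file in {conn_dir} for subject(s): {missing}"
        )
    return np.stack([read_matrix(conn_dir / f"{sid}.tsv") for sid in subject_ids])
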