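"""TSV readers/writers for matrices, partitions, manifests.

Dialect: UTF-8, tab-separated, header row; matrices carry labels in the
first row and first column. Numbers are written with ``repr`` so a
write -> read round trip reproduces values to full double precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import COVARIATE_NAMES, NuisanceSet, SubjectRecord
from .datatypes import ModularPartition, ParcelTimeSeries


def write_matrix_tsv(
    path: str | Path,
    values: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
) -> Path:
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != (len(row_labels), len(col_labels)):
        raise ValueError("label counts do not match matrix shape")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(col_labels) + "\n")
        for lab, row in zip(row_labels, values):
            fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (values, row_labels, col_labels); raises with row/column
    context on malformed cells."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    col_labels = lines[0].split("\t")[1:]
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(col_labels) + 1:
            raise ValueError(
                f"{path}:{lineno}: expected {len(col_labels) + 1} fields, got {len(parts)}"
            )
        row_labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    return np.array(rows), row_labels, col_labels


def write_square_matrix(path: str | Path, values: np.ndarray, labels: Sequence[str]) -> Path:
    return write_matrix_tsv(path, values, labels, labels)


def read_square_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    values, row_labels, col_labels = read_matrix_tsv(path)
    if row_labels != col_labels:
        raise ValueError(f"{path}: row and column labels differ")
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: matrix is not square")
    return values, row_labels


def write_partition(path: str | Path, partition: ModularPartition) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("node\tmodule\n")
        for node, mod in zip(partition.node_labels, partition.labels):
            fh.write(f"{node}\t{int(mod)}\n")
    return path


def read_partition(path: str | Path) -> ModularPartition:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["node", "module"]:
        raise ValueError(f"{path}: expected columns node, module")
    return ModularPartition(
        labels=df["module"].to_numpy(int), node_labels=df["node"].astype(str).tolist()
    )


def read_series_tsv(path: str | Path, tr_seconds: float) -> ParcelTimeSeries:
    values, _, col_labels = read_matrix_tsv(path)
    return ParcelTimeSeries(values, col_labels, tr_seconds)


def read_nuisance_tsv(path: str | Path) -> NuisanceSet:
    values, _, col_labels = read_matrix_tsv(path)
    return NuisanceSet(values, col_labels)


def read_manifest(
    manifest_path: str | Path, tr_seconds: float = 2.5
) -> list[SubjectRecord]:
    """Load a cohort written by :func:`rsnet.cohort.write_cohort`.

    Expects manifest.tsv plus covariates.tsv in the same directory; raises
    naming the subject and path when a referenced file is missing.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    man = pd.read_csv(manifest_path, sep="\t")
    cov = pd.read_csv(base / "covariates.tsv", sep="\t")
    cov = cov.set_index(["subject_id", "phase"])
    records = []
    for _, row in man.iterrows():
        spath = base / row["series_path"]
        if not spath.exists():
            raise FileNotFoundError(
                f"subject {row['subject_id']} ({row['phase']}): missing series file {spath}"
            )
        series = read_series_tsv(spath, tr_seconds)
        npath = base / row["nuisance_path"]
        if not npath.exists():
            raise FileNotFoundError(
                f"subject {row['subject_id']} ({row['phase']}): missing nuisance file {npath}"
            )
        nuis = read_nuisance_tsv(npath)
        crow = cov.loc[(row["subject_id"], row["phase"])]
        covariates = {c: float(crow[c]) for c in COVARIATE_NAMES}
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                phase=str(row["phase"]),
                covariates=covariates,
                series=series,
                nuisance=nuis,
            )
        )
    return records
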