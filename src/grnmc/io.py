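"""File formats: expression matrices, label files, and JSON model archives.

Matrices are CSV/TSV with the first column holding sample ids and the header
row holding gene ids (samples x genes orientation; a transpose flag covers
genes x samples exports).  Model archives are JSON -- human-inspectable and
diff-able -- and round-trip predictions bit-exactly because JSON doubles
round-trip exactly through Python floats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    ClassifierCoefficients,
    ClassLabels,
    ExpressionData,
    Hyperparameters,
    NetworkCoefficients,
)
from .optimizer import FitResult, Standardizer

_ARCHIVE_VERSION = 1


def _delimiter(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_matrix(path, transpose: bool = False) -> pd.DataFrame:
    """Numeric matrix with sample ids as index and gene ids as columns."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_delimiter(path))[1:]
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    df.index = df.index.map(str)
    df.columns = header  # undo pandas' silent renaming of duplicates
    if transpose:
        df = df.T
    df.columns = df.columns.map(str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing cell in {path} at sample "
            f"{df.index[r]!r}, gene {df.columns[c]!r}"
        )
    return numeric.astype(float)


def read_expression(
    path, targets_path=None, transpose: bool = False
) -> ExpressionData:
    """Load regulator (and optionally separate target) expression.

    Without ``targets_path`` the matrix is used as both regulators and
    targets (the square case).  Sample rows of the target file are aligned to
    the regulator file by id.
    """
    X = read_matrix(path, transpose=transpose)
    if targets_path is None:
        return ExpressionData(
            X.to_numpy(), X.to_numpy(), list(X.columns), list(X.columns)
        )
    Y = read_matrix(targets_path, transpose=transpose)
    missing = [s for s in X.index if s not in Y.index]
    if missing:
        raise ValueError(f"samples missing from target matrix: {missing[:5]}")
    Y = Y.loc[X.index]
    return ExpressionData(
        X.to_numpy(), Y.to_numpy(), list(X.columns), list(Y.columns)
    )


def read_labels(path, sample_ids) -> ClassLabels:
    """Two-column file (sample id, class label), aligned to ``sample_ids``."""
    df = pd.read_csv(path, sep=_delimiter(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("label file must have two columns: sample id, class")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [s for s in sample_ids if str(s) not in mapping]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    return ClassLabels.from_labels([mapping[str(s)] for s in sample_ids])


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_delimiter(path))


def save_model(result: FitResult, path) -> None:
    """Serialize a fitted model to a JSON archive."""
    std = result.standardizer
    payload = {
        "format_version": _ARCHIVE_VERSION,
        "B": result.B.B.tolist(),
        "theta0": result.coef.theta0.tolist(),
        "Theta": result.coef.Theta.tolist(),
        "lambdas": vars(result.lambdas),
        "regulator_ids": result.regulator_ids,
        "target_ids": result.target_ids,
        "class_names": result.class_names,
        "standardizer": None
        if std is None
        else {
            "x_mean": std.x_mean.tolist(),
            "x_scale": std.x_scale.tolist(),
            "y_mean": std.y_mean.tolist(),
            "y_scale": std.y_scale.tolist(),
        },
        "objective_trace": list(map(float, result.objective_trace)),
        "converged": bool(result.converged),
        "diverged": bool(result.diverged),
        "n_cycles": int(result.n_cycles),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _ARCHIVE_VERSION:
        raise ValueError("unrecognized model archive version")
    std = payload["standardizer"]
    return FitResult(
        B=NetworkCoefficients(np.array(payload["B"], dtype=float)),
        coef=ClassifierCoefficients(
            np.array(payload["theta0"], dtype=float),
            np.array(payload["Theta"], dtype=float),
        ),
        lambdas=Hyperparameters(**payload["lambdas"]),
        objective_trace=payload["objective_trace"],
        converged=payload["converged"],
        diverged=payload["diverged"],
        n_cycles=payload["n_cycles"],
        standardizer=None
        if std is None
        else Standardizer(
            np.array(std["x_mean"]), np.array(std["x_scale"]),
            np.array(std["y_mean"]), np.array(std["y_scale"]),
        ),
        regulator_ids=payload["regulator_ids"],
        target_ids=payload["target_ids"],
        class_names=payload["class_names"],
    )
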