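"""BIC-based selection of the regularization parameters on a validation split.

The criterion is the validation deviance of the training-set fit plus a
degrees-of-freedom charge,

    BIC = -2 * loglik(validation; B^tr, Theta^tr, theta0^tr) + log(n_vl) * df,

with df = the number of nonzero entries of the fitted classifier matrix
Theta (entries with |theta| < 1e-8 count as zero; network coefficients are
not charged).  Every grid point is fit on the training split from the common
cold initialization and scored on the validation split; ties are broken
toward the larger total penalty (the sparser model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, NamedTuple

import numpy as np

from .core_model import (
    ClassLabels,
    ExpressionData,
    Hyperparameters,
    log_likelihood,
)
from .optimizer import FitConfig, FitResult, fit

ZERO_TOL = 1e-8

DEFAULT_GRID = {
    "lambda1": [0.01, 0.05, 0.1, 0.5, 1.0],
    "lambda2": [0.0, 0.1, 1.0],
    "lambda3": [0.01, 0.05, 0.1, 0.5, 1.0],
    "lambda4": [0.0, 0.1, 1.0],
}


class SelectionError(RuntimeError):
    pass


class BIC(NamedTuple):
    """BIC value with its exact decomposition (deviance + log(n_vl) * df)."""

    value: float
    deviance: float
    df: int

    def __float__(self):
        return self.value


@dataclass
class SelectionGrid:
    """Candidate values per regularization parameter, plus an optional split.

    With ``per_sample=True`` grid values are interpreted as per-observation
    penalty strengths and the lambda handed to the optimizer is
    ``value * n_train`` (the loss is a sum over samples, so penalties that
    track n keep one grid meaningful across sample sizes and can reach the
    all-zero end of the path).  The default passes values through unscaled.
    """

    lambda1: list[float] = field(default_factory=lambda: list(DEFAULT_GRID["lambda1"]))
    lambda2: list[float] = field(default_factory=lambda: list(DEFAULT_GRID["lambda2"]))
    lambda3: list[float] = field(default_factory=lambda: list(DEFAULT_GRID["lambda3"]))
    lambda4: list[float] = field(default_factory=lambda: list(DEFAULT_GRID["lambda4"]))
    per_sample: bool = False
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "lambda4"):
            vals = [float(v) for v in getattr(self, name)]
            if not vals:
                raise ValueError(f"empty grid for {name}")
            if any(v < 0 for v in vals):
                raise ValueError(f"negative value in grid for {name}")
            setattr(self, name, vals)
        if (self.train_idx is None) != (self.val_idx is None):
            raise ValueError("provide both train_idx and val_idx, or neither")
        if self.train_idx is not None:
            tr = set(np.asarray(self.train_idx).tolist())
            vl = set(np.asarray(self.val_idx).tolist())
            if tr & vl:
                raise ValueError("train and validation indices overlap")

    def points(self, n_train: int | None = None):
        scale = float(n_train) if (self.per_sample and n_train) else 1.0
        return [
            Hyperparameters(*(scale * v for v in combo))
            for combo in product(self.lambda1, self.lambda2, self.lambda3, self.lambda4)
        ]

    @classmethod
    def from_file(cls, path) -> "SelectionGrid":
        """Key-value config: one `lambdaN = v1, v2, ...` line per parameter."""
        values = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                key, _, rhs = line.partition("=")
                key = key.strip()
                if key not in ("lambda1", "lambda2", "lambda3", "lambda4"):
                    raise ValueError(f"unknown grid key: {key!r}")
                values[key] = [float(v) for v in rhs.replace(",", " ").split()]
        return cls(**values)


def degrees_of_freedom(fitted: FitResult, tol: float = ZERO_TOL) -> int:
    """Number of nonzero classifier coefficients (the df of the model)."""
    return int(np.sum(np.abs(fitted.coef.Theta) > tol))


def bic(
    validation_data: ExpressionData,
    validation_labels: ClassLabels,
    fitted: FitResult,
) -> BIC:
    """Validation BIC of a training-set fit; see the module docstring."""
    if validation_data.n == 0:
        raise ValueError("empty validation set")
    X_vl = validation_data.X
    if fitted.standardizer is not None:
        X_vl = fitted.standardizer.transform_x(X_vl)
    sdata = ExpressionData(X_vl, np.zeros((X_vl.shape[0], fitted.B.k)))
    ll = log_likelihood(sdata, validation_labels, fitted.B, fitted.coef)
    df = degrees_of_freedom(fitted)
    deviance = -2.0 * ll
    return BIC(value=deviance + np.log(validation_data.n) * df, deviance=deviance, df=df)


def stratified_split(y: np.ndarray, fractions, rng) -> list[np.ndarray]:
    """Split sample indices into parts with per-class proportional allocation.

    Guarantees every class at least one sample in every part (requires each
    class to have >= len(fractions) members).  Part sizes match
    round(n * fraction) globally via largest-remainder allocation per class.
    """
    y = np.asarray(y)
    n = len(y)
    n_parts = len(fractions)
    classes = np.unique(y)
    # per-class largest-remainder allocation, each part >= 1 per class
    raw = np.zeros((len(classes), n_parts))
    counts = np.zeros((len(classes), n_parts), dtype=int)
    shuffled = {}
    for ci, cls in enumerate(classes):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        shuffled[ci] = idx
        n_c = len(idx)
        if n_c < n_parts:
            raise ValueError(
                f"class {cls} has only {n_c} samples; cannot fill {n_parts} parts"
            )
        raw[ci] = np.array([f * n_c for f in fractions])
        counts[ci] = np.maximum(np.floor(raw[ci]).astype(int), 1)
        while counts[ci].sum() < n_c:
            counts[ci, np.argmax(raw[ci] - counts[ci])] += 1
        while counts[ci].sum() > n_c:
            over = np.flatnonzero(counts[ci] > 1)
            counts[ci, over[np.argmin((raw[ci] - counts[ci])[over])]] -= 1
    # rebalance so part totals hit the largest-remainder rounding of n * f
    target = np.floor(np.array(fractions) * n).astype(int)
    while target.sum() < n:
        target[np.argmax(np.array(fractions) * n - target)] += 1
    for _ in range(n):
        totals = counts.sum(axis=0)
        if np.array_equal(totals, target):
            break
        p_over = int(np.argmax(totals - target))
        p_under = int(np.argmin(totals - target))
        movable = np.flatnonzero(counts[:, p_over] > 1)
        ci = int(movable[np.argmin((raw - counts)[movable, p_over])])
        counts[ci, p_over] -= 1
        counts[ci, p_under] += 1
    parts = [[] for _ in range(n_parts)]
    for ci in range(len(classes)):
        start = 0
        for pi in range(n_parts):
            parts[pi].extend(shuffled[ci][start : start + counts[ci, pi]].tolist())
            start += counts[ci, pi]
    return [np.sort(np.array(part)) for part in parts]


def select(
    data: ExpressionData,
    labels: ClassLabels,
    grid: SelectionGrid | None = None,
    config: FitConfig | None = None,
    fitter: Callable[..., FitResult] = fit,
) -> tuple[Hyperparameters, FitResult]:
    """Fit every grid point on the training split, return the BIC argmin.

    If the grid carries no split, a stratified 8:1 train/validation carve-out
    is drawn with the config seed.  ``fitter`` allows the pre-estimated
    network baseline to reuse the same selection machinery.
    """
    if grid is None:
        grid = SelectionGrid()
    if config is None:
        config = FitConfig()
    if grid.train_idx is None:
        rng = np.random.default_rng(config.seed)
        tr, vl = stratified_split(labels.y, (8 / 9, 1 / 9), rng)
    else:
        tr, vl = np.asarray(grid.train_idx), np.asarray(grid.val_idx)
    data_tr, labels_tr = data.subset(tr), labels.subset(tr)
    data_vl, labels_vl = data.subset(vl), labels.subset(vl)

    best = None  # (bic_value, total_penalty, lambdas, fitted)
    failures = []
    for lam in grid.points(n_train=data_tr.n):
        try:
            fitted = fitter(data_tr, labels_tr, lam, config)
            crit = bic(data_vl, labels_vl, fitted)
        except Exception as exc:  # recorded, not fatal unless all fail
            failures.append((lam, repr(exc)))
            continue
        key = (crit.value, -lam.total())
        if best is None or key < (best[0], -best[1]):
            best = (crit.value, lam.total(), lam, fitted)
    if best is None:
        lines = "\n".join(f"  {lam}: {err}" for lam, err in failures)
        raise SelectionError(f"all grid points failed to fit:\n{lines}")
    return best[2], best[3]
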