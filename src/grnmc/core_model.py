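"""Data containers and the pure mathematics of the network-based classifier.

The model couples two pieces.  A linear gene-regulatory model predicts each
target gene j from the expression of p regulator genes,

    y_ij = x_i' beta_j + eps_ij,

collecting the per-target coefficient vectors as the columns of the p x k
network matrix B.  A multinomial logistic (softmax) classifier then uses the
network-transformed expression x_i' B as its feature vector,

    Pr(Z_i = g) = pi_g(x_i, B)
                = exp(theta_g0 + x_i' B theta_g) / sum_h exp(theta_h0 + x_i' B theta_h).

The joint objective minimized by the fitting engine is

    -loglik + (1/2) ||Y - XB||_F^2
    + lam1 sum_j ||beta_j||_1 + (lam2/2) sum_j ||beta_j||_2^2
    + lam3 sum_g ||theta_g||_1 + (lam4/2) sum_g theta_g' L^s_g theta_g,

where L^s_g is the sign-adjusted normalized Laplacian of the graph induced by
the current network estimate (see :mod:`grnmc.graph_penalty`).  This module
holds only the evaluation of these quantities; optimization lives in
:mod:`grnmc.optimizer`.

All G classifier rows are estimated (no reference class); the penalties
resolve the softmax shift non-identifiability, as is standard in penalized
multinomial fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

# probabilities are clipped into this range before any division or log
PROB_CLIP = 1e-10


def _as_float_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class ExpressionData:
    """Expression of p regulator genes (X) and k target genes (Y), n samples.

    The regulator and target gene sets may coincide (square case, p = k,
    identical identifiers) -- that is the intended configuration for real
    expression matrices, where every gene is both a potential regulator and a
    target.  The simulation scenarios use disjoint sets (TFs vs regulated
    genes).
    """

    X: np.ndarray
    Y: np.ndarray
    regulator_ids: list[str] = field(default=None)
    target_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.X = _as_float_matrix(self.X, "X")
        self.Y = _as_float_matrix(self.Y, "Y")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X and Y disagree on sample count: {self.X.shape[0]} vs {self.Y.shape[0]}"
            )
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if self.X.shape[1] < 1 or self.Y.shape[1] < 1:
            raise ValueError("need at least one regulator and one target gene")
        if self.regulator_ids is None:
            self.regulator_ids = [f"reg{l + 1}" for l in range(self.X.shape[1])]
        if self.target_ids is None:
            self.target_ids = [f"tgt{j + 1}" for j in range(self.Y.shape[1])]
        self.regulator_ids = list(map(str, self.regulator_ids))
        self.target_ids = list(map(str, self.target_ids))
        if len(self.regulator_ids) != self.X.shape[1]:
            raise ValueError("regulator_ids length does not match X")
        if len(self.target_ids) != self.Y.shape[1]:
            raise ValueError("target_ids length does not match Y")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return self.Y.shape[1]

    @property
    def is_square(self) -> bool:
        """True when regulators and targets are the same gene set, in order."""
        return self.p == self.k and self.regulator_ids == self.target_ids

    def subset(self, idx) -> "ExpressionData":
        idx = np.asarray(idx)
        return ExpressionData(
            self.X[idx], self.Y[idx], self.regulator_ids, self.target_ids
        )


@dataclass
class ClassLabels:
    """One-hot class membership: Z[i, g] = 1 iff sample i is in class g."""

    Z: np.ndarray
    class_names: list[str] = field(default=None)

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError("Z must be an n x G indicator matrix")
        if self.Z.shape[1] < 2:
            raise ValueError("need at least 2 classes")
        if not np.all(np.isin(self.Z, (0.0, 1.0))) or not np.allclose(
            self.Z.sum(axis=1), 1.0
        ):
            raise ValueError("each row of Z must be a one-hot indicator")
        if self.class_names is None:
            self.class_names = [f"class{g + 1}" for g in range(self.Z.shape[1])]
        self.class_names = list(map(str, self.class_names))
        if len(self.class_names) != self.Z.shape[1]:
            raise ValueError("class_names length does not match Z")

    @classmethod
    def from_labels(cls, labels, class_names=None) -> "ClassLabels":
        labels = np.asarray(labels)
        if class_names is None:
            class_names = sorted(map(str, np.unique(labels).tolist()))
        name_to_col = {c: g for g, c in enumerate(class_names)}
        Z = np.zeros((len(labels), len(class_names)))
        for i, lab in enumerate(labels):
            Z[i, name_to_col[str(lab)]] = 1.0
        return cls(Z, list(class_names))

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def G(self) -> int:
        return self.Z.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Integer class index per sample."""
        return np.argmax(self.Z, axis=1)

    def subset(self, idx) -> "ClassLabels":
        return ClassLabels(self.Z[np.asarray(idx)], self.class_names)


@dataclass
class NetworkCoefficients:
    """The p x k regulator->target effect matrix B; column j is beta_j."""

    B: np.ndarray

    def __post_init__(self):
        self.B = _as_float_matrix(self.B, "B")

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def k(self) -> int:
        return self.B.shape[1]


@dataclass
class ClassifierCoefficients:
    """Per-class intercepts theta_g0 and coefficient rows theta_g (G x k)."""

    theta0: np.ndarray
    Theta: np.ndarray

    def __post_init__(self):
        self.theta0 = np.asarray(self.theta0, dtype=float).ravel()
        self.Theta = _as_float_matrix(self.Theta, "Theta")
        if self.theta0.shape[0] != self.Theta.shape[0]:
            raise ValueError("theta0 and Theta disagree on the number of classes")
        if not np.all(np.isfinite(self.theta0)):
            raise ValueError("theta0 contains non-finite values")

    @property
    def G(self) -> int:
        return self.Theta.shape[0]

    @property
    def k(self) -> int:
        return self.Theta.shape[1]


@dataclass
class Hyperparameters:
    """Regularization strengths: (lam1, lam2) on B; (lam3, lam4) on Theta.

    lam1/lam3 are L1 (sparsity), lam2 is L2 on B, lam4 weights the
    sign-adjusted Laplacian quadratic form on each theta_g.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    lambda3: float = 0.0
    lambda4: float = 0.0

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3", "lambda4"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative finite real, got {v}")
            setattr(self, name, v)

    def total(self) -> float:
        return self.lambda1 + self.lambda2 + self.lambda3 + self.lambda4


def linear_predictor(
    X: np.ndarray, B: NetworkCoefficients, coef: ClassifierCoefficients
) -> np.ndarray:
    """eta[i, g] = theta_g0 + x_i' B theta_g for a batch of rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != B.p:
        raise ValueError(f"X has {X.shape[1]} columns but B expects {B.p} regulators")
    if B.k != coef.k:
        raise ValueError("B and Theta disagree on the number of target genes")
    return coef.theta0[None, :] + (X @ B.B) @ coef.Theta.T


def class_probabilities(
    x: np.ndarray, B: NetworkCoefficients, coef: ClassifierCoefficients
) -> np.ndarray:
    """Softmax class probabilities pi_g(x, B), overflow-safe.

    Accepts a single length-p row (returns a length-G vector) or an n x p
    matrix (returns n x G).  Rows sum to one.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if not np.all(np.isfinite(x)):
        raise ValueError("expression input contains non-finite values")
    eta = linear_predictor(x, B, coef)
    eta = eta - eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    P = e / e.sum(axis=1, keepdims=True)
    return P[0] if single else P


def clipped_probabilities(P: np.ndarray) -> np.ndarray:
    """Clip probabilities into [PROB_CLIP, 1 - PROB_CLIP] before logs/ratios."""
    return np.clip(P, PROB_CLIP, 1.0 - PROB_CLIP)


def log_likelihood(
    data: ExpressionData,
    labels: ClassLabels,
    B: NetworkCoefficients,
    coef: ClassifierCoefficients,
) -> float:
    """Multinomial log-likelihood of the network-based classifier; always <= 0."""
    if labels.n != data.n:
        raise ValueError("labels and expression data disagree on sample count")
    eta = linear_predictor(data.X, B, coef)
    return float(np.sum(labels.Z * eta) - np.sum(logsumexp(eta, axis=1)))


def network_rss(data: ExpressionData, B: NetworkCoefficients) -> float:
    """Half the squared Frobenius error of the network regression, (1/2)||Y-XB||^2."""
    if data.p != B.p or data.k != B.k:
        raise ValueError("B shape does not match the expression data")
    R = data.Y - data.X @ B.B
    return 0.5 * float(np.sum(R * R))


def penalty_value(
    B: NetworkCoefficients,
    coef: ClassifierCoefficients,
    lambdas: Hyperparameters,
    Ls_per_class: list[np.ndarray] | None,
) -> float:
    """Total penalty: L1/L2 on the network columns, L1/Laplacian on theta rows.

    ``Ls_per_class`` holds one sign-adjusted Laplacian per class; ``None`` (or
    an empty list) means the graph term is absent (e.g. rectangular data with
    disjoint regulator/target sets, where the target-gene graph is empty).
    """
    val = lambdas.lambda1 * float(np.abs(B.B).sum())
    val += 0.5 * lambdas.lambda2 * float(np.sum(B.B * B.B))
    val += lambdas.lambda3 * float(np.abs(coef.Theta).sum())
    if lambdas.lambda4 > 0 and Ls_per_class is not None and len(Ls_per_class) > 0:
        if len(Ls_per_class) != coef.G:
            raise ValueError("need one sign-adjusted Laplacian per class")
        for g in range(coef.G):
            tg = coef.Theta[g]
            val += 0.5 * lambdas.lambda4 * float(tg @ Ls_per_class[g] @ tg)
    return val


def objective(
    data: ExpressionData,
    labels: ClassLabels,
    B: NetworkCoefficients,
    coef: ClassifierCoefficients,
    lambdas: Hyperparameters,
    Ls_per_class: list[np.ndarray] | None = None,
) -> float:
    """The full joint objective: -loglik + network RSS + penalties.

    This is the quantity the coordinate-descent engine must not increase
    across outer cycles.
    """
    return (
        -log_likelihood(data, labels, B, coef)
        + network_rss(data, B)
        + penalty_value(B, coef, lambdas, Ls_per_class)
    )
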