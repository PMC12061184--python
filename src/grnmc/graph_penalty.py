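"""Weighted gene graph, normalized Laplacian, and sign-adjusted variants.

The network estimate B induces an undirected weighted graph over genes that
are both regulators and targets: the weight between genes i and j averages
the two directed effect magnitudes,

    w_ij = (|beta_ij| + |beta_ji|) / 2.

Its normalized Laplacian L (unit diagonal on connected nodes,
-w_ij / sqrt(d_i d_j) off-diagonal) defines a smoothness penalty
theta' L theta that pulls degree-scaled coefficients of linked genes
together while penalizing hub genes only lightly.  Because two linked genes
may influence the phenotype with opposite signs, the penalty is applied to
coefficient magnitudes via the sign-adjusted Laplacian

    L^s = S' L S,   S = diag(sgn(theta_1), ..., sgn(theta_k)),

computed per class from the current classifier estimate.  Conjugation by a
diagonal sign matrix preserves positive semidefiniteness, so the penalty
remains convex within an outer cycle (signs are frozen per cycle by the
optimizer).

Convention notes: self-weights are excluded (W has zero diagonal -- a gene
cannot smooth against itself), sgn(0) := +1 (keeps S invertible; the value at
exact zeros does not affect the quadratic form), and the degree scaling is
1/sqrt(d) so that theta' L^s theta equals the pairwise-difference form

    sum_{q<j} w_qj (|theta_q|/sqrt(d_q) - |theta_j|/sqrt(d_j))^2

exactly on graphs with all-positive degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import ClassifierCoefficients, NetworkCoefficients


@dataclass
class GraphPenalty:
    """Edge weights, degrees, normalized Laplacian, per-class sign-adjusted L."""

    W: np.ndarray
    d: np.ndarray
    L: np.ndarray
    Ls: list[np.ndarray]


def edge_weights(B) -> np.ndarray:
    """Symmetric edge weights w_ij = (|beta_ij| + |beta_ji|)/2, zero diagonal.

    Only defined when the regulator and target gene sets coincide (square B).
    """
    if isinstance(B, NetworkCoefficients):
        B = B.B
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError(
            "edge weights require a square network over a common gene set; "
            f"got shape {B.shape}"
        )
    W = 0.5 * (np.abs(B) + np.abs(B.T))
    np.fill_diagonal(W, 0.0)
    return W


def normalized_laplacian(W: np.ndarray) -> np.ndarray:
    """Normalized graph Laplacian; isolated nodes get an all-zero row/column.

    Eigenvalues lie in [0, 2]; the matrix is symmetric PSD.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    d = W.sum(axis=1)
    k = W.shape[0]
    L = np.zeros((k, k))
    nz = d > 0
    inv_sqrt = np.zeros(k)
    inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
    L[np.ix_(nz, nz)] = -(W[np.ix_(nz, nz)] * np.outer(inv_sqrt[nz], inv_sqrt[nz]))
    # unit diagonal on connected nodes (self-weights are zero by convention)
    L[nz, nz] = 1.0 - W[nz, nz] / d[nz]
    return L


def sign_adjusted_laplacian(L: np.ndarray, theta_g: np.ndarray) -> np.ndarray:
    """L^s = S' L S with S = diag(sgn(theta_g)); sgn(0) := +1."""
    L = np.asarray(L, dtype=float)
    theta_g = np.asarray(theta_g, dtype=float).ravel()
    if L.shape[0] != L.shape[1] or L.shape[0] != theta_g.shape[0]:
        raise ValueError("L and theta_g have incompatible shapes")
    s = np.where(theta_g < 0, -1.0, 1.0)
    return L * np.outer(s, s)


def quadratic_form_check(
    theta_g: np.ndarray, W: np.ndarray, d: np.ndarray
) -> float:
    """Pairwise-difference form sum_{q<j} w_qj (|t_q|/sqrt(d_q) - |t_j|/sqrt(d_j))^2.

    Test oracle only: agrees with theta' L^s theta when W has zero diagonal
    and every degree is positive.
    """
    theta_g = np.asarray(theta_g, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    d = np.asarray(d, dtype=float).ravel()
    k = theta_g.shape[0]
    total = 0.0
    for q in range(k):
        for j in range(q + 1, k):
            if W[q, j] == 0:
                continue
            total += (
                W[q, j]
                * (abs(theta_g[q]) / np.sqrt(d[q]) - abs(theta_g[j]) / np.sqrt(d[j]))
                ** 2
            )
    return float(total)


def graph_from_network(B, coef: ClassifierCoefficients) -> GraphPenalty:
    """Build W, d, L and the per-class sign-adjusted Laplacians from B, Theta."""
    W = edge_weights(B)
    d = W.sum(axis=1)
    L = normalized_laplacian(W)
    Ls = [sign_adjusted_laplacian(L, coef.Theta[g]) for g in range(coef.G)]
    return GraphPenalty(W=W, d=d, L=L, Ls=Ls)
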