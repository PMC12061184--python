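"""Compiled coordinate-descent sweeps.

These kernels implement the inner loops of the fitting engine: a full cyclic
pass of soft-thresholded updates over the network coefficients B and over the
classifier coefficients Theta, at frozen working quantities.  They mutate
their arguments in place and maintain two residual caches so each coordinate
update is O(n (G + 1)):

  E[i, j] = y_ij - x_i' beta_j                 (network residual)
  U[i, g] = zeta_ig (k_ig - eta_ig)            (weighted working residual)

where eta is the current linear predictor.  Readable single-coordinate
reference implementations live in :mod:`grnmc.optimizer`; the test suite
checks the two paths agree sweep-for-sweep.
"""

import numpy as np
from numba import njit


@njit
def sweep_beta(X, B, Theta, E, U, Zeta, C, xsq, lam1, lam2, frozen):
    """One cyclic pass of coordinate updates over all (regulator l, target j).

    C[l, g] = sum_i zeta_ig x_il^2 and xsq[l] = sum_i x_il^2 are precomputed
    per cycle.  ``frozen`` marks coordinates pinned at zero (self-regulation
    in the square case).
    """
    n, p = X.shape
    k = B.shape[1]
    G = Theta.shape[0]
    for j in range(k):
        for l in range(p):
            if frozen[l, j]:
                continue
            b_old = B[l, j]
            num = b_old * xsq[l]
            den = xsq[l] + lam2
            for g in range(G):
                th = Theta[g, j]
                if th != 0.0:
                    acc = 0.0
                    for i in range(n):
                        acc += X[i, l] * U[i, g]
                    num += th * acc + b_old * th * th * C[l, g]
                    den += th * th * C[l, g]
            acc2 = 0.0
            for i in range(n):
                acc2 += X[i, l] * E[i, j]
            num += acc2
            if den <= 0.0:
                b_new = 0.0
            elif num > lam1:
                b_new = (num - lam1) / den
            elif num < -lam1:
                b_new = (num + lam1) / den
            else:
                b_new = 0.0
            diff = b_new - b_old
            if diff != 0.0:
                B[l, j] = b_new
                for i in range(n):
                    E[i, j] -= diff * X[i, l]
                for g in range(G):
                    th = Theta[g, j]
                    if th != 0.0:
                        c = th * diff
                        for i in range(n):
                            U[i, g] -= Zeta[i, g] * c * X[i, l]


@njit
def sweep_theta_class(F, theta_g, u_g, zeta_g, d_g, Ls_g, lam3, lam4, use_graph):
    """One cyclic pass over the coordinates of a single classifier row.

    F = XB are the network-transformed features, d_g[j] = sum_i zeta_ig
    F_ij^2, and Ls_g is the class's sign-adjusted Laplacian (ignored when
    ``use_graph`` is false, e.g. for an empty target-gene graph).  The class
    blocks are visited one at a time by the caller, which refreshes the
    working quantities between blocks (partial-Newton schedule).
    """
    n, k = F.shape
    for j in range(k):
        t_old = theta_g[j]
        acc = 0.0
        for i in range(n):
            acc += F[i, j] * u_g[i]
        num = acc + t_old * d_g[j]
        den = d_g[j]
        if use_graph:
            lap = 0.0
            for c in range(k):
                if c != j:
                    lap += theta_g[c] * Ls_g[c, j]
            num -= lam4 * lap
            den += lam4 * Ls_g[j, j]
        if den <= 0.0:
            t_new = 0.0
        elif num > lam3:
            t_new = (num - lam3) / den
        elif num < -lam3:
            t_new = (num + lam3) / den
        else:
            t_new = 0.0
        diff = t_new - t_old
        if diff != 0.0:
            theta_g[j] = t_new
            for i in range(n):
                u_g[i] -= zeta_g[i] * diff * F[i, j]
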