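"""Shared fixtures: small random model instances and generated datasets."""

import numpy as np
import pytest

from grnmc.core_model import (
    ClassifierCoefficients,
    ClassLabels,
    ExpressionData,
    Hyperparameters,
    NetworkCoefficients,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_instance(rng, n=12, p=4, k=6, G=3, square=False):
    """A small random (data, labels, B, coef) tuple for oracle checks."""
    if square:
        k = p
        X = rng.standard_normal((n, p))
        ids = [f"g{j}" for j in range(p)]
        data = ExpressionData(X, X, ids, ids)
    else:
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, k))
        data = ExpressionData(X, Y)
    y = rng.integers(0, G, size=n)
    while len(np.unique(y)) < G:
        y = rng.integers(0, G, size=n)
    labels = ClassLabels.from_labels(y, [str(g) for g in range(G)])
    B = NetworkCoefficients(rng.normal(0, 0.5, (p, k)))
    coef = ClassifierCoefficients(
        rng.normal(0, 0.5, G), rng.normal(0, 0.5, (G, k))
    )
    return data, labels, B, coef


def weak_signal_instance(rng, n=60, square=False):
    """Instance whose labels come from a moderate multinomial logistic truth.

    Mirrors the operating regime of the fitting engine: probabilities stay in
    the interior, so the per-cycle linearization is well behaved.
    """
    G = 3
    if square:
        k = int(rng.integers(5, 10))
        X = rng.standard_normal((n, k))
        X[:, 1] = 0.7 * X[:, 0] + 0.5 * rng.standard_normal(n)
        ids = [f"g{j}" for j in range(k)]
        data = ExpressionData(X, X, ids, ids)
        feats = X
    else:
        p = int(rng.integers(2, 5))
        k = int(rng.integers(4, 9))
        Bt = np.where(rng.random((p, k)) < 0.3, 0.7, 0.0)
        X = rng.standard_normal((n, p))
        Y = X @ Bt + rng.standard_normal((n, k))
        data = ExpressionData(X, Y)
        feats = X @ Bt
    Th = rng.normal(0, 0.3, (G, feats.shape[1]))
    eta = feats @ Th.T
    P = np.exp(eta - eta.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    y = (P.cumsum(axis=1) < rng.random(n)[:, None]).sum(axis=1)
    if len(np.unique(y)) < G:
        return None
    return data, ClassLabels.from_labels(y, [str(g) for g in range(G)])


def random_lambdas(rng, lambda4_choices=(0.0, 0.1, 1.0)):
    return Hyperparameters(
        float(rng.choice([0.01, 0.05, 0.1, 0.5, 1.0])),
        float(rng.choice([0.0, 0.1, 1.0])),
        float(rng.choice([0.01, 0.05, 0.1, 0.5, 1.0])),
        float(rng.choice(list(lambda4_choices))),
    )
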