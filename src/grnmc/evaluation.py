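"""Metrics, baselines, and the real-data interpretation workflow.

Covers classification accuracy, support-recovery metrics (TPR/TNR over the
coefficient supports of Theta and B), the pre-estimated-network baseline
(prNW: a lasso network frozen before classification), expression-based
baselines, a variance pre-filter, per-class network re-estimation with
common-edge extraction, and a per-gene one-way ANOVA screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    ClassLabels,
    ExpressionData,
    Hyperparameters,
)
from .model_selection import ZERO_TOL, FitConfig, SelectionGrid, select
from .optimizer import FitResult, fit


def classification_accuracy(true_labels, predicted) -> float:
    """Fraction of exact matches between two label vectors."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors have different lengths")
    return float(np.mean(true_labels == predicted))


@dataclass
class SelectionMetrics:
    """Support-recovery rates; average = (tpr + tnr) / 2."""

    tpr: float
    tnr: float
    average: float


def selection_metrics(true_coef, estimated_coef, tol: float = ZERO_TOL) -> SelectionMetrics:
    """TPR/TNR of the estimated support against the true support.

    An entry with magnitude > tol counts as selected.  With no true nonzeros
    the TPR (and hence the average) is undefined and reported as NaN.
    """
    true_coef = np.asarray(true_coef, dtype=float)
    estimated_coef = np.asarray(estimated_coef, dtype=float)
    if true_coef.shape != estimated_coef.shape:
        raise ValueError("coefficient arrays have different shapes")
    true_nz = np.abs(true_coef) > tol
    est_nz = np.abs(estimated_coef) > tol
    n_pos = int(true_nz.sum())
    n_neg = int((~true_nz).sum())
    tpr = float(np.sum(true_nz & est_nz) / n_pos) if n_pos else float("nan")
    tnr = float(np.sum(~true_nz & ~est_nz) / n_neg) if n_neg else float("nan")
    return SelectionMetrics(tpr=tpr, tnr=tnr, average=(tpr + tnr) / 2.0)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def prnw_baseline(
    data: ExpressionData,
    labels: ClassLabels,
    lambdas: Hyperparameters,
    config: FitConfig | None = None,
) -> FitResult:
    """Two-stage pre-estimated-network classifier.

    Stage 1 estimates the network by per-target lasso/elastic-net regression
    alone (the classifier term absent); stage 2 fits the penalized
    multinomial classifier on the frozen network features XB.  B is never
    revisited, so the network carries no label information -- the defining
    property of a pre-estimated network.
    """
    stage1 = fit(
        data,
        labels,
        Hyperparameters(lambdas.lambda1, lambdas.lambda2, 0.0, 0.0),
        config,
        fit_classifier=False,
    )
    return fit(data, labels, lambdas, config, fit_network=False, init=stage1)


def prnw_select(
    data: ExpressionData,
    labels: ClassLabels,
    grid: SelectionGrid | None = None,
    config: FitConfig | None = None,
):
    """BIC grid selection for the prNW baseline (stage-1 fits are cached)."""
    cache: dict = {}

    def fitter(dtr, ltr, lam, cfg):
        key = (lam.lambda1, lam.lambda2)
        if key not in cache:
            cache[key] = fit(
                dtr, ltr,
                Hyperparameters(lam.lambda1, lam.lambda2, 0.0, 0.0),
                cfg, fit_classifier=False,
            )
        return fit(dtr, ltr, lam, cfg, fit_network=False, init=cache[key])

    return select(data, labels, grid, config, fitter=fitter)


def expression_baseline(
    method: str,
    data: ExpressionData,
    labels: ClassLabels,
    grid: SelectionGrid | None = None,
    config: FitConfig | None = None,
    C_grid=(0.01, 0.05, 0.1, 0.5, 1.0),
) -> dict:
    """Expression-level classifiers on the target-gene matrix Y.

    ``la``/``ela`` are L1 / elastic-net multinomial logistic regressions with
    the inverse penalty C selected by the same validation BIC (df = nonzero
    coefficients); ``ksvm``/``rf`` are off-the-shelf wrappers with default
    settings (no coefficient support).  Returns a dict with a ``predict``
    closure over raw target expression and a G x k ``coef`` matrix (or None).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC

    if config is None:
        config = FitConfig()
    if grid is None or grid.train_idx is None:
        from .model_selection import stratified_split

        rng = np.random.default_rng(config.seed)
        tr, vl = stratified_split(labels.y, (8 / 9, 1 / 9), rng)
    else:
        tr, vl = np.asarray(grid.train_idx), np.asarray(grid.val_idx)

    F_tr, y_tr = data.Y[tr], labels.y[tr]
    F_vl, y_vl = data.Y[vl], labels.y[vl]
    mean, scale = F_tr.mean(axis=0), F_tr.std(axis=0)
    scale[scale == 0] = 1.0

    def _std(F):
        return (np.asarray(F, dtype=float) - mean) / scale

    names = np.array(labels.class_names)
    if method in ("ksvm", "rf"):
        model = (
            SVC(kernel="rbf")
            if method == "ksvm"
            else RandomForestClassifier(n_estimators=200, random_state=config.seed)
        )
        model.fit(_std(F_tr), y_tr)
        return {
            "predict": lambda F: names[model.predict(_std(F))],
            "coef": None,
            "model": model,
        }

    if method not in ("la", "ela"):
        raise ValueError(f"unknown baseline method {method!r}")
    from sklearn.linear_model import LogisticRegression

    best = None
    for C in C_grid:
        model = LogisticRegression(
            solver="saga", C=C, max_iter=2000, tol=1e-4, random_state=config.seed,
            l1_ratio=1.0 if method == "la" else 0.5,
        )
        model.fit(_std(F_tr), y_tr)
        # validation deviance + log(n_vl) * df, mirroring the main criterion
        logp = model.predict_log_proba(_std(F_vl))
        dev = -2.0 * float(logp[np.arange(len(y_vl)), y_vl].sum())
        df = int(np.sum(np.abs(model.coef_) > ZERO_TOL))
        crit = dev + np.log(len(y_vl)) * df
        if best is None or crit < best[0]:
            best = (crit, C, model)
    model = best[2]
    coef = np.zeros((labels.G, data.k))
    # sklearn drops to a 1-row coef matrix for 2 classes; G >= 3 here in practice
    if model.coef_.shape[0] == labels.G:
        coef = model.coef_
    return {
        "predict": lambda F: names[model.predict(_std(F))],
        "coef": coef,
        "C": best[1],
        "model": model,
    }


# ---------------------------------------------------------------------------
# Real-data workflow mechanics
# ---------------------------------------------------------------------------


def variance_filter(expression: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Keep the top_n genes by sample variance (ties broken by gene id)."""
    if not isinstance(expression, pd.DataFrame):
        expression = pd.DataFrame(np.asarray(expression, dtype=float))
        expression.columns = expression.columns.map(str)
    if top_n > expression.shape[1]:
        raise ValueError("top_n exceeds the number of genes")
    var = expression.var(axis=0, ddof=1)
    order = sorted(expression.columns, key=lambda g: (-var[g], str(g)))
    return expression.loc[:, order[:top_n]]


@dataclass
class ClassNetworks:
    """Per-class thresholded edge lists and their intersections."""

    genes: list[str]
    per_class: dict
    pairwise_common: dict
    common_edges: set


def class_networks(
    data: ExpressionData,
    labels: ClassLabels,
    fitted: FitResult | None = None,
    edge_threshold: float = 0.5,
    lambdas: Hyperparameters | None = None,
    config: FitConfig | None = None,
) -> ClassNetworks:
    """Re-estimate the network per class and extract shared strong edges.

    Restricted to the classifier-selected target genes of ``fitted`` (all
    genes when no fit is given), the network is re-estimated on each class's
    samples alone (network term only, classifier frozen), and directed edges
    with |beta| > edge_threshold are reported per class together with
    pairwise and all-class intersections.  The regularization of the
    per-class fits is a parameter (default lasso, lambda1 = 0.1).
    """
    if not data.is_square:
        raise ValueError("per-class networks require a square gene set (X = Y)")
    if lambdas is None:
        lambdas = Hyperparameters(lambda1=0.1)
    if config is None:
        config = FitConfig()

    if fitted is not None:
        sel = np.flatnonzero(np.any(np.abs(fitted.coef.Theta) > ZERO_TOL, axis=0))
        if sel.size == 0:
            warnings.warn("no classifier-selected genes; using all genes")
            sel = np.arange(data.k)
    else:
        sel = np.arange(data.k)
    genes = [data.target_ids[j] for j in sel]
    sub = ExpressionData(data.X[:, sel], data.Y[:, sel], genes, genes)

    per_class = {}
    y = labels.y
    for g, name in enumerate(labels.class_names):
        idx = np.flatnonzero(y == g)
        if idx.size < 3:
            warnings.warn(f"class {name!r} has {idx.size} samples (< 3); skipped")
            continue
        res = fit(sub.subset(idx), labels.subset(idx), lambdas, config,
                  fit_classifier=False)
        Bhat = res.B.B
        rows = [
            (genes[l], genes[j], Bhat[l, j])
            for l in range(len(genes))
            for j in range(len(genes))
            if abs(Bhat[l, j]) > edge_threshold
        ]
        per_class[name] = pd.DataFrame(
            rows, columns=["regulator", "target", "weight"]
        )

    edge_sets = {
        name: set(zip(df["regulator"], df["target"])) for name, df in per_class.items()
    }
    names = list(edge_sets)
    pairwise = {
        (a, b): edge_sets[a] & edge_sets[b]
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    common = set.intersection(*edge_sets.values()) if edge_sets else set()
    return ClassNetworks(
        genes=genes, per_class=per_class, pairwise_common=pairwise, common_edges=common
    )


def anova_screen(expression, labels) -> pd.DataFrame:
    """Per-gene one-way ANOVA of expression across classes.

    Returns a table with the F statistic, the raw p-value (no multiplicity
    correction) and a ``degenerate`` flag for genes with zero within-class
    variance (p reported as 0 there).
    """
    if isinstance(expression, pd.DataFrame):
        gene_ids = list(map(str, expression.columns))
        M = expression.to_numpy(dtype=float)
    else:
        M = np.asarray(expression, dtype=float)
        gene_ids = [f"g{j + 1}" for j in range(M.shape[1])]
    if isinstance(labels, ClassLabels):
        y = labels.y
    else:
        y = pd.factorize(np.asarray(labels))[0]
    classes = np.unique(y)
    G = len(classes)
    n = M.shape[0]
    if G < 2 or np.min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 classes with >= 2 samples each")

    grand = M.mean(axis=0)
    ssb = np.zeros(M.shape[1])
    ssw = np.zeros(M.shape[1])
    for c in classes:
        block = M[y == c]
        mu = block.mean(axis=0)
        ssb += block.shape[0] * (mu - grand) ** 2
        ssw += ((block - mu) ** 2).sum(axis=0)
    dfb, dfw = G - 1, n - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    degenerate = ssw == 0
    F = np.where(degenerate & (ssb > 0), np.inf, F)
    p = stats.f.sf(F, dfb, dfw)
    p = np.where(degenerate, 0.0, p)
    return pd.DataFrame(
        {"gene": gene_ids, "F": F, "pvalue": p, "degenerate": degenerate}
    )


def significance_summary(
    table: pd.DataFrame, selected_genes, alpha: float = 0.05
) -> dict:
    """Fraction of genes with p < alpha inside a subset vs its complement."""
    selected = set(map(str, selected_genes))
    is_sel = table["gene"].astype(str).isin(selected)
    sig = table["pvalue"] < alpha
    return {
        "selected_fraction": float(sig[is_sel].mean()) if is_sel.any() else float("nan"),
        "complement_fraction": float(sig[~is_sel].mean()) if (~is_sel).any() else float("nan"),
        "n_selected": int(is_sel.sum()),
        "n_complement": int((~is_sel).sum()),
    }
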