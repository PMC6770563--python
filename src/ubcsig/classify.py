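"""Basal/luminal subtype classification from a gene signature.

Elastic-net-regularized logistic regression in the glmnet parameterization

    min_beta  -(1/n) loglik(beta)
              + lambda * ( alpha*||beta||_1 + (1-alpha)/2*||beta||_2^2 )

with (alpha, lambda) jointly tuned by stratified k-fold cross-validation on
binomial deviance (ties toward the larger, more parsimonious lambda).
Features are standardized internally and coefficients back-transformed to
the original expression scale.  Stability-path gene selection draws
class-stratified half-samples, runs the lasso path on each and records the
first q genes to enter, with q set by the per-comparison error-rate bound
q^2 <= PCER * (2*pi - 1) * p^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, lars_path
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SplitPlan",
    "ElasticNetModel",
    "ClassifierMetrics",
    "StabilitySelectionResult",
    "split_train_test",
    "fit_elastic_net_logistic",
    "evaluate_classifier",
    "stability_path_select",
    "external_validation",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class SplitPlan:
    train_ids: np.ndarray
    test_ids: np.ndarray
    proportion: float
    stratum_counts: dict


@dataclass
class ElasticNetModel:
    intercept: float
    coefficients: np.ndarray      # original (unstandardized) scale
    gene_ids: np.ndarray
    alpha: float
    lam: float
    positive_class: str
    classes: tuple
    cv_deviance_path: pd.DataFrame | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(positive class) per sample."""
        return expit(self.decision_function(X))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        pos = self.predict_proba(X) >= threshold
        neg = [c for c in self.classes if c != self.positive_class][0]
        return np.where(pos, self.positive_class, neg)

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coefficients": dict(zip(map(str, self.gene_ids),
                                     map(float, self.coefficients))),
            "alpha": float(self.alpha),
            "lambda": float(self.lam),
            "positive_class": self.positive_class,
        }


@dataclass
class ClassifierMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_ci: tuple
    confusion: np.ndarray   # rows = true (pos, neg), cols = predicted (pos, neg)
    ci_method: str
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy_ci": list(self.accuracy_ci),
            "confusion": self.confusion.tolist(),
            "ci_method": self.ci_method,
            "n": self.n,
        }


@dataclass
class StabilitySelectionResult:
    selection_frequency: pd.Series
    stable_set: list
    pi_threshold: float
    pcer: float
    q_per_subsample: int
    n_subsamples: int


def split_train_test(
    sample_ids, labels, proportion: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Class-stratified random train/test split, reproducible from the seed.

    The per-class training size is round(proportion * n_class) (round half
    up), so each class's training fraction is within one sample of the
    global proportion.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    labels = np.asarray(labels)
    if not 0.0 < proportion < 1.0:
        raise ValueError("proportion must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    counts = {}
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(math.floor(proportion * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
        counts[str(cls)] = {"train": n_train, "test": len(idx) - n_train}
    return SplitPlan(
        train_ids=sample_ids[np.sort(train)],
        test_ids=sample_ids[np.sort(test)],
        proportion=proportion,
        stratum_counts=counts,
    )


def _as_matrix(X, gene_ids=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.columns.to_numpy(dtype=object)
    X = np.asarray(X, dtype=float)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
    return X, np.asarray(gene_ids, dtype=object)


def _encode_labels(y, positive_class):
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if len(classes) > 2:
        raise ValueError(f"expected binary labels, got {list(classes)}")
    if positive_class is None:
        positive_class = "basal" if "basal" in classes else classes[1]
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not found in labels")
    return (y == positive_class).astype(float), positive_class, tuple(classes)


def _lambda_path(Xs, y01, alpha, n_lambda, lambda_min_ratio):
    n = len(y01)
    a = max(alpha, 1e-3)  # glmnet convention: ridge path anchored near lasso lmax
    lam_max = np.abs(Xs.T @ (y01 - y01.mean())).max() / (n * a)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _polish_intercept(Xs, y01, beta, b0, n_iter=50):
    """Newton refinement of the unpenalized intercept at fixed coefficients."""
    eta_x = Xs @ beta
    for _ in range(n_iter):
        p = expit(b0 + eta_x)
        grad = p.mean() - y01.mean()
        hess = np.mean(p * (1 - p))
        if hess < 1e-12:
            break
        step = grad / hess
        b0 -= step
        if abs(step) < 1e-12:
            break
    return float(b0)


def _fit_path(Xs, y01, alpha, lambdas, tol=1e-4, max_iter=2000):
    """Warm-started saga fits down a lambda path on standardized data.

    The intercept is re-polished by Newton at each solution: saga's
    stopping rule can fire early when every coefficient is shrunk to zero,
    leaving the (unpenalized) intercept short of its optimum.
    """
    n = len(y01)
    clf = LogisticRegression(
        solver="saga", l1_ratio=float(alpha),
        C=1.0, max_iter=max_iter, tol=tol, warm_start=True,
    )
    coefs, intercepts = [], []
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        clf.fit(Xs, y01)
        beta = clf.coef_[0].copy()
        coefs.append(beta)
        intercepts.append(
            _polish_intercept(Xs, y01, beta, float(clf.intercept_[0]))
        )
    return np.array(coefs), np.array(intercepts)


def _binomial_deviance(y01, eta):
    # -2 * mean bernoulli loglik, numerically stable
    return float(np.mean(2 * (np.logaddexp(0.0, eta) - y01 * eta)))


def fit_elastic_net_logistic(
    X,
    y,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_folds: int = 10,
    seed: int = 0,
    positive_class=None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    gene_ids=None,
) -> ElasticNetModel:
    """Elastic-net logistic regression with joint (alpha, lambda) CV."""
    Xm, gene_ids = _as_matrix(X, gene_ids)
    if Xm.shape[1] == 0:
        raise ValueError("empty gene set")
    y01, positive_class, classes = _encode_labels(y, positive_class)
    n = len(y01)
    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xm - mu) / sd

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xs, y01))
    records = []
    best = None
    for alpha in alpha_grid:
        lambdas = _lambda_path(Xs, y01, alpha, n_lambda, lambda_min_ratio)
        dev = np.zeros(len(lambdas))
        for tr, va in folds:
            if len(np.unique(y01[tr])) < 2:
                raise ValueError("a CV fold contains a single class; reduce folds")
            coefs, icepts = _fit_path(Xs[tr], y01[tr], alpha, lambdas)
            eta = Xs[va] @ coefs.T + icepts[None, :]
            for k in range(len(lambdas)):
                dev[k] += _binomial_deviance(y01[va], eta[:, k])
        dev /= len(folds)
        # path is ordered from large lambda down: argmin takes the first
        # (largest-lambda) minimizer, i.e. the parsimonious tie-break
        k_best = int(np.argmin(dev))
        records.append(
            pd.DataFrame({"alpha": alpha, "lambda": lambdas, "cv_deviance": dev})
        )
        cand = (dev[k_best], alpha, lambdas[k_best])
        if best is None or cand[0] < best[0] or (
            cand[0] == best[0] and cand[2] > best[2]
        ):
            best = cand
    _, alpha, lam = best

    coefs, icepts = _fit_path(Xs, y01, alpha, np.array([lam]), tol=1e-8,
                              max_iter=20000)
    beta_std, b0_std = coefs[0], icepts[0]
    beta = beta_std / sd
    b0 = b0_std - float(np.sum(beta_std * mu / sd))
    return ElasticNetModel(
        intercept=b0,
        coefficients=beta,
        gene_ids=gene_ids,
        alpha=float(alpha),
        lam=float(lam),
        positive_class=positive_class,
        classes=classes,
        cv_deviance_path=pd.concat(records, ignore_index=True),
    )


def fit_elastic_net_at(
    X, y, alpha: float, lam: float, positive_class=None, gene_ids=None
) -> ElasticNetModel:
    """Fit at frozen (alpha, lambda) — used for external validation."""
    Xm, gene_ids = _as_matrix(X, gene_ids)
    y01, positive_class, classes = _encode_labels(y, positive_class)
    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xm - mu) / sd
    coefs, icepts = _fit_path(Xs, y01, alpha, np.array([lam]), tol=1e-8,
                              max_iter=20000)
    beta = coefs[0] / sd
    b0 = icepts[0] - float(np.sum(coefs[0] * mu / sd))
    return ElasticNetModel(
        intercept=b0, coefficients=beta, gene_ids=gene_ids,
        alpha=float(alpha), lam=float(lam),
        positive_class=positive_class, classes=classes,
    )


def evaluate_classifier(
    model: ElasticNetModel,
    X_test,
    y_test,
    positive_class=None,
    ci_method: str = "clopper-pearson",
    n_boot: int = 2000,
    seed: int = 0,
) -> ClassifierMetrics:
    """Accuracy / sensitivity / specificity with a 95% CI on accuracy.

    Test genes are re-ordered to the model's training gene order; a missing
    gene is an error.  Predictions threshold P(positive) at 0.5.
    """
    pos = positive_class or model.positive_class
    if isinstance(X_test, pd.DataFrame):
        missing = [g for g in model.gene_ids if g not in X_test.columns]
        if missing:
            raise KeyError(f"test matrix is missing model genes: {missing}")
        Xm = X_test.loc[:, list(model.gene_ids)].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_test, dtype=float)
        if Xm.shape[1] != len(model.gene_ids):
            raise ValueError("test matrix width does not match model gene count")
    y_true = np.asarray(y_test)
    pred = model.predict(Xm)
    tp = int(np.sum((y_true == pos) & (pred == pos)))
    fn = int(np.sum((y_true == pos) & (pred != pos)))
    fp = int(np.sum((y_true != pos) & (pred == pos)))
    tn = int(np.sum((y_true != pos) & (pred != pos)))
    n = tp + fn + fp + tn
    correct = tp + tn
    accuracy = correct / n
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    if ci_method == "clopper-pearson":
        ci = proportion_confint(correct, n, alpha=0.05, method="beta")
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        hits = (pred == y_true).astype(float)
        stats = rng.choice(hits, size=(n_boot, n), replace=True).mean(axis=1)
        ci = (float(np.quantile(stats, 0.025)), float(np.quantile(stats, 0.975)))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ClassifierMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy_ci=(float(ci[0]), float(ci[1])),
        confusion=np.array([[tp, fn], [fp, tn]]),
        ci_method=ci_method,
        n=n,
    )


def stability_q(p: int, pi_threshold: float, pcer: float) -> int:
    """Largest q with q^2 <= PCER * (2*pi - 1) * p^2 (expected-false-selection bound)."""
    bound = pcer * (2 * pi_threshold - 1.0) * p * p
    return int(math.floor(math.sqrt(bound))) if bound > 0 else 0


def stability_path_select(
    X,
    y,
    pi_threshold: float = 0.8,
    pcer: float = 0.1,
    n_subsamples: int = 100,
    seed: int = 0,
    positive_class=None,
    gene_ids=None,
) -> StabilitySelectionResult:
    """Stability-path gene selection over class-stratified half-samples."""
    Xm, gene_ids = _as_matrix(X, gene_ids)
    y01, _, _ = _encode_labels(y, positive_class)
    n, p = Xm.shape
    for cls in (0.0, 1.0):
        if np.sum(y01 == cls) < 4:
            raise ValueError("need at least 4 samples per class for half-sampling")
    q = stability_q(p, pi_threshold, pcer)
    if q == 0:
        raise ValueError(
            "PCER bound gives q = 0; increase pcer or reduce the gene set"
        )
    q = min(q, p)
    rng = np.random.default_rng(seed)
    idx_pos = np.where(y01 == 1.0)[0]
    idx_neg = np.where(y01 == 0.0)[0]
    hits = np.zeros(p)
    for _ in range(n_subsamples):
        sub = np.concatenate([
            rng.choice(idx_pos, size=len(idx_pos) // 2, replace=False),
            rng.choice(idx_neg, size=len(idx_neg) // 2, replace=False),
        ])
        Xs = Xm[sub]
        mu, sd = Xs.mean(axis=0), Xs.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (Xs - mu) / sd
        yc = y01[sub] - y01[sub].mean()
        _, _, coefs = lars_path(Xs, yc, method="lasso", max_iter=8 * q)
        entered = (coefs != 0).argmax(axis=1).astype(float)
        entered[~(coefs != 0).any(axis=1)] = np.inf
        order = np.argsort(entered, kind="stable")
        first_q = [j for j in order if np.isfinite(entered[j])][:q]
        hits[first_q] += 1
    freq = pd.Series(hits / n_subsamples, index=gene_ids)
    stable = list(freq.index[freq >= pi_threshold])
    return StabilitySelectionResult(
        selection_frequency=freq,
        stable_set=stable,
        pi_threshold=pi_threshold,
        pcer=pcer,
        q_per_subsample=q,
        n_subsamples=n_subsamples,
    )


def external_validation(
    X_train,
    y_train,
    X_test,
    y_test,
    alpha: float | None = None,
    lam: float | None = None,
    positive_class=None,
    **cv_kwargs,
) -> tuple[ElasticNetModel, ClassifierMetrics]:
    """Train on dataset A (frozen or CV-tuned (alpha, lambda)), score on B."""
    if alpha is not None and lam is not None:
        model = fit_elastic_net_at(
            X_train, y_train, alpha=alpha, lam=lam, positive_class=positive_class
        )
    else:
        model = fit_elastic_net_logistic(
            X_train, y_train, positive_class=positive_class, **cv_kwargs
        )
    metrics = evaluate_classifier(model, X_test, y_test)
    return model, metrics
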