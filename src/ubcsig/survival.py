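"""Overall-survival prediction from gene signatures.

Implements the survival arm of the pipeline: univariate Cox screening,
ridge-penalized Cox with cross-validated lambda (Verweij–van Houwelingen
partial-likelihood criterion), the "Boot Lasso" procedure (B bootstrap
resamples, lasso-Cox selection on each, genes retained when selected in at
least a fraction of resamples, final ridge refit), inverse-probability-of-
censoring-weighted (IPCW) Brier scores and their time integral (IBS),
nearest-neighbor conditional Kaplan-Meier curves, and maximally selected
log-rank cut points with the Lausen–Schumacher adjusted p-value.

Tie handling is Breslow throughout (the scikit-survival convention).  The
censoring survival estimate G is the Kaplan-Meier of the censoring
distribution, evaluated with left limits at event times as IPCW requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm
from lifelines import CoxPHFitter, KaplanMeierFitter
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "SurvivalData",
    "CoxModel",
    "BootLassoResult",
    "PredictionErrorCurve",
    "CutpointResult",
    "univariate_cox_screen",
    "fit_ridge_cox",
    "boot_lasso_cox",
    "brier_score",
    "integrated_brier",
    "cv_prediction_error",
    "conditional_km",
    "maxstat_cutpoint",
    "kaplan_meier",
]


@dataclass
class SurvivalData:
    """Right-censored survival outcomes (time in years, event 1 = death)."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if len(self.time) != len(self.event):
            raise ValueError("time and event must align")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalData":
        ids = self.sample_ids[idx] if self.sample_ids is not None else None
        return SurvivalData(self.time[idx], self.event[idx], ids)

    @classmethod
    def from_annotation(cls, annotation: pd.DataFrame) -> "SurvivalData":
        return cls(
            time=annotation["os_time"].to_numpy(),
            event=annotation["os_event"].to_numpy(),
            sample_ids=annotation["sample_id"].to_numpy(dtype=object)
            if "sample_id" in annotation
            else None,
        )

    def to_structured(self):
        return Surv.from_arrays(self.event.astype(bool), self.time)


def kaplan_meier(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier step function: (event times, survival just after each)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    uniq = np.unique(t[e == 1])
    surv = np.empty(len(uniq))
    s = 1.0
    for i, ti in enumerate(uniq):
        n_risk = np.sum(t >= ti)
        d = np.sum((t == ti) & (e == 1))
        s *= 1.0 - d / n_risk
        surv[i] = s
    return uniq, surv


def _step_eval(times: np.ndarray, values: np.ndarray, at: np.ndarray,
               left: bool = False) -> np.ndarray:
    """Right-continuous step function evaluation; ``left`` gives S(t-)."""
    side = "left" if left else "right"
    idx = np.searchsorted(times, at, side=side)
    out = np.ones(len(np.atleast_1d(at)))
    pos = idx > 0
    out[pos] = values[idx[pos] - 1]
    return out


@dataclass
class CoxModel:
    """Penalized Cox model with a Breslow baseline cumulative hazard."""

    coefficients: np.ndarray          # on the standardized scale
    gene_ids: np.ndarray
    penalty: str                      # {ridge, lasso, none, null}
    lam: float
    train_mean: np.ndarray
    train_sd: np.ndarray
    baseline_times: np.ndarray        # event times
    baseline_cumhaz: np.ndarray       # H0 at those times (Breslow)
    cv_path: pd.DataFrame | None = None

    def linear_predictor(self, X) -> np.ndarray:
        Xm = _extract(X, self.gene_ids)
        Z = (Xm - self.train_mean) / self.train_sd
        return Z @ self.coefficients

    def predict_survival(self, X, times) -> np.ndarray:
        """S(t|x) matrix, shape (n_samples, n_times)."""
        eta = self.linear_predictor(X)
        times = np.atleast_1d(np.asarray(times, dtype=float))
        h0 = _step_eval(self.baseline_times, self.baseline_cumhaz, times)
        h0 = np.where(
            np.searchsorted(self.baseline_times, times, side="right") > 0, h0, 0.0
        )
        return np.exp(-np.outer(np.exp(eta), h0))

    def to_dict(self) -> dict:
        # report coefficients per unit of original expression
        return {
            "penalty": self.penalty,
            "lambda": float(self.lam),
            "coefficients": {
                str(g): float(b / s)
                for g, b, s in zip(self.gene_ids, self.coefficients, self.train_sd)
            },
        }


@dataclass
class BootLassoResult:
    B: int
    selection_count: pd.Series
    retained_set: list
    retain_fraction: float
    final_model: CoxModel
    empty: bool = False


@dataclass
class PredictionErrorCurve:
    times: np.ndarray
    brier: np.ndarray
    ibs: float
    t_max: float
    model_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "brier": self.brier, "model": self.model_label}
        )


@dataclass
class CutpointResult:
    cut_value: float
    cut_quantile: float
    max_statistic: float
    adjusted_p: float
    epsilon_range: tuple
    candidate_values: np.ndarray = field(repr=False, default=None)
    candidate_statistics: np.ndarray = field(repr=False, default=None)


def _extract(X, gene_ids) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [g for g in gene_ids if g not in X.columns]
        if missing:
            raise KeyError(f"missing genes: {missing}")
        return X.loc[:, list(gene_ids)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(gene_ids):
        raise ValueError("matrix width does not match gene list")
    return X


def _gene_ids_of(X, gene_ids=None):
    if isinstance(X, pd.DataFrame):
        return X.columns.to_numpy(dtype=object)
    if gene_ids is not None:
        return np.asarray(gene_ids, dtype=object)
    return np.array([f"g{i}" for i in range(np.asarray(X).shape[1])], dtype=object)


def breslow_partial_loglik(Z: np.ndarray, time, event, beta: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood (unscaled)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = Z @ beta
    order = np.argsort(-time, kind="stable")  # descending: running risk-set sums
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    exp_eta = np.exp(eta_o)
    ll = 0.0
    cum = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        cum += exp_eta[i:j].sum()
        ev = np.arange(i, j)[e_o[i:j] == 1]
        if len(ev):
            ll += eta_o[ev].sum() - len(ev) * np.log(cum)
        i = j
    return float(ll)


def _breslow_baseline(Z, time, event, beta):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = Z @ beta
    exp_eta = np.exp(eta)
    uniq = np.unique(time[event == 1])
    cumhaz = np.empty(len(uniq))
    h = 0.0
    for i, ti in enumerate(uniq):
        at_risk = exp_eta[time >= ti].sum()
        d = np.sum((time == ti) & (event == 1))
        h += d / at_risk
        cumhaz[i] = h
    return uniq, cumhaz


def univariate_cox_screen(X, surv: SurvivalData, gene_ids=None) -> pd.DataFrame:
    """One unpenalized Cox fit per standardized gene; Wald p and BH FDR.

    Degenerate (constant) genes are reported with NaN estimates rather than
    raising.  Raw Wald p-values are the primary column (matching how the
    screen is used); a BH-adjusted column is provided alongside.
    """
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 events")
    gene_ids = _gene_ids_of(X, gene_ids)
    Xm = _extract(X, gene_ids)
    rows = []
    df = pd.DataFrame({"time": surv.time, "event": surv.event})
    for k, g in enumerate(gene_ids):
        x = Xm[:, k]
        s = x.std()
        if s == 0 or not np.isfinite(s):
            rows.append((g, np.nan, np.nan, np.nan, True))
            continue
        df["x"] = (x - x.mean()) / s
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
            rows.append(
                (
                    g,
                    float(cph.params_["x"]),
                    float(np.exp(cph.params_["x"])),
                    float(cph.summary.loc["x", "p"]),
                    False,
                )
            )
        except Exception:
            rows.append((g, np.nan, np.nan, np.nan, True))
    out = pd.DataFrame(
        rows, columns=["gene", "log_hr", "hazard_ratio", "wald_p", "degenerate"]
    )
    p = out["wald_p"].to_numpy()
    out["bh_fdr"] = benjamini_hochberg(p)
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


DEFAULT_RIDGE_LAMBDAS = tuple(np.geomspace(1e-3, 1e3, 13))


def fit_ridge_cox(
    X,
    surv: SurvivalData,
    n_folds: int = 10,
    seed: int = 0,
    lambdas=DEFAULT_RIDGE_LAMBDAS,
    gene_ids=None,
) -> CoxModel:
    """Ridge Cox with lambda by k-fold cross-validated partial likelihood.

    The CV criterion is Verweij & van Houwelingen's cross-validated partial
    log-likelihood: sum over folds of loglik(all data; beta_{-k}) -
    loglik(training fold; beta_{-k}).  Larger is better; ties break toward
    the larger lambda.
    """
    gene_ids = _gene_ids_of(X, gene_ids)
    Xm = _extract(X, gene_ids)
    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Xm - mu) / sd
    y = surv.to_structured()

    lambdas = np.sort(np.asarray(list(lambdas), dtype=float))
    rng = np.random.default_rng(seed)
    folds = _event_stratified_folds(surv, n_folds, rng)
    cvpl = np.zeros(len(lambdas))
    for k, lam in enumerate(lambdas):
        for va in folds:
            tr = np.setdiff1d(np.arange(len(surv)), va)
            if surv.event[tr].sum() < 1:
                raise ValueError("a CV fold training set has no events")
            est = CoxPHSurvivalAnalysis(alpha=float(lam))
            est.fit(Z[tr], y[tr])
            beta = est.coef_
            cvpl[k] += breslow_partial_loglik(
                Z, surv.time, surv.event, beta
            ) - breslow_partial_loglik(Z[tr], surv.time[tr], surv.event[tr], beta)
    # ties toward larger lambda: scan from the largest
    k_best = len(lambdas) - 1 - int(np.argmax(cvpl[::-1]))
    lam = float(lambdas[k_best])
    est = CoxPHSurvivalAnalysis(alpha=lam)
    est.fit(Z, y)
    beta = est.coef_
    bt, bh = _breslow_baseline(Z, surv.time, surv.event, beta)
    return CoxModel(
        coefficients=beta,
        gene_ids=gene_ids,
        penalty="ridge",
        lam=lam,
        train_mean=mu,
        train_sd=sd,
        baseline_times=bt,
        baseline_cumhaz=bh,
        cv_path=pd.DataFrame({"lambda": lambdas, "cvpl": cvpl}),
    )


def _event_stratified_folds(surv: SurvivalData, n_folds: int, rng) -> list:
    """Partition indices into folds balanced on the event indicator."""
    folds = [[] for _ in range(n_folds)]
    for cls in (1, 0):
        idx = np.where(surv.event == cls)[0]
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _fit_null_km(surv: SurvivalData) -> CoxModel:
    """Covariate-free model: Breslow baseline = Nelson-Aalen of the data."""
    t, h = _breslow_baseline(np.zeros((len(surv), 1)), surv.time, surv.event,
                             np.zeros(1))
    return CoxModel(
        coefficients=np.zeros(1),
        gene_ids=np.array(["__null__"], dtype=object),
        penalty="null",
        lam=0.0,
        train_mean=np.zeros(1),
        train_sd=np.ones(1),
        baseline_times=t,
        baseline_cumhaz=h,
    )


def boot_lasso_cox(
    X,
    surv: SurvivalData,
    B: int = 200,
    retain_fraction: float = 0.5,
    seed: int = 0,
    inner_folds: int = 3,
    ridge_folds: int = 10,
    gene_ids=None,
) -> BootLassoResult:
    """Bootstrap-Lasso gene retention followed by a ridge Cox refit.

    B bootstrap resamples (with replacement, size n); on each, a lasso-Cox
    path is fit and lambda chosen by ``inner_folds``-fold held-out partial
    likelihood inside the bootstrap.  Genes with nonzero coefficients in at
    least ``retain_fraction`` of the resamples form the retained set, on
    which a ridge Cox model is fit to the full data.  An empty retained set
    yields a flagged null (Kaplan-Meier) model.
    """
    gene_ids = _gene_ids_of(X, gene_ids)
    Xm = _extract(X, gene_ids)
    n, p = Xm.shape
    rng = np.random.default_rng(seed)
    counts = np.zeros(p)
    b_done = 0
    attempts = 0
    while b_done < B:
        attempts += 1
        if attempts > 20 * B:
            raise RuntimeError("could not draw enough valid bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        t_b, e_b = surv.time[idx], surv.event[idx]
        if e_b.sum() < max(3, inner_folds):
            continue
        Xb = Xm[idx]
        sd = Xb.std(axis=0)
        if np.any(sd == 0):  # degenerate resample of a constant column
            sd = np.where(sd > 0, sd, 1.0)
        Zb = (Xb - Xb.mean(axis=0)) / sd
        try:
            support = _lasso_cox_support(Zb, t_b, e_b, inner_folds, rng)
        except (ValueError, ArithmeticError):
            continue
        counts[support] += 1
        b_done += 1
    freq = counts / B
    retained = list(np.asarray(gene_ids, dtype=object)[freq >= retain_fraction])
    if retained:
        final = fit_ridge_cox(
            pd.DataFrame(Xm, columns=gene_ids).loc[:, retained],
            surv,
            n_folds=ridge_folds,
            seed=seed,
        )
        empty = False
    else:
        final = _fit_null_km(surv)
        empty = True
    return BootLassoResult(
        B=B,
        selection_count=pd.Series(counts.astype(int), index=gene_ids),
        retained_set=retained,
        retain_fraction=retain_fraction,
        final_model=final,
        empty=empty,
    )


def _lasso_cox_support(Z, time, event, inner_folds, rng) -> np.ndarray:
    """Support of a lasso-Cox fit at a CV-chosen lambda on one resample.

    Lambda is picked by the one-standard-error rule on held-out partial
    log-likelihood (the glmnet parsimony convention): the largest lambda
    whose mean CV score is within one SE of the best.  On pure-noise data
    this collapses to the empty model rather than chasing CV noise.
    """
    y = Surv.from_arrays(event.astype(bool), time)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=30, alpha_min_ratio=0.01)
    path.fit(Z, y)
    alphas = path.alphas_
    surv_b = SurvivalData(time, event)
    folds = _event_stratified_folds(surv_b, inner_folds, rng)
    fold_scores = []
    for va in folds:
        tr = np.setdiff1d(np.arange(len(time)), va)
        if event[tr].sum() < 1 or event[va].sum() < 1:
            continue
        inner = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, alpha_min_ratio=0.01
        )
        inner.fit(Z[tr], y[tr])
        n_va = max(len(va), 1)
        fold_scores.append([
            breslow_partial_loglik(Z[va], time[va], event[va],
                                   inner.coef_[:, k]) / n_va
            for k in range(inner.coef_.shape[1])
        ])
    scores = np.asarray(fold_scores)
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(len(scores))
    k_best = int(np.argmax(mean))
    threshold = mean[k_best] - se[k_best]
    # alphas are descending: the first index within one SE is the largest lambda
    k_1se = int(np.argmax(mean >= threshold))
    return np.where(path.coef_[:, k_1se] != 0)[0]


def censoring_km(surv: SurvivalData) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier of the censoring distribution (event = censored)."""
    return kaplan_meier(surv.time, 1 - surv.event)


def brier_score(
    surv_test: SurvivalData,
    predicted_survival: np.ndarray,
    t: float,
    g_times: np.ndarray | None = None,
    g_surv: np.ndarray | None = None,
) -> float:
    """IPCW Brier score at time t.

    ``predicted_survival`` holds S(t|x_i) per test sample.  Weights come
    from the censoring Kaplan-Meier G computed on the test data (or supplied
    explicitly): subjects with an observed event before t weight 1/G(T_i-),
    subjects still at risk at t weight 1/G(t); censored-before-t subjects
    contribute zero.
    """
    S = np.asarray(predicted_survival, dtype=float)
    if S.shape != surv_test.time.shape:
        raise ValueError("predicted survival must align with test samples")
    if np.any((S < 0) | (S > 1)):
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    if g_times is None or g_surv is None:
        g_times, g_surv = censoring_km(surv_test)
    time, event = surv_test.time, surv_test.event
    died = (time <= t) & (event == 1)
    alive = time > t
    contrib = np.zeros(len(time))
    if died.any():
        g_left = _step_eval(g_times, g_surv, time[died], left=True)
        if np.any(g_left < 1e-8):
            bad = time[died][g_left < 1e-8]
            raise ZeroDivisionError(
                f"censoring survival vanishes before event time(s) {bad[:3]}"
            )
        contrib[died] = S[died] ** 2 / g_left
    if alive.any():
        g_t = _step_eval(g_times, g_surv, np.array([t]))[0]
        if g_t < 1e-8:
            raise ZeroDivisionError(f"censoring survival vanishes at t={t}")
        contrib[alive] = (1.0 - S[alive]) ** 2 / g_t
    return float(contrib.mean())


def integrated_brier(
    surv_test: SurvivalData,
    predict: Callable[[np.ndarray], np.ndarray],
    t_max: float = 3.0,
    model_label: str = "model",
) -> PredictionErrorCurve:
    """Brier curve on the observed-time grid in (0, t_max] and trapezoidal IBS.

    ``predict(times)`` must return S(t|x), shape (n_samples, n_times).
    The grid is the sorted unique observed times restricted to (0, t_max],
    with 0 and t_max appended so the trapezoid covers the whole window;
    IBS = integral / t_max.
    """
    grid = np.unique(surv_test.time)
    grid = grid[(grid > 0) & (grid <= t_max)]
    grid = np.unique(np.concatenate([[0.0], grid, [t_max]]))
    S = np.asarray(predict(grid), dtype=float)
    g_times, g_surv = censoring_km(surv_test)
    bs = np.array(
        [
            brier_score(surv_test, S[:, k], t, g_times, g_surv)
            for k, t in enumerate(grid)
        ]
    )
    ibs = float(np.trapezoid(bs, grid) / t_max)
    return PredictionErrorCurve(
        times=grid, brier=bs, ibs=ibs, t_max=t_max, model_label=model_label
    )


def cv_prediction_error(
    model_spec,
    X,
    surv: SurvivalData,
    n_folds: int = 10,
    seed: int = 0,
    t_max: float = 3.0,
    model_label: str | None = None,
    **fit_kwargs,
) -> PredictionErrorCurve:
    """Out-of-fold survival predictions pooled into one Brier/IBS computation.

    ``model_spec`` is "null" (training-fold Kaplan-Meier), "ridge",
    "bootlasso", or a callable ``fit(X_train, surv_train) -> CoxModel``.
    """
    if callable(model_spec):
        fit = model_spec
        label = model_label or "custom"
    elif model_spec == "null":
        fit = lambda Xtr, str_: _fit_null_km(str_)  # noqa: E731
        label = model_label or "null"
    elif model_spec == "ridge":
        fit = lambda Xtr, str_: fit_ridge_cox(Xtr, str_, seed=seed, **fit_kwargs)  # noqa: E731
        label = model_label or "full_signature"
    elif model_spec == "bootlasso":
        fit = lambda Xtr, str_: boot_lasso_cox(  # noqa: E731
            Xtr, str_, seed=seed, **fit_kwargs
        ).final_model
        label = model_label or "boot_lasso"
    else:
        raise ValueError(f"unknown model_spec {model_spec!r}")

    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    rng = np.random.default_rng(seed)
    folds = _event_stratified_folds(surv, n_folds, rng)
    grid = np.unique(surv.time)
    grid = grid[(grid > 0) & (grid <= t_max)]
    grid = np.unique(np.concatenate([[0.0], grid, [t_max]]))
    S_pool = np.empty((len(surv), len(grid)))
    for va in folds:
        if len(va) == 0:
            continue
        tr = np.setdiff1d(np.arange(len(surv)), va)
        model = fit(Xdf.iloc[tr], surv.subset(tr))
        if model.penalty == "null":
            S_va = model.predict_survival(
                np.zeros((len(va), 1)), grid
            )
        else:
            S_va = model.predict_survival(Xdf.iloc[va], grid)
        S_pool[va] = S_va
    g_times, g_surv = censoring_km(surv)
    bs = np.array(
        [brier_score(surv, S_pool[:, k], t, g_times, g_surv)
         for k, t in enumerate(grid)]
    )
    ibs = float(np.trapezoid(bs, grid) / t_max)
    return PredictionErrorCurve(
        times=grid, brier=bs, ibs=ibs, t_max=t_max, model_label=label
    )


def conditional_km(
    signature_values,
    surv: SurvivalData,
    span: float = 0.25,
    anchors=("lowest", "median", "highest"),
) -> dict:
    """Nearest-neighbor (rectangular-kernel) conditional Kaplan-Meier curves.

    For each anchor (the smallest, median and largest signature value) the
    ceil(span * n) samples nearest in signature value form the neighborhood
    (ties by sample order) and its Kaplan-Meier curve is returned, labeled
    low / medium / high.
    """
    x = np.asarray(signature_values, dtype=float)
    n = len(x)
    k = int(np.ceil(span * n))
    if k < 2:
        raise ValueError("span * n must be at least 2")
    anchor_values = {
        "lowest": np.min(x),
        "median": np.median(x),
        "highest": np.max(x),
    }
    label_of = {"lowest": "low", "median": "medium", "highest": "high"}
    curves = {}
    for a in anchors:
        av = anchor_values[a]
        order = np.argsort(np.abs(x - av), kind="stable")
        nb = np.sort(order[:k])
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[nb], surv.event[nb])
        sf = kmf.survival_function_
        curves[label_of[a]] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return curves


def _logrank_stats_at_cuts(x, time, event, cut_values) -> np.ndarray:
    """Standardized two-group log-rank statistic for each cut (group: x <= c).

    Vectorized over cuts: at-risk and event counts for every cut come from
    cumulative sums of the (samples x cuts) membership matrix along
    descending time order.
    """
    cut_values = np.asarray(cut_values, dtype=float)
    order = np.argsort(-time, kind="stable")
    t, e, xs = time[order], event[order], x[order]
    G = xs[:, None] <= cut_values[None, :]          # (n, n_cuts)
    n1_cum = np.cumsum(G, axis=0)                    # at-risk in group1
    n_cum = np.arange(1, len(t) + 1)

    uniq, first = np.unique(-t, return_index=True)   # descending-time blocks
    # index of the last sample in each time block = at-risk set size there
    last = np.r_[first[1:], len(t)] - 1
    stats_U = np.zeros(len(cut_values))
    stats_V = np.zeros(len(cut_values))
    for f, l in zip(first, last):
        ev = e[f:l + 1] == 1
        d = int(ev.sum())
        if d == 0:
            continue
        n_t = n_cum[l]
        n1 = n1_cum[l]
        d1 = G[f:l + 1][ev].sum(axis=0)
        frac = n1 / n_t
        stats_U += d1 - d * frac
        if n_t > 1:
            stats_V += d * frac * (1 - frac) * (n_t - d) / (n_t - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(stats_V > 0, stats_U / np.sqrt(stats_V), 0.0)
    return out


def maxstat_cutpoint(
    signature_values,
    surv: SurvivalData,
    epsilon: tuple = (0.1, 0.9),
) -> CutpointResult:
    """Maximally selected log-rank cut point with adjusted p-value.

    Candidate cuts are the observed values whose left-group proportion lies
    in [epsilon_1, epsilon_2].  M = max |standardized log-rank|; the adjusted
    p uses the Lausen–Schumacher Brownian-bridge improved-Bonferroni
    approximation, floored at the pointwise two-sided normal p (which it
    equals when only one candidate exists) and capped at 1.
    """
    x = np.asarray(signature_values, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if surv.event.sum() < 5:
        raise ValueError("need at least 5 events")
    if np.all(x == x[0]):
        raise ValueError("all signature values identical; no cut point exists")
    n = len(x)
    sorted_x = np.sort(np.unique(x))
    prop = np.array([(x <= c).mean() for c in sorted_x])
    inside = (prop >= epsilon[0]) & (prop <= epsilon[1]) & (prop < 1.0)
    cand = sorted_x[inside]
    if len(cand) == 0:
        raise ValueError("no candidate cuts inside the epsilon quantile window")
    stats = _logrank_stats_at_cuts(x, surv.time, surv.event, cand)
    k = int(np.argmax(np.abs(stats)))
    M = float(np.abs(stats[k]))
    pointwise = float(2 * norm.sf(M))
    if len(cand) == 1:
        p_adj = pointwise
    else:
        t1 = float((x <= cand[0]).mean())
        t2 = float((x <= cand[-1]).mean())
        if M <= 1e-12:
            p_adj = 1.0
        else:
            phi = norm.pdf(M)
            p_adj = phi * (M - 1.0 / M) * np.log(
                (t2 * (1 - t1)) / (t1 * (1 - t2))
            ) + 4 * phi / M
        p_adj = max(p_adj, pointwise)
    p_adj = float(min(p_adj, 1.0))
    return CutpointResult(
        cut_value=float(cand[k]),
        cut_quantile=float((x <= cand[k]).mean()),
        max_statistic=M,
        adjusted_p=p_adj,
        epsilon_range=tuple(epsilon),
        candidate_values=cand,
        candidate_statistics=stats,
    )
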