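"""Precision-weighted differential expression and comparative-CT qPCR.

The DE route mirrors the voom/limma approach: counts go to log-CPM, a
per-gene linear model is fit, the mean-variance trend (sqrt residual sd vs
average log-count) is estimated by lowess and inverted into per-observation
precision weights (predicted sd^-4); weighted least squares then yields
per-gene effects whose variances are shrunk by empirical Bayes (inverse-chi
prior; hyperparameters d0, s0^2 by moment matching on log-variances via
digamma/trigamma inversion) to give moderated t statistics with d0 + d_g
degrees of freedom and BH-adjusted FDR.

qPCR quantification uses the comparative-CT (delta-delta-CT) method against
a reference gene (typically HPRT1) and a control condition, with
two-sample Student t tests on replicate delta-CT values and BH FDR across
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .normalization import CountMatrix, ExpressionMatrix, log_cpm
from .survival import benjamini_hochberg

__all__ = ["DEResult", "voom_weights", "moderated_t_test", "ddct_quantify"]

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    table: pd.DataFrame          # gene, logFC, t, p, fdr, df_resid
    prior_df: float              # d0
    prior_var: float             # s0^2


def _design_matrix(design, n_samples: int) -> np.ndarray:
    """Accept a two-group label vector or an explicit design with intercept."""
    design = np.asarray(design)
    if design.ndim == 1:
        groups = np.unique(design)
        if len(groups) != 2:
            raise ValueError(f"expected 2 groups, got {list(groups)}")
        X = np.column_stack(
            [np.ones(n_samples), (design == groups[1]).astype(float)]
        )
        return X
    if design.shape[0] != n_samples:
        raise ValueError("design rows must match number of samples")
    return design.astype(float)


def voom_weights(
    counts: CountMatrix, design, span: float = 0.5, prior: float = 0.5
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Mean-variance precision weights from the lowess sd trend.

    Returns the log-CPM matrix and a (genes x samples) weight matrix,
    weight = predicted-sd^-4 interpolated at each observation's fitted
    log-count.
    """
    X = _design_matrix(design, counts.n_samples)
    if X.ndim != 2 or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    groups_ok = counts.n_samples - X.shape[1] >= 1
    if not groups_ok:
        raise ValueError("need residual degrees of freedom (more samples)")
    expr = log_cpm(counts, prior=prior)
    Y = expr.values
    lib = counts.library_sizes

    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ coef).T
    resid = Y - fitted
    df = counts.n_samples - X.shape[1]
    s = np.sqrt((resid**2).sum(axis=1) / df)

    # average log2 count per gene; offset converts mean log-CPM back to counts
    offset = np.mean(np.log2(lib + 2 * prior)) - np.log2(1e6)
    sx = Y.mean(axis=1) + offset
    sy = np.sqrt(s)
    lo = lowess(sy, sx, frac=span, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]
    lx, keep = np.unique(lx, return_index=True)
    ly = ly[keep]

    fitted_logcount = fitted + np.log2((lib + 2 * prior) / 1e6)[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, lx, ly)
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    weights = pred_sqrt_sd ** -4
    return expr, weights


def _trigamma_inverse(y: float, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by the standard Newton iteration on 1/x scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed variances: returns (d0, s0^2)."""
    ok = (s2 > 0) & np.isfinite(s2)
    z = np.log(s2[ok])
    d = df[ok].astype(float)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - np.mean(polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(e_mean)
    return float(d0), float(s0_2)


def moderated_t_test(
    expr: ExpressionMatrix | np.ndarray,
    weights: np.ndarray | None,
    design,
    coef: int = 1,
    prior_df: float | None = None,
    gene_ids=None,
) -> DEResult:
    """Per-gene weighted least squares with empirical-Bayes moderated t.

    ``prior_df`` overrides the estimated d0: 0 gives the ordinary (weighted)
    t-test, ``numpy.inf`` the normal test with the pooled prior variance.
    """
    if isinstance(expr, ExpressionMatrix):
        Y = expr.values
        gene_ids = expr.gene_ids
    else:
        Y = np.asarray(expr, dtype=float)
        if gene_ids is None:
            gene_ids = np.array([f"g{i}" for i in range(Y.shape[0])], dtype=object)
    n_genes, n_samples = Y.shape
    X = _design_matrix(design, n_samples)
    if weights is None:
        weights = np.ones_like(Y)
    W = np.asarray(weights, dtype=float)
    if W.shape != Y.shape:
        raise ValueError("weights must match the expression matrix shape")
    df_resid = n_samples - X.shape[1]
    if df_resid < 1:
        raise ValueError("residual degrees of freedom must be >= 1")

    beta = np.empty(n_genes)
    s2 = np.empty(n_genes)
    v_coef = np.empty(n_genes)
    for g in range(n_genes):
        w = W[g]
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWy = Xw.T @ Y[g]
        xtwx_inv = np.linalg.inv(XtWX)
        b = xtwx_inv @ XtWy
        resid = Y[g] - X @ b
        s2[g] = float(np.sum(w * resid**2) / df_resid)
        beta[g] = b[coef]
        v_coef[g] = xtwx_inv[coef, coef]

    dfs = np.full(n_genes, df_resid, dtype=float)
    d0, s0_2 = _fit_f_dist(s2, dfs)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = np.full(n_genes, s0_2)
        t_stat = beta / np.sqrt(s2_post * v_coef)
        p = 2 * stats.norm.sf(np.abs(t_stat))
        df_total = np.full(n_genes, np.inf)
    else:
        s2_post = (d0 * s0_2 + dfs * s2) / (d0 + dfs) if d0 > 0 else s2
        df_total = d0 + dfs
        t_stat = beta / np.sqrt(s2_post * v_coef)
        p = 2 * stats.t.sf(np.abs(t_stat), df=df_total)
    table = pd.DataFrame(
        {
            "gene": gene_ids,
            "logFC": beta,
            "t": t_stat,
            "p": p,
            "fdr": benjamini_hochberg(p),
            "df_resid": dfs,
            "s2": s2,
            "s2_post": s2_post,
        }
    )
    return DEResult(table=table, prior_df=float(d0), prior_var=float(s0_2))


def ddct_quantify(
    records: pd.DataFrame,
    control_condition: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Comparative-CT quantification with per-gene t tests and BH FDR.

    ``records`` columns: sample, condition, gene, ct_target, ct_ref.
    Duplicate wells of the same (sample, condition, gene) are averaged
    before delta-CT; records lacking a reference CT are rejected with a log
    entry.  Fold change = 2**(-ddCT) vs the control condition.
    """
    required = {"sample", "condition", "gene", "ct_target", "ct_ref"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if control_condition not in set(records["condition"]):
        raise ValueError(f"control condition {control_condition!r} not present")
    bad = records["ct_ref"].isna() | records["ct_target"].isna()
    if bad.any():
        for _, row in records[bad].iterrows():
            logger.warning(
                "rejecting qPCR record without complete CT values: "
                "sample=%s gene=%s condition=%s",
                row["sample"], row["gene"], row["condition"],
            )
        records = records[~bad]
    wells = (
        records.groupby(["sample", "condition", "gene"], as_index=False)[
            ["ct_target", "ct_ref"]
        ].mean()
    )
    wells["dct"] = wells["ct_target"] - wells["ct_ref"]

    rows = []
    for gene, gdf in wells.groupby("gene"):
        ctrl = gdf.loc[gdf["condition"] == control_condition, "dct"]
        if len(ctrl) < 2:
            raise ValueError(
                f"gene {gene!r}: need >= 2 control replicates, got {len(ctrl)}"
            )
        for cond, cdf in gdf.groupby("condition"):
            if cond == control_condition:
                continue
            if len(cdf) < 2:
                raise ValueError(
                    f"gene {gene!r}, condition {cond!r}: need >= 2 replicates"
                )
            ddct = cdf["dct"].mean() - ctrl.mean()
            t_stat, t_p = stats.ttest_ind(
                cdf["dct"], ctrl, equal_var=not welch
            )
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "mean_dct": cdf["dct"].mean(),
                    "control_mean_dct": ctrl.mean(),
                    "ddct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                    "t_p": t_p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        # FDR across genes, within each comparison condition
        out["fdr"] = np.nan
        for cond in out["condition"].unique():
            m = out["condition"] == cond
            out.loc[m, "fdr"] = benjamini_hochberg(out.loc[m, "t_p"].to_numpy())
    return out
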