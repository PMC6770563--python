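"""Parametric empirical-Bayes location/scale batch adjustment (ComBat).

Each gene is standardized by its grand mean (and optional covariate effects)
and pooled variance; per-batch location (gamma) and scale (delta^2) are then
shrunk toward parametric priors — normal for gamma, inverse-gamma for
delta^2, hyperparameters by method of moments across genes — via the coupled
fixed-point updates, and the data are back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .normalization import ExpressionMatrix

__all__ = ["ComBatParams", "combat_adjust"]


@dataclass
class ComBatParams:
    batches: np.ndarray
    gamma_hat: np.ndarray      # (n_batches, n_genes)
    gamma_star: np.ndarray
    delta2_hat: np.ndarray
    delta2_star: np.ndarray
    gamma_prior_mean: np.ndarray   # per batch
    gamma_prior_var: np.ndarray
    delta_prior_shape: np.ndarray  # inverse-gamma lambda per batch
    delta_prior_scale: np.ndarray  # inverse-gamma theta per batch
    grand_mean: np.ndarray         # alpha_g
    pooled_var: np.ndarray         # sigma2_g
    design_coef: np.ndarray | None
    n_iter: np.ndarray

    def to_dict(self) -> dict:
        return {
            "batches": [
                b.item() if hasattr(b, "item") else b for b in self.batches
            ],
            "gamma_hat": self.gamma_hat.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_hat": self.delta2_hat.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "gamma_prior_mean": self.gamma_prior_mean.tolist(),
            "gamma_prior_var": self.gamma_prior_var.tolist(),
            "delta_prior_shape": self.delta_prior_shape.tolist(),
            "delta_prior_scale": self.delta_prior_scale.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "pooled_var": self.pooled_var.tolist(),
            "n_iter": self.n_iter.tolist(),
        }


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_adjust(
    matrix: ExpressionMatrix,
    batch,
    covariates: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> tuple[ExpressionMatrix, ComBatParams]:
    """Adjust expression for batch with the parametric ComBat algorithm.

    Parameters
    ----------
    matrix:
        Log-scale expression, genes x samples.
    batch:
        Per-sample batch labels (length = n samples); >= 2 batches, each with
        >= 2 samples.
    covariates:
        Optional (n_samples, k) design of biological covariates to protect
        during standardization.  Must not be confounded with batch.
    """
    X = matrix.values
    batch = np.asarray(batch)
    n_genes, n_samples = X.shape
    if len(batch) != n_samples:
        raise ValueError("batch labels do not match number of samples")
    levels, batch_idx = np.unique(batch, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("ComBat requires at least 2 batches")
    counts = np.bincount(batch_idx)
    if np.any(counts < 2):
        small = levels[counts < 2]
        raise ValueError(f"batch(es) with fewer than 2 samples: {list(small)}")

    # design: batch indicators + optional covariates; OLS per gene
    B = np.zeros((n_samples, len(levels)))
    B[np.arange(n_samples), batch_idx] = 1.0
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n_samples:
            covariates = covariates.T
        design = np.hstack([B, covariates])
    else:
        design = B
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("covariate design is confounded with batch")
    beta_hat, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (k, n_genes)

    pi_b = counts / n_samples
    grand_mean = pi_b @ beta_hat[: len(levels)]  # alpha_g
    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if covariates is not None:
        cov_fit = covariates @ beta_hat[len(levels):]
        stand_mean = stand_mean + cov_fit.T
        design_coef = beta_hat[len(levels):]
    else:
        design_coef = None
    resid = X - (design @ beta_hat).T
    pooled_var = (resid**2).mean(axis=1)  # sigma2_g over all samples
    if np.any(pooled_var <= 0):
        raise ValueError("gene(s) with zero pooled variance; drop constant rows")
    Z = (X - stand_mean) / np.sqrt(pooled_var)[:, None]

    nb = len(levels)
    gamma_hat = np.empty((nb, n_genes))
    delta2_hat = np.empty((nb, n_genes))
    for b in range(nb):
        zb = Z[:, batch_idx == b]
        gamma_hat[b] = zb.mean(axis=1)
        delta2_hat[b] = zb.var(axis=1, ddof=1)

    g_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    lam = np.array([_aprior(delta2_hat[b]) for b in range(nb)])
    theta = np.array([_bprior(delta2_hat[b]) for b in range(nb)])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    iters = np.zeros(nb, dtype=int)
    for b in range(nb):
        n_b = counts[b]
        zb = Z[:, batch_idx == b]
        g_old = gamma_hat[b].copy()
        d_old = delta2_hat[b].copy()
        change = np.inf
        it = 0
        while change > tol:
            it += 1
            if it > max_iter:
                raise RuntimeError(
                    f"ComBat EB updates did not converge for batch {levels[b]!r} "
                    f"(last change {change:.3g} after {max_iter} iterations)"
                )
            g_new = (n_b * t2[b] * gamma_hat[b] + d_old * g_bar[b]) / (
                n_b * t2[b] + d_old
            )
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[b] + 0.5 * ss) / (n_b / 2.0 + lam[b] - 1.0)
            change = max(
                np.abs(g_new - g_old).max() / np.abs(g_old).max(),
                np.abs(d_new - d_old).max() / d_old.max(),
            )
            g_old, d_old = g_new, d_new
        gamma_star[b], delta2_star[b] = g_old, d_old
        iters[b] = it

    adjusted = Z.copy()
    for b in range(nb):
        cols = batch_idx == b
        adjusted[:, cols] = (adjusted[:, cols] - gamma_star[b][:, None]) / np.sqrt(
            delta2_star[b]
        )[:, None]
    adjusted = adjusted * np.sqrt(pooled_var)[:, None] + stand_mean

    out = ExpressionMatrix(
        gene_ids=matrix.gene_ids.copy(),
        sample_ids=matrix.sample_ids.copy(),
        values=adjusted,
        transform=matrix.transform,
        pseudocount=matrix.pseudocount,
        effective_libsizes=matrix.effective_libsizes,
    )
    params = ComBatParams(
        batches=levels,
        gamma_hat=gamma_hat,
        gamma_star=gamma_star,
        delta2_hat=delta2_hat,
        delta2_star=delta2_star,
        gamma_prior_mean=g_bar,
        gamma_prior_var=t2,
        delta_prior_shape=lam,
        delta_prior_scale=theta,
        grand_mean=grand_mean,
        pooled_var=pooled_var,
        design_coef=design_coef,
        n_iter=iters,
    )
    return out, params
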