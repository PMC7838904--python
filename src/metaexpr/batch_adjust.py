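"""Parametric empirical-Bayes location/scale batch adjustment.

Implements the standard parametric EB procedure for removing additive and
multiplicative batch effects from a genes x samples matrix while optionally
protecting biological covariates: per-gene standardization against a full
least-squares fit, method-of-moments hyperpriors (normal for locations,
inverse-gamma for scales), and the iterative posterior update run to
convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from metaexpr.core_io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Fitted batch-adjustment parameters.

    ``gamma_star``/``delta2_star`` are EB-shrunk per-gene, per-batch additive
    and multiplicative effects (genes x batches). ``grand_mean`` and
    ``var_pooled`` are the per-gene standardization parameters;
    ``covariate_coefs`` holds the protected-covariate coefficients
    (genes x covariate columns, empty when no covariates were supplied).
    """

    batches: list[str]
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    grand_mean: np.ndarray
    var_pooled: np.ndarray
    covariate_coefs: np.ndarray
    n_iterations: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.delta2_star <= 0):
            raise ValidationError("delta2_star must be strictly positive")


def _design_matrix(
    batch: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    levels = sorted(set(batch.tolist()))
    onehot = np.column_stack([(batch == b).astype(float) for b in levels])
    if covariates is not None:
        design = np.hstack([onehot, covariates])
    else:
        design = onehot
    return design, levels, onehot


def _covariate_columns(groups: np.ndarray) -> np.ndarray | None:
    """Treatment-coded dummy columns for a categorical covariate (ref dropped)."""
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        return None
    return np.column_stack([(groups == g).astype(float) for g in levels[1:]])


def combat_adjust(
    values: np.ndarray,
    batch: np.ndarray,
    covariates: np.ndarray | None = None,
    conv: float = 1e-6,
    max_iter: int = 5000,
    passthrough_single_batch: bool = False,
) -> tuple[np.ndarray, BatchModel]:
    """Remove batch effects from ``values`` (genes x samples) by parametric EB.

    Parameters
    ----------
    values
        Expression matrix, genes x samples, log scale.
    batch
        Per-sample batch labels; every batch needs >= 2 samples.
    covariates
        Optional design columns (e.g. biological-group dummies) whose effects
        are estimated jointly and protected from removal. May also be a 1-D
        array of categorical labels, which is dummy-coded internally.
    conv, max_iter
        Convergence tolerance and cap for the iterative posterior update.
    passthrough_single_batch
        With a single batch the precondition fails; set this flag to return
        the input unchanged instead.
    """
    values = np.asarray(values, dtype=float)
    batch = np.asarray(batch)
    if values.ndim != 2:
        raise ValidationError("values must be genes x samples")
    ngenes, nsamples = values.shape
    if batch.shape != (nsamples,):
        raise ValidationError("one batch label per sample required")

    levels, counts = np.unique(batch, return_counts=True)
    if len(levels) < 2:
        if passthrough_single_batch:
            model = BatchModel(
                batches=[str(levels[0])],
                gamma_star=np.zeros((ngenes, 1)),
                delta2_star=np.ones((ngenes, 1)),
                grand_mean=values.mean(axis=1),
                var_pooled=np.maximum(values.var(axis=1, ddof=1), 1e-12),
                covariate_coefs=np.zeros((ngenes, 0)),
                n_iterations=np.zeros(1, dtype=int),
            )
            return values.copy(), model
        raise ValidationError("batch adjustment needs >= 2 batches")
    small = [str(b) for b, c in zip(levels, counts) if c < 2]
    if small:
        raise ValidationError(f"batches with a single sample: {small}")

    if covariates is not None:
        covariates = np.asarray(covariates)
        if covariates.ndim == 1:
            covariates = _covariate_columns(covariates)
        if covariates is not None:
            covariates = np.asarray(covariates, dtype=float)
            if covariates.shape[0] != nsamples:
                raise ValidationError("covariates must have one row per sample")

    design, batch_levels, onehot = _design_matrix(batch, covariates)
    nbatch = len(batch_levels)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError(
            "design matrix is rank-deficient (covariates confounded with batch)"
        )

    # 1. per-gene least squares and standardization
    bhat, *_ = np.linalg.lstsq(design, values.T, rcond=None)  # params x genes
    batch_frac = counts / nsamples
    grand_mean = batch_frac @ bhat[:nbatch, :]  # per-gene weighted batch mean
    fitted_full = (design @ bhat).T
    var_pooled = ((values - fitted_full) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None] * np.ones((1, nsamples))
    if covariates is not None and covariates.shape[1] > 0:
        stand_mean = stand_mean + (covariates @ bhat[nbatch:, :]).T
    s_data = (values - stand_mean) / np.sqrt(var_pooled)[:, None]

    # 2. per-batch location/scale estimates on standardized data
    gamma_hat = np.empty((ngenes, nbatch))
    delta2_hat = np.empty((ngenes, nbatch))
    for j, b in enumerate(batch_levels):
        cols = batch == b
        gamma_hat[:, j] = s_data[:, cols].mean(axis=1)
        delta2_hat[:, j] = s_data[:, cols].var(axis=1, ddof=1)
    delta2_hat = np.maximum(delta2_hat, 1e-12)

    # 3. EB shrinkage with method-of-moments hyperpriors
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    tau2 = np.maximum(tau2, 1e-12)
    d_mean = delta2_hat.mean(axis=0)
    d_var = np.maximum(delta2_hat.var(axis=0, ddof=1), 1e-12)
    a_prior = (2 * d_var + d_mean**2) / d_var
    b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iterations = np.zeros(nbatch, dtype=int)
    for j, b in enumerate(batch_levels):
        cols = batch == b
        n_b = int(cols.sum())
        sdat = s_data[:, cols]
        g_old = gamma_hat[:, j].copy()
        d_old = delta2_hat[:, j].copy()
        for it in range(max_iter):
            g_new = (n_b * tau2[j] * gamma_hat[:, j] + d_old * gamma_bar[j]) / (
                n_b * tau2[j] + d_old
            )
            ssq = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (b_prior[j] + 0.5 * ssq) / (n_b / 2 + a_prior[j] - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        else:
            logger.warning("EB update for batch %s hit max_iter=%d", b, max_iter)
        n_iterations[j] = it + 1
        gamma_star[:, j] = g_old
        delta2_star[:, j] = np.maximum(d_old, 1e-12)

    # 4. remove shrunk effects, restore scale and structure
    adjusted = np.empty_like(values)
    for j, b in enumerate(batch_levels):
        cols = batch == b
        adjusted[:, cols] = (
            s_data[:, cols] - gamma_star[:, j][:, None]
        ) / np.sqrt(delta2_star[:, j])[:, None]
    adjusted = adjusted * np.sqrt(var_pooled)[:, None] + stand_mean

    cov_coefs = (
        bhat[nbatch:, :].T
        if covariates is not None and covariates.shape[1] > 0
        else np.zeros((ngenes, 0))
    )
    model = BatchModel(
        batches=[str(b) for b in batch_levels],
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        covariate_coefs=cov_coefs,
        n_iterations=n_iterations,
    )
    return adjusted, model
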