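"""Feature-level harmonization: probe collapsing, quantile normalization,
and the mean-variance precision-weight transform for count data."""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from metaexpr.core_io import ExpressionDataset, ProbeGeneMap, ValidationError

logger = logging.getLogger(__name__)


def collapse_probes_max_sd(
    ds: ExpressionDataset, probe_map: ProbeGeneMap
) -> ExpressionDataset:
    """Collapse probes to genes, keeping the probe with the largest sample SD.

    For each gene exactly one probe row survives and is relabeled to the gene
    id. SD uses denominator n-1. Ties are broken by the lexicographically
    smallest probe id. Probes absent from the map are dropped and logged.
    """
    if ds.feature_level != "probe":
        raise ValidationError("collapse_probes_max_sd expects a probe-level dataset")
    mapped_idx = [i for i, p in enumerate(ds.feature_ids) if p in probe_map]
    n_dropped = ds.n_features - len(mapped_idx)
    if n_dropped:
        logger.info("dropping %d probes absent from the probe map", n_dropped)
    if not mapped_idx:
        raise ValidationError("no probes in common between dataset and probe map")

    sds = np.std(ds.values, axis=1, ddof=1)
    best: dict[str, tuple[float, str, int]] = {}
    for i in mapped_idx:
        probe = ds.feature_ids[i]
        gene = probe_map[probe]
        key = (-sds[i], probe)  # max SD, then lexicographically smallest probe
        if gene not in best or key < (-best[gene][0], best[gene][1]):
            best[gene] = (sds[i], probe, i)
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return replace(
        ds,
        values=ds.values[rows, :],
        feature_ids=genes,
        feature_level="gene",
    )


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean-of-sorted-columns reference.

    After the transform every column has the same sorted value vector. Tied
    values within a column receive the mean of the reference values at the
    tied positions, which makes the operation idempotent.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValidationError("quantile normalization needs a matrix with >= 2 columns")
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # average reference over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        ref_sorted = reference.copy()
        for a, b in zip(starts, ends):
            if b - a > 1:
                ref_sorted[a:b] = ref_sorted[a:b].mean()
        assigned[order] = ref_sorted
        out[:, j] = assigned
    return out


def voom_transform(
    counts: np.ndarray,
    library_sizes: np.ndarray | None = None,
    group_labels: np.ndarray | None = None,
    span: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Transform counts to log-CPM with precision weights from the fitted
    mean-variance trend.

    log-CPM is the closed form ``log2((count + 0.5) / (lib + 1) * 1e6)``.
    The trend is a locally weighted linear regression (span ``span``) of
    per-gene residual sqrt-standard-deviation on mean log2-count, evaluated
    at per-observation fitted log-counts with linear extrapolation beyond the
    fitted range; weights are the inverse of the predicted variance
    (fourth power of the predicted sqrt-SD).

    Returns ``(logcpm, weights)``, both genes x samples; weights are strictly
    positive and finite.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValidationError("counts must be genes x samples")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValidationError("counts must be non-negative integers")
    ngenes, nsamples = counts.shape
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = np.asarray(library_sizes, dtype=float)
    if np.any(library_sizes <= 0):
        raise ValidationError("library sizes must be positive")

    logcpm = np.log2((counts + 0.5) / (library_sizes + 1.0) * 1e6)

    # per-gene fitted values: group means if labels given, else gene means
    if group_labels is not None:
        group_labels = np.asarray(group_labels)
        fitted = np.empty_like(logcpm)
        resid_df = nsamples
        for g in np.unique(group_labels):
            mask = group_labels == g
            if mask.sum() < 2:
                raise ValidationError(f"group {g!r} has fewer than 2 samples")
            fitted[:, mask] = logcpm[:, mask].mean(axis=1, keepdims=True)
            resid_df -= 1
    else:
        if nsamples < 2:
            raise ValidationError("voom needs at least 2 samples")
        fitted = logcpm.mean(axis=1, keepdims=True) * np.ones((1, nsamples))
        resid_df = nsamples - 1
    resid = logcpm - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / resid_df)
    sqrt_sd = np.sqrt(sigma)

    # mean log2-count per gene (depth-adjusted back to the count scale)
    mean_logcount = logcpm.mean(axis=1) + np.mean(np.log2(library_sizes + 1.0)) - np.log2(1e6)

    fit = lowess(sqrt_sd, mean_logcount, frac=span, return_sorted=True)
    fx, fy = fit[:, 0], fit[:, 1]
    fx, keep = np.unique(fx, return_index=True)
    fy = fy[keep]

    # fitted per-observation log-counts on the same scale as mean_logcount
    obs_logcount = fitted + (np.log2(library_sizes + 1.0) - np.log2(1e6))[None, :]
    pred = _interp_extrapolate(obs_logcount.ravel(), fx, fy).reshape(obs_logcount.shape)
    pred = np.clip(pred, 1e-6, None)  # keep weights finite and positive
    weights = 1.0 / pred**4
    return logcpm, weights


def _interp_extrapolate(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation using the end-segment slopes."""
    y = np.interp(x, xp, fp)
    if xp.size >= 2:
        left = x < xp[0]
        right = x > xp[-1]
        if left.any():
            slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y[left] = fp[0] + slope * (x[left] - xp[0])
        if right.any():
            slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y[right] = fp[-1] + slope * (x[right] - xp[-1])
    return y


def quantile_normalize_dataset(ds: ExpressionDataset) -> ExpressionDataset:
    """Dataset-level convenience wrapper around :func:`quantile_normalize`."""
    return replace(ds, values=quantile_normalize(ds.values))


def logcpm_frame(counts: pd.DataFrame) -> pd.DataFrame:
    """Closed-form log-CPM of a counts DataFrame (no weights)."""
    logcpm, _ = voom_transform(counts.to_numpy())
    return pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)
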