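"""Two-group differential expression with empirical-Bayes moderated t.

Per-gene (optionally precision-weighted) least-squares fits, variance
shrinkage toward a moment-estimated prior, two-sided p-values on the
augmented degrees of freedom, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from metaexpr.core_io import ValidationError

logger = logging.getLogger(__name__)

#: Cap applied when the moment estimator diverges (all variances equal).
MAX_PRIOR_DF = 1e6


@dataclass
class DEResult:
    """Per-gene differential-expression table for one platform/comparison."""

    platform_id: str
    comparison: str
    genes: list[str]
    log2fc: np.ndarray
    t_mod: np.ndarray
    df_total: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_case: int
    n_control: int
    prior_df: float = np.nan
    prior_var: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "log2fc": self.log2fc,
                "t": self.t_mod,
                "df": self.df_total,
                "p": self.p,
                "q": self.q,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def trigamma_inverse(x: float) -> float:
    """Solve ``trigamma(y) = x`` for y > 0 by Newton iteration."""
    if x <= 0:
        return MAX_PRIOR_DF
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match prior df ``d0`` and prior variance ``s0^2`` from the
    distribution of log residual variances (scaled-F model)."""
    ok = s2 > 0
    if ok.sum() < 2:
        return MAX_PRIOR_DF, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        d0 = min(d0, MAX_PRIOR_DF)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = MAX_PRIOR_DF
        s02 = np.exp(emean)
    return float(d0), float(s02)


def moderated_t(
    values: np.ndarray,
    group_labels: np.ndarray,
    case: str,
    control: str,
    weights: np.ndarray | None = None,
    platform_id: str = "",
    comparison: str = "",
    genes: list[str] | None = None,
    prior_df: float | None = None,
) -> DEResult:
    """Empirical-Bayes moderated two-group t-test per gene.

    Parameters
    ----------
    values
        Genes x samples matrix (log scale).
    group_labels
        Per-sample labels; samples not in ``case``/``control`` are ignored.
    weights
        Optional genes x samples precision weights (e.g. from the
        mean-variance transform); the fit becomes weighted least squares.
    prior_df
        Override for the prior degrees of freedom ``d0`` (0 disables
        moderation, recovering the ordinary t-test); estimated by moments
        when None.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    case_mask = group_labels == case
    ctrl_mask = group_labels == control
    n1, n2 = int(case_mask.sum()), int(ctrl_mask.sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"each group needs >= 2 samples (case={n1}, control={n2})"
        )
    keep = case_mask | ctrl_mask
    y = values[:, keep]
    x = case_mask[keep].astype(float)  # 1 = case
    ngenes, nsamples = y.shape
    df_resid = nsamples - 2
    if df_resid <= 0:
        raise ValidationError("zero residual degrees of freedom")

    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)[:, keep]
        if w.shape != y.shape or np.any(w <= 0):
            raise ValidationError("weights must be positive and match values")

    # per-gene WLS for model y = b0 + b1*x: closed form via weighted group means
    w1 = w * x[None, :]
    w2 = w * (1.0 - x)[None, :]
    sw1 = w1.sum(axis=1)
    sw2 = w2.sum(axis=1)
    mean1 = (w1 * y).sum(axis=1) / sw1
    mean2 = (w2 * y).sum(axis=1) / sw2
    log2fc = mean1 - mean2
    fitted = np.where(x[None, :] > 0.5, mean1[:, None], mean2[:, None])
    rss = (w * (y - fitted) ** 2).sum(axis=1)
    s2 = rss / df_resid
    unscaled_se2 = 1.0 / sw1 + 1.0 / sw2  # stderr^2 = s2 * unscaled_se2

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s02 = estimate_prior(s2, df_resid) if d0 > 0 else (0.0, 0.0)
    if d0 > 0:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
    else:
        s2_post = s2.copy()
    df_total = np.full(ngenes, min(df_resid + d0, MAX_PRIOR_DF))

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log2fc / np.sqrt(s2_post * unscaled_se2)
    degenerate = s2_post <= 0
    t_mod = np.where(degenerate, 0.0, t_mod)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    # degenerate rule: zero residual variance in both groups -> p = 1,
    # log2FC reported as computed
    zero_var = s2 == 0
    p = np.where(degenerate | zero_var, 1.0, p)
    t_mod = np.where(zero_var, 0.0, t_mod)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    if genes is None:
        genes = [f"g{i}" for i in range(ngenes)]
    return DEResult(
        platform_id=platform_id,
        comparison=comparison,
        genes=list(genes),
        log2fc=log2fc,
        t_mod=t_mod,
        df_total=df_total,
        p=p,
        q=bh_adjust(p),
        n_case=n1,
        n_control=n2,
        prior_df=d0,
        prior_var=s02 if d0 > 0 else np.nan,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j``, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
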