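"""Best-performing-cutoff stratification, Kaplan-Meier estimation, log-rank
testing, and univariate Cox proportional hazards for one gene's expression.

The cutoff scan evaluates every integer expression percentile between the
lower and upper quartile, keeps the split with the smallest log-rank p, and
reports that raw p. Minimum-p selection is anti-conservative by
construction (no multiplicity correction is applied); see the README.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from metaexpr.core_io import SurvivalTable, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    Each curve is a frame with columns ``time``, ``n_risk``, ``n_event``,
    ``n_censor``, ``survival``; it starts at (0, 1) and steps down at event
    times only.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValidationError("negative survival times")
    if groups is None:
        groups = np.zeros(times.size, dtype=object)
        groups[:] = "all"
    groups = np.asarray(groups, dtype=object)
    curves: dict[str, pd.DataFrame] = {}
    for g in sorted(set(groups.tolist()), key=str):
        mask = groups == g
        if not mask.any():
            raise ValidationError(f"empty group {g!r}")
        t, e = times[mask], events[mask]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t)
        rows = [{"time": 0.0, "n_risk": t.size, "n_event": 0, "n_censor": 0, "survival": 1.0}]
        surv = 1.0
        for u in uniq:
            at = t == u
            n_risk = int((t >= u).sum())
            d = int(e[at].sum())
            c = int((~e[at].astype(bool)).sum())
            if d > 0:
                surv *= 1.0 - d / n_risk
            rows.append(
                {"time": float(u), "n_risk": n_risk, "n_event": d, "n_censor": c, "survival": surv}
            )
        curves[str(g)] = pd.DataFrame(rows)
    return curves


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(
    times: np.ndarray,
    events: np.ndarray,
    group_indicator: np.ndarray,
) -> tuple[float, float]:
    """Standard unweighted two-group log-rank test.

    Returns ``(chi2, p)``; ``group_indicator`` is boolean/0-1 for group 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grp = np.asarray(group_indicator).astype(bool)
    if grp.all() or not grp.any():
        raise ValidationError("log-rank needs two non-empty groups")
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & grp).sum())
        dying = (times == t) & (events == 1)
        d = int(dying.sum())
        d1 = int((dying & grp).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariate)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    beta: float
    se: float
    hr: float
    ci_lower: float
    ci_upper: float
    wald_p: float
    n_iterations: int
    monotone: bool = False  # likelihood diverged (complete separation in time)


def _cox_derivatives(
    beta: float,
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
    ties: str,
) -> tuple[float, float, float]:
    """(log-likelihood, score, information) at beta for a scalar covariate."""
    eta = beta * x
    theta = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time
    t_s, e_s, x_s, th_s = times[order], events[order], x[order], theta[order]

    loglik = score = info = 0.0
    s0 = s1 = s2 = 0.0  # risk-set accumulators (entering as time decreases)
    i = 0
    n = times.size
    while i < n:
        t = t_s[i]
        j = i
        # add everyone with this time to the risk set
        while j < n and t_s[j] == t:
            s0 += th_s[j]
            s1 += x_s[j] * th_s[j]
            s2 += x_s[j] ** 2 * th_s[j]
            j += 1
        block = slice(i, j)
        dying = e_s[block] == 1
        d = int(dying.sum())
        if d > 0:
            xd = x_s[block][dying]
            thd = th_s[block][dying]
            t0, t1, t2 = thd.sum(), (xd * thd).sum(), (xd**2 * thd).sum()
            loglik += beta * xd.sum()
            score += xd.sum()
            for ell in range(d):
                f = ell / d if ties == "efron" else 0.0
                den = s0 - f * t0
                num1 = s1 - f * t1
                num2 = s2 - f * t2
                loglik -= np.log(den)
                score -= num1 / den
                info += num2 / den - (num1 / den) ** 2
        i = j
    return loglik, score, info


def cox_univariate(
    times: np.ndarray,
    events: np.ndarray,
    group_indicator: np.ndarray,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Univariate Cox partial-likelihood fit with Efron (default) or Breslow
    tie handling, Newton-Raphson to score < ``tol``.

    Monotone likelihood (all events in one group preceding the other's) is
    flagged and the confidence interval reported as unbounded.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(group_indicator, dtype=float)
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie handling {ties!r}")
    if np.ptp(x) == 0:
        raise ValidationError("group indicator is constant; effect inestimable")
    for level in np.unique(x):
        if events[x == level].sum() < 1:
            raise ValidationError("each group needs at least one event")

    beta = 0.0
    monotone = False
    it = 0
    for it in range(1, max_iter + 1):
        _, score, info = _cox_derivatives(beta, times, events, x, ties)
        if info <= 0:
            monotone = True
            break
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(beta) > 20:
            monotone = True
            break
        if abs(score) < tol:
            break
    _, _, info = _cox_derivatives(beta, times, events, x, ties)
    if monotone or info <= 0:
        logger.warning("monotone partial likelihood; CI unbounded")
        return CoxResult(
            beta=float(np.sign(beta) * np.inf) if monotone else beta,
            se=np.inf,
            hr=float(np.exp(np.sign(beta) * np.inf)) if beta != 0 else np.nan,
            ci_lower=0.0,
            ci_upper=np.inf,
            wald_p=1.0,
            n_iterations=it,
            monotone=True,
        )
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    zcrit = stats.norm.isf(0.025)
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - zcrit * se)),
        ci_upper=float(np.exp(beta + zcrit * se)),
        wald_p=float(2.0 * stats.norm.sf(abs(z))),
        n_iterations=it,
        monotone=False,
    )


# ---------------------------------------------------------------------------
# best-performing cutoff
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Result of dichotomizing one gene's expression at the best cutoff."""

    gene_id: str
    cutoff_percentile: int
    cutoff_value: float
    n_low: int
    n_high: int
    logrank_chi2: float
    logrank_p: float
    km_curves: dict[str, pd.DataFrame]
    cox: CoxResult

    def __post_init__(self) -> None:
        if not 25 <= self.cutoff_percentile <= 75:
            raise ValidationError("cutoff percentile must lie in [25, 75]")
        if self.n_low == 0 or self.n_high == 0:
            raise ValidationError("both expression groups must be non-empty")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": self.gene_id,
                    "cutoff_percentile": self.cutoff_percentile,
                    "cutoff_value": self.cutoff_value,
                    "n_low": self.n_low,
                    "n_high": self.n_high,
                    "logrank_chi2": self.logrank_chi2,
                    "logrank_p": self.logrank_p,
                    "hr": self.cox.hr,
                    "hr_ci_lower": self.cox.ci_lower,
                    "hr_ci_upper": self.cox.ci_upper,
                    "wald_p": self.cox.wald_p,
                }
            ]
        )


def best_cutoff_stratify(
    expr: pd.Series | dict[str, float] | np.ndarray,
    surv: SurvivalTable,
    gene_id: str = "",
    percentile_range: tuple[int, int] = (25, 75),
) -> SurvivalFit:
    """Scan integer expression percentiles in ``percentile_range`` and keep
    the dichotomization (high = expression >= cutoff) with minimum log-rank p.

    Ties go to the percentile closest to the median, then the lower one.
    Splits leaving a group empty are skipped; if every split is skipped
    (e.g. constant expression), an error is raised.
    """
    if isinstance(expr, dict):
        expr = pd.Series(expr)
    if isinstance(expr, pd.Series):
        missing = [s for s in surv.sample_ids if s not in expr.index]
        if missing:
            raise ValidationError(f"expression missing for samples: {missing[:5]}")
        values = expr.loc[surv.sample_ids].to_numpy(dtype=float)
    else:
        values = np.asarray(expr, dtype=float)
        if values.shape != (len(surv),):
            raise ValidationError("expression length must match survival table")
    if len(surv) < 10:
        raise ValidationError("need >= 10 samples with survival records")
    if surv.event.sum() < 1:
        raise ValidationError("need at least one observed event")

    lo, hi = percentile_range
    best: tuple[float, int] | None = None  # (p, percentile)
    results: dict[int, tuple[float, float, float]] = {}
    for pct in range(lo, hi + 1):
        cutoff = float(np.percentile(values, pct))
        high = values >= cutoff
        if high.all() or not high.any():
            continue
        chi2, p = logrank_test(surv.time, surv.event, high)
        results[pct] = (cutoff, chi2, p)
        key = (p, abs(pct - 50), pct)
        if best is None or key < (best[0], abs(best[1] - 50), best[1]):
            best = (p, pct)
    if best is None:
        raise ValidationError("no valid split found (constant expression?)")

    pct = best[1]
    cutoff, chi2, p = results[pct]
    high = values >= cutoff
    labels = np.where(high, "high", "low")
    try:
        cox = cox_univariate(surv.time, surv.event, high.astype(float))
    except ValidationError as exc:  # e.g. zero events in one group
        logger.warning("Cox fit unavailable at the selected cutoff: %s", exc)
        cox = CoxResult(
            beta=np.nan,
            se=np.inf,
            hr=np.nan,
            ci_lower=0.0,
            ci_upper=np.inf,
            wald_p=1.0,
            n_iterations=0,
            monotone=True,
        )
    return SurvivalFit(
        gene_id=gene_id,
        cutoff_percentile=pct,
        cutoff_value=cutoff,
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        logrank_chi2=chi2,
        logrank_p=p,
        km_curves=km_estimate(surv.time, surv.event, labels),
        cox=cox,
    )
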