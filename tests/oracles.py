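"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic from first principles with
plain loops and scipy building blocks, staying independent of the package's
vectorized implementations.
"""

import math

import numpy as np
from scipy import special, stats


def oracle_two_sample_t(y, labels, case, control):
    """Ordinary pooled-variance two-sample t per gene (loops)."""
    out = []
    for row in y:
        a = [v for v, l in zip(row, labels) if l == case]
        b = [v for v, l in zip(row, labels) if l == control]
        n1, n2 = len(a), len(b)
        fc = np.mean(a) - np.mean(b)
        ss = sum((v - np.mean(a)) ** 2 for v in a) + sum(
            (v - np.mean(b)) ** 2 for v in b
        )
        s2 = ss / (n1 + n2 - 2)
        t = fc / math.sqrt(s2 * (1 / n1 + 1 / n2))
        out.append((fc, t, s2))
    return out


def oracle_moderated_t(y, labels, case, control):
    """Separate implementation of the EB moderated t (loops + closed forms)."""
    basic = oracle_two_sample_t(y, labels, case, control)
    n1 = sum(1 for l in labels if l == case)
    n2 = sum(1 for l in labels if l == control)
    df = n1 + n2 - 2
    s2 = np.array([b[2] for b in basic])
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        # invert trigamma by bisection (independent of the package's Newton)
        lo, hi = 1e-8, 1e8
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if special.polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0 = 2 * math.sqrt(lo * hi)
        s02 = math.exp(
            np.mean(e) + special.digamma(d0 / 2) - math.log(d0 / 2)
        )
    else:
        d0 = 1e6
        s02 = math.exp(np.mean(e))
    results = []
    for fc, _, s2g in basic:
        s2post = (d0 * s02 + df * s2g) / (d0 + df)
        t = fc / math.sqrt(s2post * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), df + d0)
        results.append((fc, t, p, d0, s02))
    return results


def oracle_bh(pvals):
    """Definitional BH: q_(i) = min_{j>=i} m p_(j)/j, via explicit loops."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [None] * m
    for rank_idx, i in enumerate(order, start=1):
        candidates = []
        for rank_j in range(rank_idx, m + 1):
            j = order[rank_j - 1]
            candidates.append(m * pvals[j] / rank_j)
        q[i] = min(1.0, min(candidates))
    return q


def oracle_icc(xa, xb):
    """Double-loop integrative correlation for two gene x sample arrays."""
    g = xa.shape[0]
    out = []
    for i in range(g):
        va, vb = [], []
        for j in range(g):
            if j == i:
                continue
            va.append(stats.pearsonr(xa[i], xa[j])[0])
            vb.append(stats.pearsonr(xb[i], xb[j])[0])
        out.append(stats.pearsonr(va, vb)[0])
    return np.array(out)


def oracle_weighted_stouffer(pvals, fcs, iccs):
    """Direct evaluation of the weighted combination for one gene."""
    zs, ws = [], []
    for p, fc, icc in zip(pvals, fcs, iccs):
        z = stats.norm.isf(p / 2)
        if fc < 0:
            z = -z
        w = abs(fc) + abs(fc) * icc**2
        zs.append(z)
        ws.append(w)
    zc = sum(w * z for w, z in zip(ws, zs)) / math.sqrt(sum(w**2 for w in ws))
    pc = 2 * stats.norm.sf(abs(zc))
    return zc, pc


def oracle_fisher_enrichment(n_universe, n_set, n_query, overlap):
    """P(X >= overlap) for X ~ Hypergeom by explicit summation."""
    total = 0.0
    for k in range(overlap, min(n_set, n_query) + 1):
        total += (
            math.comb(n_set, k)
            * math.comb(n_universe - n_set, n_query - k)
            / math.comb(n_universe, n_query)
        )
    return total


def oracle_km(times, events):
    """Hand product-limit estimator; returns {event_time: survival}."""
    surv = 1.0
    out = {}
    for t in sorted(set(times)):
        n_risk = sum(1 for u in times if u >= t)
        d = sum(1 for u, e in zip(times, events) if u == t and e == 1)
        if d:
            surv *= 1 - d / n_risk
        out[t] = surv
    return out
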