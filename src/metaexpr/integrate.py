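"""Cross-platform integration: integrative correlation coefficients, the
weighted Stouffer combination W = |log2FC| * (1 + ICC^2), integration-driven
discovery rates, cross-dataset concordance curves, and top-k selection.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from metaexpr.core_io import ValidationError
from metaexpr.diffexp import DEResult, bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# integrative correlation
# ---------------------------------------------------------------------------

@dataclass
class ICCTable:
    """Per-gene integrative correlation coefficients across platform pairs.

    ``pairwise`` maps (platform_a, platform_b) -> Series of per-gene ICCs
    indexed by the pair's shared-gene universe.
    """

    pairwise: dict[tuple[str, str], pd.Series]
    platforms: list[str]

    def summary(self) -> pd.Series:
        """Per-gene mean ICC over available pairs; genes on < 2 platforms
        have no pair and get 0 by convention."""
        if not self.pairwise:
            return pd.Series(dtype=float)
        frame = pd.DataFrame(self.pairwise)
        return frame.mean(axis=1).fillna(0.0)

    def platform_icc(self, platform: str) -> pd.Series:
        """Per-gene mean ICC over pairs involving ``platform``."""
        cols = {
            pair: s for pair, s in self.pairwise.items() if platform in pair
        }
        if not cols:
            return pd.Series(dtype=float)
        return pd.DataFrame(cols).mean(axis=1).fillna(0.0)

    def icc_for(self, gene: str, platform: str) -> float:
        vals = [
            s.loc[gene]
            for pair, s in self.pairwise.items()
            if platform in pair and gene in s.index and not math.isnan(s.loc[gene])
        ]
        return float(np.mean(vals)) if vals else 0.0


#: Above this many shared genes the pairwise ICC switches to a float32
#: fast path (memory-bandwidth bound elementwise ops); small fixtures keep
#: full double precision for oracle-equivalence testing.
_FAST_PATH_MIN_GENES = 1500


def _row_correlation_matrix(x: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Gene x gene Pearson correlation; zero-variance rows yield NaN rows."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (xc / norms[:, None]).astype(dtype)
    return z @ z.T


def _pair_icc(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Per-gene Pearson correlation between the two platforms' gene-gene
    correlation profiles, self-correlation excluded, fully vectorized.

    Callers must remove zero-variance genes beforehand.
    """
    g = xa.shape[0]
    dtype = np.float32 if g > _FAST_PATH_MIN_GENES else np.float64
    ca = _row_correlation_matrix(xa, dtype)
    cb = _row_correlation_matrix(xb, dtype)
    n = g - 1  # profile length after removing the self term
    da = np.diag(ca).astype(np.float64)
    db = np.diag(cb).astype(np.float64)
    sa = ca.sum(axis=1, dtype=np.float64) - da
    sb = cb.sum(axis=1, dtype=np.float64) - db
    sab = np.einsum("ij,ij->i", ca, cb, dtype=np.float64) - da * db
    saa = np.einsum("ij,ij->i", ca, ca, dtype=np.float64) - da**2
    sbb = np.einsum("ij,ij->i", cb, cb, dtype=np.float64) - db**2
    num = n * sab - sa * sb
    den = np.sqrt(np.maximum(n * saa - sa**2, 0.0) * np.maximum(n * sbb - sb**2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.where(np.isfinite(r), r, 0.0)
    return np.clip(r, -1.0, 1.0)


def integrative_correlation(
    matrices: dict[str, pd.DataFrame],
) -> ICCTable:
    """Integrative correlation coefficients for every platform pair.

    ``matrices`` maps platform id -> gene x sample DataFrame. For each pair
    the shared-gene universe is intersected; a gene's ICC for the pair is
    the Pearson correlation between its within-platform correlation profiles
    (correlation of the gene with every other shared gene). Zero-variance
    genes get ICC 0 and are logged.
    """
    if len(matrices) < 2:
        raise ValidationError("integrative correlation needs >= 2 platforms")
    platforms = sorted(matrices)
    pairwise: dict[tuple[str, str], pd.Series] = {}
    for pa, pb in itertools.combinations(platforms, 2):
        shared = matrices[pa].index.intersection(matrices[pb].index).sort_values()
        if len(shared) < 3:
            raise ValidationError(
                f"platforms {pa}/{pb} share only {len(shared)} genes (need >= 3)"
            )
        xa = matrices[pa].loc[shared].to_numpy(dtype=float)
        xb = matrices[pb].loc[shared].to_numpy(dtype=float)
        zero_var = (xa.std(axis=1) == 0) | (xb.std(axis=1) == 0)
        if zero_var.any():
            logger.info(
                "pair (%s, %s): %d zero-variance genes get ICC 0",
                pa,
                pb,
                int(zero_var.sum()),
            )
        valid = ~zero_var
        if valid.sum() < 3:
            raise ValidationError(
                f"platforms {pa}/{pb}: fewer than 3 genes with variance"
            )
        icc = np.zeros(len(shared))
        icc[valid] = _pair_icc(xa[valid], xb[valid])
        pairwise[(pa, pb)] = pd.Series(icc, index=shared)
    return ICCTable(pairwise=pairwise, platforms=platforms)


# ---------------------------------------------------------------------------
# weighted Stouffer combination
# ---------------------------------------------------------------------------

def stouffer_weight(log2fc, icc):
    """Integration weight ``|log2FC| + |log2FC| * ICC^2``.

    Lies in [|log2FC|, 2|log2FC|] for ICC in [-1, 1].
    """
    log2fc = np.asarray(log2fc, dtype=float)
    icc = np.asarray(icc, dtype=float)
    if np.any(np.abs(icc) > 1 + 1e-12):
        raise ValidationError("ICC must lie in [-1, 1]")
    w = np.abs(log2fc) * (1.0 + icc**2)
    return float(w) if w.ndim == 0 else w


@dataclass
class IntegrationResult:
    """Combined cross-platform ranking for one comparison.

    ``table`` is indexed by gene with columns ``n_platforms``, ``z_combined``,
    ``p_combined``, ``q``, ``rank`` and per-platform ``z_<pid>``, ``w_<pid>``,
    ``fc_<pid>`` (NaN where the gene was not measured).
    """

    comparison: str
    platforms: list[str]
    table: pd.DataFrame

    def top_genes(self, k: int) -> list[str]:
        if k > len(self.table):
            raise ValidationError(
                f"k={k} exceeds the {len(self.table)} ranked genes"
            )
        return self.table.sort_values("rank").index[:k].tolist()

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.12g")


def signed_z(p: np.ndarray, log2fc: np.ndarray) -> np.ndarray:
    """Signed normal quantile: ``sign(log2FC) * Phi^-1(1 - p/2)``.

    p = 0 is clamped to the smallest positive normal float (logged).
    """
    p = np.asarray(p, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    tiny = np.finfo(float).tiny
    if np.any(p < tiny):
        logger.info("clamping %d zero p-values to %g", int((p < tiny).sum()), tiny)
    p = np.clip(p, tiny, 1.0)
    z_mag = stats.norm.isf(p / 2.0)
    sign = np.where(log2fc < 0, -1.0, 1.0)
    return sign * z_mag


def combine_platforms(
    de_results: list[DEResult],
    icc: ICCTable | dict[str, pd.Series] | None,
    comparison: str | None = None,
) -> IntegrationResult:
    """ICC-weighted Stouffer combination of per-platform DE evidence.

    Each gene is combined over exactly the platforms where it was measured.
    Per platform, ``Z_i = sign(log2FC_i) * Phi^-1(1 - p_i/2)`` and
    ``W_i = |log2FC_i| * (1 + ICC_i^2)``; the combined statistic is
    ``Z = sum(W_i Z_i) / sqrt(sum(W_i^2))`` with two-sided normal p, BH q
    over all genes, and rank by ascending p (ties broken by descending mean
    |log2FC|, then gene id). Genes with all weights zero get Z = 0, p = 1.
    """
    if not de_results:
        raise ValidationError("need at least one DEResult")
    if comparison is None:
        comparison = de_results[0].comparison
    platforms = [de.platform_id for de in de_results]
    if len(set(platforms)) != len(platforms):
        raise ValidationError("duplicate platform ids in DE results")

    per_platform: dict[str, pd.DataFrame] = {}
    for de in de_results:
        z = signed_z(de.p, de.log2fc)
        if icc is None:
            icc_vals = pd.Series(0.0, index=de.genes)
        elif isinstance(icc, ICCTable):
            icc_vals = icc.platform_icc(de.platform_id).reindex(de.genes).fillna(0.0)
        else:
            icc_vals = icc.get(de.platform_id, pd.Series(dtype=float))
            icc_vals = icc_vals.reindex(de.genes).fillna(0.0)
        w = stouffer_weight(de.log2fc, icc_vals.to_numpy())
        per_platform[de.platform_id] = pd.DataFrame(
            {"z": z, "w": w, "fc": de.log2fc}, index=de.genes
        )

    genes = sorted(set().union(*(df.index for df in per_platform.values())))
    zmat = pd.DataFrame(index=genes, columns=platforms, dtype=float)
    wmat = pd.DataFrame(index=genes, columns=platforms, dtype=float)
    fcmat = pd.DataFrame(index=genes, columns=platforms, dtype=float)
    for pid, df in per_platform.items():
        zmat.loc[df.index, pid] = df["z"]
        wmat.loc[df.index, pid] = df["w"]
        fcmat.loc[df.index, pid] = df["fc"]

    zv = zmat.to_numpy()
    wv = wmat.to_numpy()
    present = ~np.isnan(zv)
    wz = np.nansum(np.where(present, wv * zv, 0.0), axis=1)
    w2 = np.nansum(np.where(present, wv**2, 0.0), axis=1)
    all_zero = w2 <= 0
    if all_zero.any():
        logger.info("%d genes with all-zero weights get Z = 0", int(all_zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_comb = wz / np.sqrt(w2)
    z_comb = np.where(all_zero, 0.0, z_comb)
    p_comb = 2.0 * stats.norm.sf(np.abs(z_comb))
    p_comb = np.clip(p_comb, np.finfo(float).tiny, 1.0)
    q = bh_adjust(p_comb)

    mean_abs_fc = np.nanmean(np.abs(fcmat.to_numpy()), axis=1)
    order = pd.DataFrame(
        {"p": p_comb, "neg_fc": -mean_abs_fc, "gene": genes}
    ).sort_values(["p", "neg_fc", "gene"], kind="stable")
    rank = np.empty(len(genes), dtype=int)
    rank[order.index.to_numpy()] = np.arange(1, len(genes) + 1)

    table = pd.DataFrame(
        {
            "n_platforms": present.sum(axis=1),
            "z_combined": z_comb,
            "p_combined": p_comb,
            "q": q,
            "rank": rank,
            "mean_abs_log2fc": mean_abs_fc,
        },
        index=pd.Index(genes, name="gene"),
    )
    for pid in platforms:
        table[f"z_{pid}"] = zmat[pid]
        table[f"w_{pid}"] = wmat[pid]
        table[f"fc_{pid}"] = fcmat[pid]
    return IntegrationResult(comparison=comparison, platforms=platforms, table=table)


# ---------------------------------------------------------------------------
# IDR and concordance curves
# ---------------------------------------------------------------------------

@dataclass
class IDRCurve:
    """Integration-driven discovery rate over a grid of |Z| thresholds."""

    comparison: str
    z_grid: np.ndarray
    n_combined_significant: np.ndarray
    n_exclusive: np.ndarray
    idr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z_grid,
                "n_combined_significant": self.n_combined_significant,
                "n_exclusive": self.n_exclusive,
                "idr": self.idr,
            }
        )


def idr_curve(res: IntegrationResult, z_grid: np.ndarray | None = None) -> IDRCurve:
    """Fraction of combined-significant genes missed by every single platform.

    At each threshold z the denominator counts genes with |combined Z| >= z;
    the numerator those among them with |Z_i| < z on every platform where
    the gene was measured. Empty denominator yields idr = 0 by convention.
    """
    if z_grid is None:
        z_grid = np.arange(0.0, 8.0 + 1e-9, 0.1)
    z_grid = np.asarray(z_grid, dtype=float)
    zc = np.abs(res.table["z_combined"].to_numpy())
    zp = np.abs(res.table[[f"z_{p}" for p in res.platforms]].to_numpy())
    n_comb = np.empty(z_grid.size, dtype=int)
    n_excl = np.empty(z_grid.size, dtype=int)
    for i, z in enumerate(z_grid):
        sig = zc >= z
        # platform NaN (gene absent) must not count as detection
        detected_any = np.nanmax(np.where(np.isnan(zp), -np.inf, zp), axis=1) >= z
        n_comb[i] = int(sig.sum())
        n_excl[i] = int((sig & ~detected_any).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        idr = np.where(n_comb > 0, n_excl / np.maximum(n_comb, 1), 0.0)
    return IDRCurve(
        comparison=res.comparison,
        z_grid=z_grid,
        n_combined_significant=n_comb,
        n_exclusive=n_excl,
        idr=idr,
    )


@dataclass
class ConcordanceCurve:
    """Fraction of consistently deregulated genes among the top-k ranked."""

    comparison: str
    k_grid: np.ndarray
    fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_grid, "fraction": self.fraction})


def concordance_curve(
    res: IntegrationResult,
    dataset_log2fc: dict[str, pd.Series],
    k_grid: np.ndarray | None = None,
    fc_cut: float = 1.0,
) -> ConcordanceCurve:
    """Cross-dataset concordance of the combined ranking.

    A gene is consistently deregulated when, in at least half of the
    datasets (ceil(n/2)), its log2FC exceeds ``fc_cut`` in the same
    direction (all qualifying datasets up, or all down). Requires >= 2
    datasets for the comparison.
    """
    if len(dataset_log2fc) < 2:
        raise ValidationError("concordance needs >= 2 datasets for the comparison")
    if k_grid is None:
        k_grid = np.arange(50, 2001, 50)
    k_grid = np.asarray(k_grid, dtype=int)
    if k_grid.size == 0:
        raise ValidationError("empty k grid")
    n_datasets = len(dataset_log2fc)
    need = math.ceil(n_datasets / 2)

    ranked = res.table.sort_values("rank").index
    fc = pd.DataFrame({d: s for d, s in dataset_log2fc.items()}).reindex(ranked)
    up = (fc > fc_cut).sum(axis=1).to_numpy()
    down = (fc < -fc_cut).sum(axis=1).to_numpy()
    concordant = (up >= need) | (down >= need)

    fraction = np.empty(k_grid.size)
    cum = np.concatenate(([0], np.cumsum(concordant)))
    for i, k in enumerate(k_grid):
        kk = min(int(k), len(ranked))
        fraction[i] = cum[kk] / kk if kk > 0 else 0.0
    return ConcordanceCurve(comparison=res.comparison, k_grid=k_grid, fraction=fraction)


def select_top_k(curves: list[ConcordanceCurve], default_k: int = 500) -> int:
    """Pick the grid k where the concordance curves are closest together.

    Returns the k minimizing the spread (max - min) of the curves' fractions;
    with a single curve or a flat spread profile, returns ``default_k``.
    Ties among minimizers go to the k closest to ``default_k`` (then the
    smaller k).
    """
    if not curves:
        raise ValidationError("no concordance curves supplied")
    grid = curves[0].k_grid
    if grid.size == 0:
        raise ValidationError("empty k grid")
    for c in curves[1:]:
        if not np.array_equal(c.k_grid, grid):
            raise ValidationError("concordance curves must share a k grid")
    if len(curves) == 1:
        return default_k
    fractions = np.vstack([c.fraction for c in curves])
    spread = fractions.max(axis=0) - fractions.min(axis=0)
    if np.allclose(spread, spread[0]):
        return default_k
    min_spread = spread.min()
    candidates = grid[np.isclose(spread, min_spread)]
    best = candidates[np.lexsort((candidates, np.abs(candidates - default_k)))][0]
    return int(best)
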