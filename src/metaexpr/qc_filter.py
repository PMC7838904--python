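"""Sample- and gene-level filters applied before integration.

Covers the tumor-content threshold, stromal-gene removal, a robust PCA
outlier flagger, and the assessment of biological- versus dataset-effect
strength via pairwise sample similarities.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from metaexpr.core_io import (
    ExpressionDataset,
    TUMOR_GROUPS,
    ValidationError,
    load_gene_list,
)

logger = logging.getLogger(__name__)


def filter_by_tumor_content(
    ds: ExpressionDataset, threshold: float = 0.40
) -> ExpressionDataset:
    """Drop tumor-bearing samples whose known tumor content is below ``threshold``.

    The bound is inclusive: content == threshold passes ("minimum acceptable").
    Control/HGPIN samples and samples with unknown content are always kept.
    """
    if not 0 <= threshold <= 1:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    if ds.tumor_content is None:
        logger.info("%s: no tumor_content recorded; filter is a no-op", ds.dataset_id)
        return ds
    groups = ds.groups_array()
    is_tumor = np.isin(groups, list(TUMOR_GROUPS))
    known = ~np.isnan(ds.tumor_content)
    drop = is_tumor & known & (ds.tumor_content < threshold)
    n_unknown_tumor = int((is_tumor & ~known).sum())
    if n_unknown_tumor:
        logger.info(
            "%s: %d tumor samples with unknown content retained",
            ds.dataset_id,
            n_unknown_tumor,
        )
    if drop.all():
        raise ValidationError("tumor-content filter removed every sample")
    logger.info(
        "%s: tumor-content filter removed %d of %d samples (threshold %.2f)",
        ds.dataset_id,
        int(drop.sum()),
        ds.n_samples,
        threshold,
    )
    out = ds.subset_samples(~drop)
    if out.n_samples == 0:
        raise ValidationError("tumor-content filter removed every sample")
    return out


def remove_stromal_genes(
    ds: ExpressionDataset,
    gene_lists: Iterable[str | Path | Sequence[str]],
) -> ExpressionDataset:
    """Drop every gene in the union of the supplied lists from the matrix.

    Each entry of ``gene_lists`` is a path to a plain-text gene list or an
    in-memory sequence of symbols. Genes absent from the matrix are ignored.
    """
    if ds.feature_level != "gene":
        raise ValidationError("stromal filtering requires a gene-level dataset")
    union: set[str] = set()
    for i, entry in enumerate(gene_lists):
        if isinstance(entry, (str, Path)):
            genes = load_gene_list(entry)
        else:
            genes = [str(g) for g in entry]
        logger.info("stromal list %d: %d genes", i + 1, len(genes))
        union.update(genes)
    present = union & set(ds.feature_ids)
    absent = union - present
    if absent:
        logger.info("%d listed genes absent from matrix; ignored", len(absent))
    logger.info(
        "removing %d of %d genes (list union %d)",
        len(present),
        ds.n_features,
        len(union),
    )
    keep = [i for i, g in enumerate(ds.feature_ids) if g not in present]
    return ds.subset_features(keep)


def pca_outlier_flags(
    ds: ExpressionDataset,
    n_components: int = 3,
    mad_multiplier: float = 4.0,
) -> np.ndarray:
    """Flag samples far from the bulk in leading principal-component space.

    A sample is flagged when its score on any of the first ``n_components``
    components lies more than ``mad_multiplier`` scaled-MAD units from that
    component's median. Zero-variance components are skipped. Deterministic
    given the input; invariant to sample order and global additive shifts.
    """
    if ds.n_samples < 3:
        raise ValidationError("PCA outlier flagging needs at least 3 samples")
    if n_components > min(ds.n_features, ds.n_samples):
        raise ValidationError(
            f"n_components={n_components} exceeds min(features, samples)"
        )
    x = ds.values.T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    # SVD-based scores; deterministic sign is irrelevant for |deviation|
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    flags = np.zeros(ds.n_samples, dtype=bool)
    for j in range(min(n_components, scores.shape[1])):
        col = scores[:, j]
        if s[j] <= 1e-10 * max(1.0, s[0]):
            continue  # zero-variance component
        med = np.median(col)
        mad = stats.median_abs_deviation(col, scale="normal")
        if mad == 0:
            continue
        flags |= np.abs(col - med) > mad_multiplier * mad
    return flags


@dataclass
class EffectStrengthReport:
    """Pairwise-similarity comparison of biological vs dataset effects."""

    within_group_cross_dataset_sims: np.ndarray
    within_dataset_cross_group_sims: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    alpha: float = 0.05

    @property
    def biological_stronger(self) -> bool:
        """True iff cross-dataset same-group pairs are more similar than
        same-dataset cross-group pairs (median rule) at significance alpha."""
        return (
            float(np.median(self.within_group_cross_dataset_sims))
            > float(np.median(self.within_dataset_cross_group_sims))
            and self.ks_pvalue < self.alpha
        )


def effect_strength_assessment(
    datasets: Sequence[ExpressionDataset],
    alpha: float = 0.05,
    max_pairs_per_list: int | None = 20000,
    seed: int = 0,
) -> EffectStrengthReport:
    """Compare biological-group effects against dataset (batch) effects.

    Builds two distributions of Pearson sample-sample similarities over the
    shared-gene intersection: pairs from the same biological group but
    different datasets, and pairs from the same dataset but different groups,
    then runs a two-sided two-sample KS test. The KS test itself is
    unsigned; direction is established by comparing medians (see
    :attr:`EffectStrengthReport.biological_stronger`).
    """
    if len(datasets) < 2:
        raise ValidationError("effect-strength assessment needs >= 2 datasets")
    shared = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        shared &= set(ds.feature_ids)
    if len(shared) < 10:
        raise ValidationError(f"only {len(shared)} shared genes; need >= 10")
    shared_list = sorted(shared)

    # assemble one sample x gene matrix over the shared universe
    blocks, sample_ds, sample_grp = [], [], []
    for ds in datasets:
        idx = {g: i for i, g in enumerate(ds.feature_ids)}
        rows = [idx[g] for g in shared_list]
        blocks.append(ds.values[rows, :].T)
        sample_ds.extend([ds.dataset_id] * ds.n_samples)
        sample_grp.extend(ds.sample_groups)
    x = np.vstack(blocks)
    sample_ds_arr = np.asarray(sample_ds, dtype=object)
    sample_grp_arr = np.asarray(sample_grp, dtype=object)

    sims = np.corrcoef(x)  # sample x sample Pearson over shared genes
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    same_ds = sample_ds_arr[iu] == sample_ds_arr[ju]
    same_grp = sample_grp_arr[iu] == sample_grp_arr[ju]
    bio = sims[iu, ju][same_grp & ~same_ds]
    batch = sims[iu, ju][~same_grp & same_ds]
    if bio.size == 0:
        raise ValidationError("no same-group cross-dataset sample pairs")
    if batch.size == 0:
        raise ValidationError("no cross-group same-dataset sample pairs")
    if max_pairs_per_list is not None:
        rng = np.random.default_rng(seed)
        if bio.size > max_pairs_per_list:
            bio = rng.choice(bio, max_pairs_per_list, replace=False)
        if batch.size > max_pairs_per_list:
            batch = rng.choice(batch, max_pairs_per_list, replace=False)
    ks = stats.ks_2samp(bio, batch, alternative="two-sided")
    return EffectStrengthReport(
        within_group_cross_dataset_sims=bio,
        within_dataset_cross_group_sims=batch,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        alpha=alpha,
    )


def pairwise_shared_genes(datasets: Sequence[ExpressionDataset]) -> list[str]:
    """Genes measured in every dataset, sorted."""
    shared = set(datasets[0].feature_ids)
    for ds in datasets[1:]:
        shared &= set(ds.feature_ids)
    return sorted(shared)


def _all_pairs(items: Sequence) -> Iterable[tuple]:
    return itertools.combinations(items, 2)
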