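"""Multi-dataset, multi-platform synthetic expression and survival data with
recorded ground truth, so every pipeline stage is testable offline.

Expression model per dataset: value = gene baseline + group effect (planted
genes only) + per-gene batch location, with noise scaled by a per-gene batch
scale factor. Sequencing-style datasets emit negative-binomial counts whose
means come from the Gaussian model via ``exp2``. All randomness flows from a
single seed through per-dataset substreams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from metaexpr.core_io import ExpressionDataset, SurvivalTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneratorConfig:
    """Settings for :func:`generate_multiplatform`."""

    n_genes: int = 5000
    n_platforms: int = 3
    datasets_per_platform: int = 2
    samples_per_group: int = 15
    groups: tuple[str, ...] = ("control", "primary_tumor")
    de_fraction: float = 0.04
    effect_meanlog: float = 0.0
    effect_sdlog: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    batch_shift_sd: float = 0.5
    batch_scale_sdlog: float = 0.2
    coverage_fractions: tuple[float, ...] | None = None  # per platform
    noise_sd: tuple[float, ...] | None = None  # per platform
    platform_types: tuple[str, ...] | None = None  # "array" | "seq"
    nb_dispersion: float = 0.1
    seq_library_size: float = 2e6
    tumor_content_range: tuple[float, float] = (0.2, 0.95)

    def resolved(self) -> "GeneratorConfig":
        cfg = GeneratorConfig(**asdict(self))
        if cfg.coverage_fractions is None:
            cfg.coverage_fractions = tuple([1.0] * cfg.n_platforms)
        if cfg.noise_sd is None:
            cfg.noise_sd = tuple(
                1.0 + 0.25 * i for i in range(cfg.n_platforms)
            )
        if cfg.platform_types is None:
            cfg.platform_types = tuple(["array"] * cfg.n_platforms)
        if len(cfg.coverage_fractions) != cfg.n_platforms:
            raise ValidationError("one coverage fraction per platform required")
        if len(cfg.noise_sd) != cfg.n_platforms:
            raise ValidationError("one noise SD per platform required")
        if len(cfg.platform_types) != cfg.n_platforms:
            raise ValidationError("one platform type per platform required")
        if min(cfg.coverage_fractions) <= 0:
            raise ValidationError("coverage fractions must be positive")
        if not cfg.groups:
            raise ValidationError("at least one group required")
        if not 0 <= cfg.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")
        return cfg


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    seed: int
    de_genes: dict[str, dict[str, float]]  # comparison -> gene -> log2 effect
    batch_location: dict[str, dict[str, float]]  # dataset -> gene -> shift
    batch_scale: dict[str, dict[str, float]]  # dataset -> gene -> scale
    platform_coverage: dict[str, list[str]]
    tumor_content: dict[str, float]  # sample -> true fraction
    survival_effects: dict[str, dict] = field(default_factory=dict)

    def de_gene_ids(self, comparison: str) -> set[str]:
        return set(self.de_genes.get(comparison, {}))

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")


def generate_multiplatform(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Generate one dataset per (platform, replicate) with planted DE genes,
    batch effects, platform-specific coverage, and recorded truth.

    Same (config, seed) produces byte-identical outputs. Group effects are
    planted relative to the first group in ``config.groups`` (the control),
    and recorded per comparison as ``"<group>_vs_<control>"``.
    """
    cfg = (config or GeneratorConfig()).resolved()
    root = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    baseline = root.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)

    control = cfg.groups[0]
    # planted group effects: comparison -> per-gene effect vector
    effects: dict[str, np.ndarray] = {}
    de_genes: dict[str, dict[str, float]] = {}
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    for grp in cfg.groups[1:]:
        comp = f"{grp}_vs_{control}"
        eff = np.zeros(cfg.n_genes)
        if n_de > 0:
            idx = root.choice(cfg.n_genes, n_de, replace=False)
            mag = root.lognormal(cfg.effect_meanlog, cfg.effect_sdlog, n_de)
            sign = root.choice([-1.0, 1.0], n_de)
            eff[idx] = sign * mag
        effects[comp] = eff
        de_genes[comp] = {
            genes[i]: float(eff[i]) for i in np.flatnonzero(eff != 0)
        }

    # platform coverage subsets (comprehensive first platform)
    coverage: dict[str, list[str]] = {}
    platform_gene_idx: dict[str, np.ndarray] = {}
    for p in range(cfg.n_platforms):
        pid = f"platform{p + 1}"
        n_cov = max(3, int(round(cfg.coverage_fractions[p] * cfg.n_genes)))
        idx = np.sort(root.choice(cfg.n_genes, n_cov, replace=False))
        platform_gene_idx[pid] = idx
        coverage[pid] = [genes[i] for i in idx]

    datasets: list[ExpressionDataset] = []
    batch_location: dict[str, dict[str, float]] = {}
    batch_scale: dict[str, dict[str, float]] = {}
    tumor_content: dict[str, float] = {}
    tumor_groups = {"primary_tumor", "metastatic_primary_tumor", "metastasis"}

    for p in range(cfg.n_platforms):
        pid = f"platform{p + 1}"
        idx = platform_gene_idx[pid]
        for d in range(cfg.datasets_per_platform):
            did = f"{pid}_ds{d + 1}"
            rng = np.random.default_rng([seed, p, d])  # per-dataset substream
            gamma = rng.normal(0.0, cfg.batch_shift_sd, cfg.n_genes)
            delta = rng.lognormal(0.0, cfg.batch_scale_sdlog, cfg.n_genes)
            batch_location[did] = {genes[i]: float(gamma[i]) for i in idx}
            batch_scale[did] = {genes[i]: float(delta[i]) for i in idx}

            sample_ids, sample_groups, columns, tcs = [], [], [], []
            for grp in cfg.groups:
                comp = f"{grp}_vs_{control}"
                group_eff = effects.get(comp, np.zeros(cfg.n_genes))
                for s in range(cfg.samples_per_group):
                    sid = f"{did}_{grp}_s{s + 1}"
                    noise = rng.normal(0.0, cfg.noise_sd[p], cfg.n_genes)
                    col = baseline + group_eff + gamma + delta * noise
                    sample_ids.append(sid)
                    sample_groups.append(grp)
                    columns.append(col[idx])
                    if grp in tumor_groups:
                        tc = float(rng.uniform(*cfg.tumor_content_range))
                    else:
                        tc = float("nan")
                    tcs.append(tc)
                    if not np.isnan(tc):
                        tumor_content[sid] = tc
            values = np.column_stack(columns)
            if cfg.platform_types[p] == "seq":
                # NB counts with mean proportional to exp2 of the Gaussian model
                mu = np.exp2(values)
                mu = mu / mu.sum(axis=0, keepdims=True) * cfg.seq_library_size
                r = 1.0 / cfg.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-8)))
                values = counts.astype(float)
            datasets.append(
                ExpressionDataset(
                    dataset_id=did,
                    platform_id=pid,
                    values=values,
                    feature_ids=coverage[pid],
                    sample_ids=sample_ids,
                    sample_groups=sample_groups,
                    tumor_content=np.asarray(tcs),
                    feature_level="gene",
                )
            )
    truth = SyntheticTruth(
        seed=seed,
        de_genes=de_genes,
        batch_location=batch_location,
        batch_scale=batch_scale,
        platform_coverage=coverage,
        tumor_content=tumor_content,
    )
    return datasets, truth


def generate_survival(
    expr: pd.Series,
    true_hr: float,
    censoring_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.02,
    cutpoint: float | None = None,
) -> tuple[SurvivalTable, dict]:
    """Exponential survival with hazard multiplied by ``true_hr`` above the
    cutpoint (default: the expression median), plus independent uniform
    censoring tuned to approximately the requested censoring rate.

    Returns the table and a truth record (hr, cutpoint, achieved censoring).
    """
    if true_hr <= 0:
        raise ValidationError("true_hr must be positive")
    if not 0 <= censoring_rate < 1:
        raise ValidationError("censoring_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    values = expr.to_numpy(dtype=float)
    if cutpoint is None:
        cutpoint = float(np.median(values))
    high = values >= cutpoint
    hazard = baseline_hazard * np.where(high, true_hr, 1.0)
    event_times = rng.exponential(1.0 / hazard)

    if censoring_rate == 0:
        time, event = event_times, np.ones(values.size, dtype=int)
    else:
        # pick uniform-censoring horizon tau so E[fraction censored] matches
        h_levels, h_counts = np.unique(hazard, return_counts=True)
        weights = h_counts / h_counts.sum()

        def expected_censored(tau: float) -> float:
            return float(
                (weights * (1 - np.exp(-h_levels * tau)) / (h_levels * tau)).sum()
            )

        f = lambda tau: expected_censored(tau) - censoring_rate
        hi = 1.0
        while f(hi) > 0 and hi < 1e9:
            hi *= 10
        tau = brentq(f, 1e-9, hi)
        censor_times = rng.uniform(0, tau, values.size)
        event = (event_times <= censor_times).astype(int)
        time = np.minimum(event_times, censor_times)

    table = SurvivalTable(
        sample_ids=list(expr.index.astype(str)), time=time, event=event
    )
    truth = {
        "true_hr": float(true_hr),
        "cutpoint": cutpoint,
        "requested_censoring": float(censoring_rate),
        "achieved_censoring": float(1 - np.mean(event)),
        "seed": int(seed),
    }
    return table, truth
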