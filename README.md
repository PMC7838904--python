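# metaexpr

Cross-platform transcriptomics integration toolkit. It combines two-group
differential-expression evidence from multiple microarray/RNA-seq datasets
via an ICC-weighted Stouffer method, quantifies the integration gain (IDR),
selects stage-hallmark gene sets by cross-dataset concordance, assembles a
molecular alteration map (MAM) across disease-stage comparisons, and
stratifies survival by a best-performing expression cutoff.

## What it does

1. **Per-dataset preprocessing** (`core_io`, `qc_filter`, `preprocess`):
   TSV matrix/metadata loading; merging of `normal`/`BPH`/`NAD` samples into
   one `control` group; tumor-content filtering (default ≥ 0.40, inclusive;
   unknown content passes); stromal gene removal from plain-text lists;
   probe→gene collapsing by maximal sample SD; within-dataset quantile
   normalization; a voom-style log-CPM + precision-weight transform for
   count data; robust PCA outlier flagging and a biological-vs-dataset
   effect-strength KS assessment.
2. **Per-platform combination** (`batch_adjust`): parametric empirical-Bayes
   location/scale batch adjustment (ComBat algorithm) across same-platform
   datasets, protecting biological groups as covariates by default.
3. **Per-platform differential expression** (`diffexp`): empirical-Bayes
   moderated t with optional precision weights, and Benjamini–Hochberg
   correction.
4. **Integration** (`integrate`): per-gene integrative correlation
   coefficients across platform pairs; weighted Stouffer combination with
   `W = |log2FC| + |log2FC|·ICC²` and `Z = Σ W_i Z_i / sqrt(Σ W_i²)`; each
   gene is combined over exactly the platforms where it was measured;
   IDR curves (fraction of combined-significant genes missed by every single
   platform), cross-dataset concordance curves, and top-k selection
   (default k = 500).
5. **Map assembly + enrichment** (`mam`): boolean region patterns over the
   stage comparisons assign each top-k gene to named regions with
   per-comparison up/down direction; generic one-sided Fisher-exact
   over-representation against user gene sets (GMT).
6. **Survival** (`survival`): best-performing-cutoff dichotomization (scan of
   integer percentiles 25–75, minimum log-rank p), Kaplan–Meier curves, and
   univariate Cox (Efron ties) with HR and 95% CI.
   *Note*: the minimum-p cutoff scan is anti-conservative by construction —
   the selected p-value is reported raw, without multiplicity correction,
   and should be interpreted accordingly (the test suite demonstrates the
   inflation under the null).
7. **Synthetic data** (`synthetic_data`): a fully seeded multi-platform
   generator with planted DE effects, batch location/scale effects, platform
   coverage subsets, NB counts for sequencing-style platforms, tumor-content
   annotations, and expression-linked survival — every pipeline stage is
   testable offline with known ground truth.

## CLI

```bash
metaexpr simulate --seed 1 --n-genes 1000 --out sim/
metaexpr preprocess --matrix m.tsv --metadata meta.tsv --out-matrix p.tsv --out-metadata pm.tsv
metaexpr combine --matrix a.tsv --metadata am.tsv --matrix b.tsv --metadata bm.tsv --out adj.tsv
metaexpr diffexp --matrix adj.tsv --metadata am.tsv --case primary_tumor --control control --out de.tsv
metaexpr run-all --config config.yaml --out run/
metaexpr survival --matrix expr.tsv --table surv.tsv --gene AR --out fit.tsv
```

Exit codes: 0 success, 2 validation error, 3 runtime failure.

A minimal `config.yaml` for an end-to-end synthetic run:

```yaml
seed: 1
top_k: 500
tumor_content_threshold: 0.40
simulate:
  n_genes: 2000
  n_platforms: 3
  datasets_per_platform: 2
  samples_per_group: 15
  de_fraction: 0.04
comparisons:
  - {name: tumor_vs_control, case: primary_tumor, control: control}
```

Real data instead of simulation: replace `simulate:` with a `datasets:` list
of `{matrix, metadata, feature_level, probe_map, counts}` entries
(tab-separated matrices, features × samples, first column `feature_id`;
metadata columns `sample_id`, `dataset`, `platform`, `group`, optional
`tumor_content`). Stromal lists are plain text (one symbol per line, `#`
comments); region specs are YAML (`name`, `required_in`, `required_out`).

The run directory contains every intermediate table as TSV, a
`manifest.json` with versions/seed/config hash, and `pipeline.log`.

## Conventions worth knowing

- Expression values entering integration must be on a log2-like scale
  (arrays: log2 intensities; sequencing: log-CPM from the voom transform).
- Signed platform Z-scores: `Z_i = sign(log2FC_i) · Φ⁻¹(1 − p_i/2)`.
- Genes on a single platform are combined over that platform alone; genes
  with all-zero weights get Z = 0, p = 1.
- The tumor-content bound is inclusive (content = threshold passes); samples
  with unknown content pass.
- Rank ties break by descending mean |log2FC|, then gene id — output is
  deterministic.
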