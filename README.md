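# mfselector

Monotonic gene selection for staged (time-course) expression data.

Given a genes × samples expression matrix and an ordered assignment of
samples to `N` stages, `mfselector` scores every gene with a **total
discriminating error** (`de_total`): for each level `k = 1..N-1` it separates
stages `1..k` from the rest with the best horizontal discriminating line,
counts the samples on the wrong side, charges each sample at most once
across levels (one-time outlier masking), and sums the selected per-level
errors. Genes are then ranked with:

- pooled **permutation p- and q-values** of `de_total` (whole-label
  permutations shared across genes),
- **SVDE**, a noise-perturbation stability index that breaks ties among
  equal-`de_total` genes (add N(0, sd/10) noise, rescan, average the squared
  change over `M` replicates),
- filters `de_total <= 7`, `p < 1e-5` and `N-1` distinct discriminating
  lines (all configurable).

A weighted-rank (Cuzick-type) trend test is included as a comparator, and a
synthetic benchmark generator produces the 120-gene / 50-sample / 5-stage
dataset spanning nine monotonicity archetypes (good, slightly/moderately/
severely overlapping, outliers, partially ordered).

## CLI

```sh
# generate a synthetic benchmark (matrix, stage labels, truth files)
mfselector simulate --direction asc --seed 1 --out-prefix sim

# rank monotonic genes (defaults: B=500 permutations, M=100 SVDE replicates,
# de_total <= 7, p < 1e-5, distinct-lines filter on)
mfselector score sim.matrix.tsv sim.labels.tsv --direction both \
    --seed 1 --out ranked.tsv

# weighted-rank trend test per gene
mfselector cuzick sim.matrix.tsv sim.labels.tsv --direction asc
```

Inputs are delimited text: the matrix has a header row of sample ids and the
gene id in the first column; the label file has `sample<TAB>stage` rows
(stage order = first appearance, or set `stage_order` in a YAML `--config`).
`score --plot-data FILE` additionally exports a long-format
`(gene, sample_number, stage, value)` table for scatter-plot tooling.

## Library

```python
import mfselector as mf

ds = mf.make_dataset("ascending", seed=1)            # synthetic benchmark
scores = mf.score_matrix(ds.matrix, ds.design)       # de_total per gene/direction
pool = mf.build_null_pool(ds.matrix, ds.design, B=500, seed=1)
sv = mf.svde_matrix(ds.matrix, ds.design, "ascending", M=100, seed=1)
```

See `mfselector.pipeline.score_pipeline` for the full scored-and-ranked
path used by the CLI.

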