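# crossgex

Cross-domain translation of drug-induced gene-expression time series.

`crossgex` predicts a target domain's expression trajectory (e.g. human
in vitro, or rat in vivo) from a source domain's trajectory (rat in vitro)
for a previously unseen compound. It provides:

- **`crossgex.synthetic`** — a paired two-domain cohort generator with a
  shared compound×dose latent response, domain-specific time grids and
  replicate counts, replicate noise, a configurable fraction of constant
  (unresponsive) genes, and an exact noise-free oracle for the target-domain
  mean trajectory.
- **`crossgex.genesets`** — plain-text gene-set loading, nested random
  gene-set families (optionally ortholog-restricted), and a variance screen
  that rejects candidate sets whose mean per-gene variance falls more than a
  tolerance (default 3%) below a reference set's.
- **`crossgex.encoding`** — the level-plus-slope re-encoding of trajectories
  into [0, 1] (first entry per gene: scaled expression at the first time
  point; remaining entries: rescaled slopes between consecutive time
  points), its exact inverse, and flat / genes×time layouts.
- **`crossgex.pairing`** — learning examples by the full 2×2 replicate
  cross-product per compound-dose cell (controls enter as a fourth dose
  level), seeded discard of one of three in vivo replicates, and
  leave-one-compound-out splits.
- **`crossgex.models`** — five predictors behind one fit/predict contract:
  a dense bottleneck network (256-160-32-96-256), a modified autoencoder
  (70-70-60-70-70) initialised by grafting a source-domain autoencoder's
  encoder onto a target-domain autoencoder's decoder, a CNN whose kernels
  slide along the gene axis, k-nearest-neighbours, and a random regression
  forest. Networks are implemented in NumPy (no deep-learning framework
  required) with Adam, MAE loss and L1 activity regularization, and are
  bit-reproducible given a seed.
- **`crossgex.evaluation`** — leave-one-compound-out evaluation with the
  genes×time mean absolute error, paired two-tailed t-tests against the
  random-forest baseline with Benjamini–Hochberg correction, summary tables
  and per-gene prediction-overlay plots.

## Test

```bash
python -m pytest tests/
```

The suite includes property tests (hypothesis), finite-difference gradient
checks for the hand-written backpropagation, and an acceptance suite
(`tests/test_acceptance.py`) covering combinatorial targets and scaled-down
end-to-end model-ranking and gene-set-size experiments. The full run takes
roughly 10–15 minutes on one CPU; everything is seeded.

## CLI

```bash
crossgex simulate --n-compounds 12 --n-genes 40 --seed 1 --out-dir cohort/
crossgex genesets --dataset cohort/source --core-size 20 --increment 15 \
    --n-levels 5 --seed 2 --out-dir sets/
crossgex pair --source cohort/source --target cohort/target \
    --genes sets/random_20.txt --out-prefix examples
crossgex loocv --examples examples --model cnn --seed 3 --out folds_cnn.tsv
crossgex loocv --examples examples --model rrf --seed 3 --out folds_rrf.tsv
crossgex compare --folds cnn=folds_cnn.tsv --folds rrf=folds_rrf.tsv \
    --out comparison.tsv
crossgex report --comparison random20=comparison.tsv --out-dir report/
```

`crossgex run --config run.yaml` drives an end-to-end experiment
(simulate → pair → LOOCV per model → compare) from a single YAML file:

```yaml
seed: 4
out_dir: results
simulation: {n_compounds: 12, n_genes: 40, replicate_noise_sd: 0.1}
gene_set: {size: 20}
training: {epochs: 100, k: 5, n_trees: 100}
models: [cnn, naive_encoder, knn, rrf]
```

## File formats

Datasets are two TSVs (`<prefix>.expression.tsv`: genes × samples;
`<prefix>.samples.tsv`: sample_id, compound, dose, time_h, replicate plus
design columns). Gene sets are one id per line; ortholog maps are
two-column TSVs. Encoded instances and learning examples are TSVs with
provenance columns and a metadata header line.
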