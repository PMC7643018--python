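# neurodiff

Differential diagnosis of normal aging (NC), Alzheimer's disease (AD) and
frontotemporal dementia (FTD) from multi-scale, multi-type structural MRI
features — exercisable end-to-end on synthetic cohorts, with no restricted
data downloads.

The pipeline:

1. **Parcellation** (`neurodiff.parcellation`) — each anatomical ROI is
   subdivided into patches at three scales (500 / 1,000 / 2,000 members per
   patch) by 1-D k-means: on voxel intensity for volume features, on vertex
   thickness for cortical-surface features. Patches are clustered once on a
   template and propagated to subjects through a correspondence map
   (identity by default). Features are patch volume (member count × voxel
   volume) and mean patch thickness. The default six feature sets have
   dimensions 1,488 / 705 / 343 (volume) and 527 / 255 / 131 (thickness) —
   3,449 features in total.
2. **w-scoring** (`neurodiff.wscore`) — per-feature OLS on normal-control
   rows over covariates (age, sex, field strength, ICV, site, scanner);
   features become standardized residuals. Includes group-wise Welch
   t-tests with Benjamini–Hochberg FDR control.
3. **Fusion network** (`neurodiff.mmdnn`) — seven MLP blocks: one branch
   per feature set with hidden sizes `[3N, round(3N/4), 50]`, plus a fusion
   MLP over the concatenated 50-unit embeddings. Two-stage training
   (independent branch pretraining, fusion training, joint fine-tuning)
   with weighted cross-entropy, Adam (lr 5e-5), batch 100, dropout 0.5 and
   early stopping (patience 20), all implemented in NumPy with explicit
   backprop for reproducibility.
4. **GAN augmentation** (`neurodiff.gan`) — a 100-d-noise → 512 → 3,449
   tanh generator and the fusion network as discriminator with a fourth
   "fake" channel, trained alternately; real rows are range-normalized to
   [-1, 1]. At test time only the three real channels are used.
5. **Evaluation** (`neurodiff.ensemble`) — subject-level stratified 10-fold
   cross-validation; within each fold ten networks with different inner
   validation subsets vote by averaged-then-softmaxed probabilities.
   Normative models and range normalizers are refit per fold on training
   rows only. Paired one-tailed t-tests with FDR compare runs.
6. **Synthetic cohorts** (`neurodiff.synthetic`) — templates (label +
   intensity volumes, vertex tables) and cohorts with configurable
   covariate slopes, group-specific atrophy maps in residual-SD units, and
   subject-level random effects.

## CLI

```sh
neurodiff simulate  --config config.yaml             # synthetic cohort (+ template)
neurodiff parcellate --config config.yaml --template-prefix out/template
neurodiff wscore    --config config.yaml --metadata out/metadata.csv --features out/features.csv
neurodiff train     --config config.yaml --metadata out/metadata.csv --wscores out/wscores.csv
neurodiff crossval  --config config.yaml --metadata out/metadata.csv --features out/features.csv [--use-gan] [--no-ensemble]
neurodiff evaluate  --config config.yaml --predictions pred.csv
neurodiff compare   --config config.yaml --baseline a/metrics.json --improved b/metrics.json
```

All subcommands accept a YAML config (see `neurodiff.cli.example_config`
for the schema and defaults); every stage is seeded and writes CSV/JSON
artifacts into the configured output directory.

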