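# stabbench

Curation, leakage-aware splitting, training and identity-stratified
evaluation for mega-scale protein folding-stability datasets.

## The problem

Massively parallel cDNA-display proteolysis assays measure the folding
free energy ΔG (kcal/mol) of hundreds of thousands of variants — point
mutants, insertions and deletions — across hundreds of small protein
domains (40–72 aa, natural and de novo designed). Benchmarking a
sequence-based stability predictor on such data is mostly a data-hygiene
problem:

- **Curation.** The same protein is measured through several synonymous
  DNA constructs. Replicates must be aggregated per unique protein
  sequence, entries with replicate SD(ΔG) > 2 kcal/mol or
  SD(log K50) > 0.5 discarded, and domains with fewer than 100 measured
  sequences dropped.
- **Splitting without leakage.** The data are hierarchical (domains →
  mutants), so generalization has two layers: to new mutants of a
  training domain, and to entirely unseen domains. 10% of domains are
  held out whole ("test-set-only"); mutants of the remaining domains are
  split 80/10/10 into train/validation/test.
- **Identity stratification.** Each held-out domain is characterised by
  its maximum percent identity to any training wildtype under a local
  alignment passing e-value < 10⁻³ (0% when nothing passes), so
  performance can be read as a function of distance from the training
  set.
- **Evaluation.** Per-domain Spearman's R between predicted and measured
  ΔG; a paired comparison of training one model on all domains pooled
  versus one model per closest training domain (Wilcoxon rank-sum); and
  per-domain linear recalibration — ΔG_cal = a·ΔG_pred + b fit by OLS —
  reporting RMSE and R² = 1 − SS_res/SS_tot before and after (rank
  metrics are untouched by this affine correction).

The package implements this pipeline end to end, with two desk-scale
trainable predictor families (ridge regression on k-mer counts, and a
small NumPy transformer with a start-token regression head, trained with
gradient accumulation, early stopping on validation loss and
best-checkpoint selection), plus a synthetic-data generator that emulates
the deposit's structure with known ground truth so every stage is
testable without downloads.

## Worked example

```python
from stabbench import RunConfig, run_pipeline, report

config = RunConfig(seed=7, out_dir="runs/demo", run_id="demo")
run_dir = run_pipeline(config)      # synthetic input; ~10 s on one CPU
rep = report(run_dir)
```

Summarising `rep` (as printed by the code in this example):

```
curated 6726 sequences from 13054 raw rows (22 natural + 18 de novo domains)
test-set-only domains: 4, Spearman R 0.90-0.93 (mean 0.91)
collective - single mean Spearman difference: +0.28 (rank-sum p=1.000, n=1 matched domains)
recalibration: RMSE 4.40 -> 0.48 kcal/mol, R^2 -12.54 -> 0.85
```

Reading this: curation removed the planted noisy replicates and kept all
40 domains; the pooled ("collective") ridge model ranks mutants of the
four fully held-out domains at Spearman ≈ 0.9; on the one held-out domain
with a sequence-matched training partner, pooling beat the
single-partner-domain model by +0.28 (one pair cannot reach
significance; `scripts/acceptance.py` repeats this over ten seeds); and
although absolute predictions were badly mis-scaled on held-out domains
(negative R² before), a per-domain linear recalibration restores
kcal/mol-scale accuracy without changing any rank metric.

The same stages are available as a CLI:

```
stabbench simulate --seed 7 --out-dir data/
stabbench curate --input data/measurements.csv --min-seqs 100 --out-dir curated/
stabbench split --curated curated/curated.csv --seed 7 --out-dir split/
stabbench run --seed 7 --out-dir runs/demo
stabbench report --run-dir runs/demo
```

`stabbench curate` also reads real mega-scale deposit tables directly
(`--column-map` maps the deposit's column names onto the schema; the
defaults match the Tsuboyama-style layout).

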