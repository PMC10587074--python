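# potencybench

Benchmark calculations for quantitative compound potency prediction have a
well-known puzzle: machine-learning regressors of very different complexity —
and even trivial controls — land within a few hundredths of a pIC50 unit of
each other on ChEMBL-style activity classes. `potencybench` is a tested,
reusable pipeline for *diagnosing* why. It runs the full study design that
traces the effect to potency value distributions: most compounds in a curated
activity class sit at intermediate potency near the class median, and in that
sub-range a constant median prediction is already near-optimal, dominating
global error statistics regardless of method.

The package is aimed at cheminformaticians who build or evaluate potency
regression models and want benchmark numbers decomposed in a way that
separates learning from distributional artifacts.

## What it computes

For each activity class (a set of compounds with measured pIC50 ∈ [5, 11]
against one target, qualified when each potency sub-range LOW [5,7),
MID [7,9), HIGH [9,11] holds ≥ 75 compounds):

* **Models** — support vector regression with the Tanimoto kernel
  K(a,b) = |a∧b|/|a∨b| on folded 2048-bit ECFP4 fingerprints (C grid
  {1, 10, 100, 1000}), random forest regression on the raw bits (grid over
  trees/split/leaf/features), both tuned by grid search with 3-fold CV;
  **controls** — 1-NN and 3-NN potency assignment by Tanimoto similarity,
  and median regression (MR), the constant predictor ŷ = median(y_train).
* **Metrics** — MAE = (1/n)Σ|yᵢ−ŷᵢ|, RMSE = √(Σ(yᵢ−ŷᵢ)²/n), squared
  Pearson r², decomposed globally and per potency sub-range of the
  *experimental* value; pairwise Wilcoxon signed-rank tests over 10 trials
  at the Bonferroni-corrected threshold α = 0.005 (10 method pairs).
* **Protocols** — 10-trial random 50/50 splits; balanced training-set
  ladders of sizes 6, 12, 18, 30, 48, 78, 126, 204, 330 (equal per-sub-range
  counts, nested) against a fixed sub-range-balanced test set; an imbalanced
  ladder control.

A synthetic activity-class generator reproduces the relevant anatomy of the
curated classes (analogue-series fingerprint structure, intermediate-potency
bulk with class median in [7, 8], learnable additive SAR), so the entire
pipeline runs and is tested without downloading anything. Deposited curated
class CSVs can be loaded through `curation.load_class_csv` with a
configurable column mapping.

## Worked example

```python
import numpy as np
from potencybench import experiments, regressors, splits
from potencybench.synthetic_data import SyntheticSARConfig, generate_benchmark_suite

suite = generate_benchmark_suite(3, SyntheticSARConfig(min_per_subrange=140), seed=1)
cfg = experiments.RunConfig(methods=regressors.METHODS, n_trials=10, seed=1,
                            grid=regressors.FAST_RFR_GRID)
metrics, sig = experiments.run_benchmark(suite, cfg)
g = metrics[metrics.scope == "GLOBAL"].groupby("method")["mae"].mean().round(3)
print(g)
```

prints (global MAE, mean over 3 classes × 10 trials):

```
method
1-NN    0.616
3-NN    0.626
MR      1.015
RFR     0.552
SVR     0.540
Name: mae, dtype: float64
```

All four learning/similarity methods sit within 0.09 pIC50 units of each
other while the median-regression control trails by ~0.4 — yet decomposing
by sub-range (`metrics[metrics.scope == "MID"]`) shows MR matching them to
within ~0.1 in the intermediate range where most test compounds live, with
MR errors up to ~2 pIC50 units only in the tails. That contrast is the
diagnosed mechanism.

A command-line interface mirrors the library:

```bash
potencybench generate --n-classes 3 --seed 1 --out classes/
potencybench benchmark classes/*.csv --trials 10 --seed 1 --fast-rfr --out results/
potencybench ladder classes/*.csv --seed 1 --fast-rfr --out results/
potencybench report classes/*.csv --plots --out report/
```

Canonical outputs are tidy TSV tables; plots are optional.

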