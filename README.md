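# ccawoa

Dual-view feature fusion with canonical correlation analysis (CCA) and
wrapper feature selection with a binary-enhanced whale optimization
algorithm (bE-WOA).

## What problem this solves

In image-based diagnosis pipelines — the motivating application is
dementia detection and staging from brain MRIs — two deep networks often
each produce a long feature vector per image (two "views" of the same
samples).  Concatenating them yields thousands of partly redundant
dimensions.  This package implements the two steps that turn those views
into a compact, accurate representation:

1. **CCA fusion.**  Find projection pairs `(Wx, Wy)` maximizing
   `corr(X Wx, Y Wy)` — solved as the SVD of the whitened cross-covariance
   `Lx^{-1} Cxy Ly^{-T}` with ridge-regularized within-view covariances —
   and fuse the views by concatenating (or summing) the projections.
2. **bE-WOA feature selection.**  Minimize the wrapper fitness

   `F(mask) = 0.99 * (1 - acc_kNN(mask)) + 0.01 * |mask| / D`

   over binary feature masks with a whale-optimization variant enhanced by
   a solution pool, migrating search, preferential selection and enriched
   encircling, using a transfer function (sigmoid or V-shaped) to map
   continuous whale positions to masks.

Evaluation follows the standard protocol: stratified 80:20 split,
per-class TPR/FNR/PPV/FDR from the confusion matrix, mean ± std over
repeated runs, and paired t-tests between pipeline arms.  A synthetic
dual-view generator with planted informative dimensions makes everything
testable offline; see `docs/methods.md` for the model and its limits.

## Worked example

```python
from ccawoa import (PipelineConfig, run_pipeline)

config = PipelineConfig(
    synthetic=dict(n_per_class=150, n_classes=4, p1=50, p2=50,
                   n_informative=10, latent_dim=10),
    n_whales=20, max_it=60, n_runs=5,
    arms=("view1", "view2", "fused", "fused+bewoa"),
)
result = run_pipeline(config, seed=1)
for arm, s in result.summaries.items():
    print(f"{arm:>12}: {100 * s.mean:.2f} +/- {100 * s.std:.2f} %")
```

prints (seed 1):

```
       view1: 68.00 +/- 2.67 %
       view2: 67.00 +/- 2.47 %
       fused: 86.33 +/- 2.86 %
 fused+bewoa: 80.33 +/- 6.44 %
```

i.e. per-arm mean ± std test accuracy over 5 stratified re-splits.  Each
raw 50-dim view classifies the four heavily overlapping classes at ~68%;
CCA fusion with Bartlett truncation concentrates the shared class signal
into a handful of canonical components and jumps to ~86%.  On this
already-compact fused vector, selection can only prune (here to 2–5 of
~6 components, `result.records.n_selected`) at a small accuracy cost —
the regime where selection pays off is a *wide* redundant feature vector,
which is what the planted-recovery experiment in
`ccawoa.experiments` exercises (there bE-WOA recovers the planted
informative columns from 100 raw dimensions and beats random-mask
baselines).  `result.ttest_bewoa_vs_fused` carries the paired t-test
between the last two arms.

The same pipeline is scriptable from a shell:

```sh
ccawoa simulate --n-per-class 150 --p1 50 --p2 50 --n-informative 10 \
       --latent-dim 10 --seed 1 --out sim/
ccawoa fuse --view1 sim/view1.csv --view2 sim/view2.csv --out fused/
ccawoa select --features fused/fused.csv --seed 1 --out sel/
ccawoa evaluate --features fused/fused.csv --mask sel/mask.txt --out eval/
ccawoa pipeline --arms view1,fused,fused+bewoa --seed 1 --out run/
```

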