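# sfgrad

Structure-function (SF) correspondence mapping for brain connectomes: how
well is functional connectivity linearly predictable from structural
connectivity — globally, parcel by parcel, and function by function — and
how does that correspondence unfold along macroscale cortical gradients?

The package is aimed at connectomics researchers who have (or want to
simulate) three ingredients on a common parcellation:

* **structural connectivity (SC)** — per-subject parcel×parcel white-matter
  streamline count and mean-length matrices from tractography;
* **functional activation (FA)** — a parcel×term matrix of meta-analytic
  activation z-scores (one column per functional term), from which
  functional connectivity (FC) is the cosine similarity of parcel activation
  profiles;
* **term semantics** — word embeddings, concreteness ratings, and
  psychometric category lexicons for the functional terms.

## What it computes

**SC measures.** Subject matrices are averaged (no zeroing threshold by
default) and normalized by the geometric mean volume of each parcel pair,
then expanded into 13 network measures: count, length, Euclidean distance,
cosine similarity of connection profiles, flow graph (continuous-time
random-walk propagator at t = 1), matching index, greedy navigation count
and length, path transitivity, search information, mean first passage time,
shortest-path length (mm), and minimum hop count.

**Global model and SF map.** FC pairs are regressed on SC measure pairs.
The predictor subset is chosen by exhaustive best-subset search, scored out
of sample over node-based cross-validation folds (test pairs connect only
held-out parcels) with

    R2_OOS = 1 - sum_i (y_i - yhat_i)^2 / sum_i (y_i - ybar_OOS)^2

per fold, and the smallest subset within one standard error of the best mean
out-of-sample adjusted R² is selected. The **SF map** is then the adjusted
R² of each parcel's FC row regressed on its SC rows.

**Per-function SF.** For each term, parcels split into active (nonzero
z-score) and inactive; streamline counts between active-active pairs are
compared to active-inactive pairs with a two-sample rank test and a fold
change (mean aa / mean ai). Terms with fewer than 50 active-active
connections are filtered; the rest are classed high/low SF by a
Bonferroni-corrected p threshold and the 20th-percentile log₂ fold-change
cutoff among significant terms.

**Gradients.** Diffusion-map embedding of the FC affinity (right
eigenvectors of M^t, M = D⁻¹W, t = 1), spectral clustering with the eigengap
heuristic, activation PCA, activation-weighted semantic diversity of each
parcel's top-10 terms, concreteness and category-proportion gradients,
cortical thickness, and Cartesian coordinates — each correlated with the SF
map (R², Spearman r, and a 10,000-run permutation null).

**Term predictors.** A linear-kernel SVM classifies high vs low SF terms
from their embeddings (4-fold stratified CV, mean AUC), and a feedforward
network (two 128-unit ReLU hidden layers) regresses the fold change.

A synthetic-data generator (`sfgrad.synthetic`) produces atlases, subject
streamline matrices (Poisson counts with exponential distance decay), sparse
activation matrices with a planted per-parcel coupling gradient and planted
high/low term classes, clustered embeddings, lexicons, and thickness maps —
so the full pipeline is testable end to end with known ground truth.

## Worked example

```python
import numpy as np
from scipy import stats
from sfgrad import SyntheticConfig, generate_dataset, run_pipeline

ds = generate_dataset(SyntheticConfig(seed=1))     # 120 parcels, 40 subjects, 60 terms
result = run_pipeline(ds, k_folds=10, seed=1)

print("chosen SC predictors:", result.selection.chosen_subset)
rho = stats.spearmanr(result.sfmap.values, ds.planted_gradient).statistic
print("Spearman(SF map, planted gradient) = %.2f" % rho)
conc = result.gradient_reports["concreteness"]
print("concreteness gradient: r = %.2f, p_null = %.4f" % (conc.spearman_r, conc.p_null))
```

prints

```
chosen SC predictors: ('cosine',)
Spearman(SF map, planted gradient) = 0.85
concreteness gradient: r = 0.41, p_null = 0.0001
```

The selection step identifies profile cosine similarity as the dominant SC
predictor of cosine FC; the parcel-wise SF map recovers the planted coupling
gradient with rank correlation 0.85; and the concreteness gradient
(activation-weighted mean concreteness of each parcel's top-10 terms) rises
significantly along the SF map, the planted analogue of the
sensory-to-association axis.

The same stages are scriptable from a shell via the `sfgrad` CLI
(`simulate`, `sc`, `fc`, `select`, `sfmap`, `termsf`, `gradients`,
`predict-sf`; see `sfgrad --help`).

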