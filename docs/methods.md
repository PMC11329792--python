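# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the method left
room.

## Structural connectivity

Subject-level streamline matrices are aggregated to a group matrix by the
arithmetic mean over subjects, divided by the geometric mean voxel volume of
the two parcels, `sqrt(vol_i * vol_j)` (larger parcels intercept more
streamlines; the normalization makes counts comparable across pairs). Two
variants exist as options but are off by default: a zeroing threshold (a
pair must be nonzero in more than a fraction X of subjects; default X = 0,
so a single connected subject keeps a pair) and length weighting
(multiplying or dividing by the group mean streamline length). Group mean
length is averaged only over subjects in which a pair is connected; pairs
connected in no subject are missing, not zero — a zero streamline count is
data, so the missing marker is NaN throughout and the diagonal (self-edges,
never considered) is always NaN.

From the group count, length and centroid-distance matrices, the 13-measure
stack is derived. Conventions, where the literature leaves freedom:

* **Edge cost** for every shortest-path computation is `1/weight` on the
  aggregated count matrix — the prevailing convention for weighted
  connectomes, recorded in each matrix's metadata.
* **Flow graph** is the continuous-time random-walk propagator
  `F(t) = diag(s) expm(t(P − I))` with `P = S⁻¹W`, at `t = 1` (configurable).
* **Navigation** routes greedily: from the current node, step to the
  structurally connected neighbor nearest (Euclidean) to the target; a
  revisit or dead end is a failed route and the pair is missing.
  Consequence worth knowing: when a direct edge exists the target itself is
  the nearest neighbor, so navigation length equals streamline length on
  directly connected pairs.
* **Search information** is `−log2` of the probability that an unbiased
  random walker follows the `1/w`-shortest path; **path transitivity** is
  the mean matching index over all node pairs of that path; **MFPT** solves
  the absorbing-chain system `(I − P_{−j}) h = 1` per target. All inherently
  directed measures are symmetrized by the arithmetic mean of the two
  directions, so every stack output is symmetric with a missing diagonal.

## Functional connectivity

Meta-analytic FC is the cosine similarity between parcel rows of the
parcel×term activation matrix: only the relative pattern of activation
across terms matters, not its magnitude (cosine FC is invariant to positive
rescaling of any parcel's row). Parcels with all-zero rows get missing FC.
FC is never sparsity-thresholded; downstream comparisons are rank-based.
The resting-state path Fisher-z transforms per-subject Pearson correlations
(r clipped at `1 − 1e−12` so atanh stays finite) and averages z across
subjects.

## SC → FC regression

Responses and predictors are vectorized over the strict upper triangle.
Rows with any missing value are dropped listwise per table and the count
reported, so every candidate subset is compared on the same rows. Two
degeneracies follow from conditioning on the length measure (defined only
for directly connected pairs): hop-count measures become constant (every
retained pair is one hop) and navigation length duplicates length. Constant
candidates are excluded from the search with a logged flag; duplicate
columns are tolerated by minimum-norm least squares.

Cross-validation is node-based: parcels are randomly partitioned into k
folds (default k = 10, seeded); a fold's test pairs join two held-out
parcels and its training pairs join two retained parcels, so test edges
connect nodes never seen in training. Mixed pairs enter neither set —
whether pairs with exactly one held-out endpoint should count as test is
genuinely open; the stricter both-endpoints definition is the default.

Best-subset search ranks all subsets of each size by training RSS using
precomputed Gram matrices over standardized predictors (standardization
leaves fits with an intercept unchanged and keeps the Gram systems well
conditioned across measures whose scales differ by orders of magnitude);
the winning subset per fold is then re-fit explicitly and scored on the
held-out pairs by out-of-sample adjusted R² and MSE. The reported subset
size is the smallest whose mean OOS adjusted R² lies within one standard
error (across folds) of the best — a one-SEM operationalization of "adding
predictors does not significantly improve performance"; a paired-t variant
is available (`rule="max"` disables the parsimony rule entirely).

The **SF map** regresses each parcel's FC row (over all other parcels) on
its SC rows for the chosen subset and stores the adjusted R²; parcels with
fewer valid pairs than predictors + 2 are missing. Columns that are
constant within a parcel's row are dropped and the adjusted-R² penalty uses
the effective (rank-based) predictor count.

## SF correspondence by term

Active parcels are those with |z| strictly above a tolerance (1e−12).
The active-active and active-inactive count vectors include zero-count
pairs. The two vectors are compared with a two-sample Mann-Whitney test,
two-sided — exact permutation enumeration when the pooled sample has ≤ 16
values (two-sided p as twice the smaller tail, capped at 1), tie-corrected
normal approximation otherwise. Fold change is `mean(aa)/mean(ai)`,
invariant to global rescaling of the count matrix, undefined when the
active-inactive mean is zero.

Terms with fewer than 50 *nonzero* active-active pairs are filtered (a
"connection" requires streamlines; a config flag counts all pairs instead).
Bonferroni correction runs over the surviving terms. Among significant
terms, the 20th percentile of log₂ fold change (linear interpolation) is
the high/low cutoff. Note the structural consequence: the percentile rule
assigns the bottom fifth of significant terms to "low" by construction, so
a world in which many weakly coupled terms fail significance will push some
genuinely coupled terms under the cutoff.

## Gradients and nulls

The diffusion map uses the right eigenvectors of `M^t`, `M = D⁻¹W`, with the
FC matrix as a precomputed affinity (negative entries clipped to zero with a
warning, diagonal zero — self-edges are not considered), ordered by
eigenvalue magnitude, scaled by `λ^t`, the trivial constant eigenvector
dropped, and signs fixed so each component's largest-magnitude entry is
positive. Spectral clustering uses scikit-learn with the same precomputed
affinity; the eigengap heuristic takes the largest gap in the sorted
normalized-Laplacian spectrum.

Top-term profiles keep each parcel's 10 largest positive activations (ties
broken by term order, stable sort). Functional diversity is the
activation-weighted mean distance of those terms' embeddings from their
activation-weighted centroid (the centroid uses the same weights; an
unweighted-centroid variant was considered and rejected for consistency).
Lexicon gradients are weighted means of per-term scores, or weighted
category proportions; terms missing from a lexicon are dropped and the
weights renormalized.

Every gradient-vs-SF-map comparison reports the linear-fit R², Spearman r,
and a permutation-null p obtained by randomly reassigning the gradient
values to parcels (10,000 permutations by default) with the add-one
estimator `p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm)`, which keeps p in
(0, 1].

## Term-level predictors

Embeddings are loaded from a term-indexed table, or estimated from a
tokenized corpus by positive pointwise mutual information over a
symmetric 5-token window factorized with truncated SVD (`U·√S` word
vectors) — a classical count-based estimator with the same interface
(default 150 dimensions, 20 SVD power iterations, seeded).

The classifier is a linear-kernel SVM with probability outputs under
stratified 4-fold CV, positive class "high", reporting per-fold and mean
AUC and accuracy. The regressor is a feedforward net, input → 128 → 128 → 1
with ReLU hidden activations, squared-error loss, adaptive-moment
optimizer, learning rate 0.01, at most 500 epochs with early stopping on a
10% inner validation split (patience 50); features and target are
standardized per training fold. All of these settings live in the report's
`train_config`.

## The synthetic world

The generator's defaults define the study conditions: 120 parcels, 40
subjects, 60 terms, 150-dimensional embeddings, activation sparsity 0.25,
and a single global seed that expands into independent per-component child
seeds (adding a generator never perturbs the others).

* **Atlas**: centroids on a jittered ellipsoidal shell (semi-axes 70/85/60
  mm, 6 mm jitter), regions by spatial octant, log-normal volumes.
* **Streamlines**: per subject, symmetric Poisson counts with mean
  `λ_ij = count_scale · exp(−d_ij / distance_scale_mm)` (80 and 15 mm by
  default — chosen so the group graph is ~75% dense, leaving genuinely
  unconnected pairs to exercise the missing-data paths), and lengths
  `d_ij (1 + ε)` on connected pairs.
* **Coupling gradient**: g runs smoothly from 0.3 to 1 along the axial
  coordinate (a floor of 0.3 reflects that no territory is fully decoupled
  from its white matter).
* **Activation**: each term seeds a parcel and activates a contiguous set of
  `sparsity × n_parcels` parcels. High-coupling terms (80% of terms,
  mirroring the 20th-percentile classification cutoff) seed the strongly
  coupled half of the cortex on a spatially spread max-min design and
  activate the seed's SC-cosine neighborhood, with values tapering to zero
  at the neighborhood boundary so FC is a smooth function of the structural
  field. Low-coupling terms seed the weakly coupled half and activate a
  contiguous core (two-thirds of the set) plus a systematic spatial scatter
  (every k-th parcel by distance rank) at reduced amplitude: the core keeps
  the rank test significant, the scatter dilutes the mean toward the
  brain-wide average and keeps the fold change low. The planted term class
  and the planted parcel gradient are deliberately one coherent world —
  structurally aligned functions live in strongly coupled cortex, as the
  sensory-to-association story implies.
* **Coupling mixing**: parcel p follows the structural pattern for an exact
  quota of `round(g_p · n_terms)` terms and is resampled as sparse
  class-neutral noise for the rest (the exact quota removes binomial noise
  from each parcel's effective coupling; class-neutral noise makes
  decoupled parcels sample semantic clusters indiscriminately, which is
  what raises their functional diversity). Per-term expected sparsity is
  preserved for any coupling profile.
* **Embeddings**: two Gaussian clusters offset by 4 along the first axis,
  with per-dimension scales decaying as `exp(−j/20)` — word embeddings
  concentrate their variance in a few leading directions, and this is what
  makes cluster mixing visible to isotropic dispersion measures, not only
  to linear classifiers. Concreteness is drawn higher for the high cluster
  (3.8 vs 2.6, sd 0.4, clipped to [1, 5]); categories are drawn with
  class-dependent probabilities strongly favoring "perceptual" for high and
  "cognitive" for low terms.
* **Thickness**: `3.6 − 0.6·ẑ − 0.4·g + noise` mm, floored at 0.5.

What the generator does **not** emulate: tractography biases (length and
curvature-dependent seeding, gyral bias), voxel-level fMRI time series,
long-range structural bundles that break the distance-decay law (the
Poisson mean is pinned to the exponential kernel, so structural geometry is
isotropic), lexical polysemy, and realistic term co-occurrence. Passing
tests therefore demonstrate that the *pipeline* recovers planted truths
under the stated statistical structure — not that any neuroscientific claim
holds on real data.

## Known limitations

* In the noise-free, fully coupled limit the per-parcel SF fit does not
  reach adjusted R² = 1: cosine FC of a sparse 120×60 activation matrix is
  a rank-≤60 kernel, and no such kernel can be an exact per-parcel linear
  function of the SC rows (symmetry forces a global affine relation, whose
  rank is that of the full measure matrix). The attained limit is ≈0.90
  minimum and ≈0.97 median per parcel; the residual is angular sampling
  noise of the 60-term bump sum and shrinks roughly as 1/n_terms.
* At 120 parcels, node-based folds hold out 12 parcels (66 test pairs), so
  global out-of-sample curves are noisy; the one-SEM rule consequently
  prefers very small subsets on the default synthetic data.
* The toy low-SF class has 12 terms; term-level predictor scores on
  pipeline-derived (rather than planted) classes are correspondingly
  unstable.
* Exhaustive search over 13 candidates is `2^13 − 1` subsets per fold;
  Gram-based ranking keeps this fast at toy scale, but the cost is
  exponential in the candidate count.
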