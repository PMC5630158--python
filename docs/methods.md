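# Methods

## The modelling problem

An internal ribosome entry site (IRES) recruits the ribosome to an mRNA
cap-independently. Massively parallel bicistronic reporter assays measure an
IRES activity value for each of tens of thousands of short RNA fragments; most
fragments show no activity, so the activity distribution is a large point mass
at the assay's detection floor with a long right tail (roughly 11% of
sequences above the floor). `irespred` models this activity from primary
sequence alone and then interrogates the trained models for the sequence
elements — k-mers, their copy number, and their position relative to the
reporter start AUG — that drive the predictions.

## Features

Each sequence is represented by exact overlapping occurrence counts of every
RNA k-mer of length 1..k_max (k_max = 4 by default, cumulative lengths rather
than exact-k, so that the short motifs U, CU, CAG remain first-class
features). Counts are recorded globally and inside 20-nt windows stepped
5'-ward from the AUG in 10-nt strides; windows are labelled by AUG-relative
half-open intervals (`[-20, 0)` is the 20 nt immediately upstream), so
sequences of different lengths share labels and coordinates match how
positional results are reported. An occurrence belongs to a window only when
its full extent lies inside it; partial 5' windows are dropped. A 174-nt
sequence therefore has 16 windows and, at k_max = 4, 340 + 16 x 340 = 5780
candidate features. A *presence* representation caps every count at 1.

## Screening

On each training partition (and only there), count features are tested by
Spearman rank correlation against activity and presence features by a
two-sided Mann-Whitney U comparing carriers to non-carriers. P-values are
adjusted by Benjamini-Hochberg step-up over all candidate features as a single
family — the most conservative reading when global and positional features are
screened together — and a feature survives at q <= 0.05 with non-zero values
in at least 10% of the partition's samples. The screen is recomputed on every
inner-CV training set and on every outer training set, so held-out data never
leak into selection.

## Model and tuning

The predictor is stochastic gradient boosting of least-squares regression
trees: 1000 trees by default, each fitted to the residual gradient on a random
fraction `f` of samples, split search over `floor(sqrt(M'))` randomly drawn
features per node, unbounded depth, and at least `m` training samples per
leaf. `(m, r, f)` — leaf size, learning rate, subsample fraction — are tuned
by nested 10-fold cross-validation: each outer training set is split into 10
inner folds, every grid cell is scored by mean validation R², and the winning
cell (ties broken toward smaller `r`, then larger `m`, then grid order) is
refit on the full outer training set and evaluated on the held-out outer fold.
Folds are stratified so above-floor sequences are spread as evenly as
possible. The default grid is m ∈ {15, 30, 60}, r ∈ {0.01, 0.05, 0.1},
f ∈ {0.5, 0.8}, spanning the standard operating range for libraries of a few
hundred to a few tens of thousands of sequences; all values are configurable.

The ensemble backend is LightGBM, configured to exactly this contract
(`subsample`/`subsample_freq`, `min_child_samples`, per-node feature fraction
`sqrt(M')/M'`, `max_depth=-1`, deterministic single-threaded training with a
seed); scikit-learn's `GradientBoostingRegressor` is available as an alternate
backend satisfying the same contract, and the contract — not the backend — is
what the tests pin down. LightGBM's histogram binning uses 63 bins with
`min_data_in_bin=1`, lossless for small integer k-mer counts. A training
partition whose screen keeps no features falls back to a constant
training-mean predictor rather than aborting the whole cross-validation, which
is what makes permuted-activity controls well defined.

If a grid cell cannot train (e.g. `m` exceeding the partition), it scores
-inf and is logged, never silently skipped.

## Evaluation

R², Pearson r and Spearman ρ are computed on outer-fold test predictions
pooled over all folds (per-fold tables carry mean ± sd); AUC-ROC (rank
formulation, mid-ranked ties) and AUC-PR (step integration, no linear
interpolation) measure separation of active from inactive sequences using the
predicted activity as the score. Two resampling experiments are provided: a
group-division permutation test (labels permuted preserving group sizes;
statistic = variance of per-group R², `range` available) with an add-one
p-value, and a positive-incidence subsampling curve (positives downsampled to
target counts, all negatives kept, 5 repetitions per target by default).

## Interpretation

Raw importances are total split-induced variance reduction (gain) accumulated
per feature and averaged over trees; each fold model's importances are divided
by that model's maximum so models with different feature counts are
comparable. A feature is *robust* when every outer fold retained it and
*predictive* when its mean normalized importance is at least 0.1. Direction
comes from substitution-based partial dependence — each observed value of the
feature substituted into its column for all of the fold's training rows,
predictions averaged, curves averaged across folds — classified by the sign of
the mean finite-difference slope; a flat or single-point curve counts as
negative, following the convention that only a strictly positive average
derivative is called activating. Positional effects of one k-mer form an
*island* when at least two consecutive windows (adjacent window starts at the
10-nt step) are robust; a per-window *consensus* across groups exists when at
least two groups agree in sign, with magnitude the largest supporting
|effect|. GC-content distributions between groups are compared by a two-sided
rank-sum test.

## Synthetic libraries

The generator emulates the statistical structure the analysis assumes, not
the biology of any particular assay: i.i.d. letters at a per-group GC
fraction; latent activity = baseline + Σ (motif effect × Gaussian positional
weight over the occurrence's AUG-relative start) + Gaussian noise
(σ = 0.3 by default); detection floor at the 0.89 quantile of latent values;
observed activity = max(latent, floor). The left-censoring reproduces the
point mass at background plus right-skewed tail; by construction ~11% of
sequences are active. Default recipes plant a U-rich activator (UUUU, +1.0,
centered 50 nt upstream of the AUG, positional s.d. 20 nt) and a global A-rich
repressor (AAAA, -0.8) in every group, with an additional far-upstream C-rich
activator (CCCC, +1.0 at -200, s.d. 25) in the retro-like group; each motif is
also explicitly planted with probability 0.3 per sequence at a position drawn
from its positional Gaussian, so that positional 4-mer features clear the 10%
prevalence screen at realistic rates. Ground truth (latents, occurrence
positions, weights, the floor) is exported so every latent is exactly
recomputable.

What the generator does **not** model: replicate noise structure beyond
i.i.d. Gaussian, promoter/splicing artifacts, RNA secondary structure, or any
dependence between sequence composition and noise. Passing recovery tests
therefore demonstrate that the pipeline's statistics behave as designed under
their own assumptions, not that real libraries satisfy those assumptions.

## Designed-oligo module

The combinatorial design substitutes (never inserts, keeping the 164-nt
variable length) the 7-nt C/U-rich TEV IRES element UACUCCC at every subset of
8 predefined sites in two backgrounds — a native beta-globin (HBB) fragment
and a synthetic 9-mer-spacer concatenation — giving 2^8 = 256 oligos per
background, 512 total, the empty placement included. Site starts default to
(2, 22, ..., 142), evenly spaced and non-overlapping, and are configurable;
the shipped HBB background is a clearly labelled synthetic stand-in with
HBB-like composition, replaceable by the authentic fragment. Each oligo gets a
10-nt barcode; barcodes are drawn by seeded greedy rejection sampling under a
pairwise Hamming distance >= 3 and may not contain the element as a substring
(avoiding spurious extra sites). Measured (or simulated) activities, with
replicates pooled as separate observations, are binned by site count (0-1,
2-3, 4-5, 6-8): fraction positive per bin, expression of positives, and a
one-way ANOVA across bins on positive observations (skipped with a warning
when a bin has fewer than two positives).

## Problem sizes used in the shipped checks

The recovery checks run the full pipeline at a deliberately scaled study
size — 2000 sequences in one group, 200 trees, a 2x2x1 grid, 5 outer x 5
inner CV folds, ten seeded replicate libraries plus one permuted-activity
control — which preserves every qualitative property being asserted
(screening behaviour, nested-CV tuning, robustness counting, directionality)
at a fraction of the full-scale cost. The headline real-library performance
values quoted in the README require the externally hosted measured library
and are documented as an optional reproduction, not recomputed here.

## Known limitations

- The exact hyperparameter grid used for the original measured library is not
  public in detail; the default grid is a documented stand-in and the winning
  cell is always recorded per fold.
- Whether split-candidate features are redrawn per node or per tree is an
  open choice in the field; per-node is the default (standard practice), and
  the sklearn backend follows the same rule.
- BH is applied to one pooled family per representation; screening count and
  presence features as separate simultaneous families would need a different
  family decision.
- Importance normalization makes effects comparable across models but not
  across differently-sized feature spaces in any absolute sense; only signs
  and relative magnitudes are interpreted.
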