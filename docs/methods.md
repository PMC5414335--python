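# Methods

## The activity statistic

For a sample with expression values for *n* genes, of which *m* belong to a
binary target-gene signature, the profile is ranked from high to low
normalized expression (ties broken by lexicographic gene symbol, so the
ranking is a deterministic function of the values). Walking the ranking,
let `S_k` be the number of targets among the top *k* genes. The foreground
and background CDFs are `F_fg(k) = S_k/m` and `F_bg(k) = (k − S_k)/(n − m)`,
and the preliminary score is the signed maximal deviation `d(k*) =
F_fg(k*) − F_bg(k*)` where `|d|` is maximal over `k ∈ [1, n]`, taking the
first `k` on ties. The statistic lies in [−1, 1]; it equals +1 exactly when
all present targets occupy the top *m* ranks and −1 when they occupy the
bottom *m*. It is a two-sample Kolmogorov–Smirnov-type statistic on ranks
with the sign retained, which is what produces the bimodal ± score
distributions that activity-based stratification relies on.

Increasing the expression of every target gene by a common δ > 0 can only
move targets up the ranking, so the preliminary score is monotone under
target up-shifts. The implementation computes `d(k)` for every `k` by a
vectorized cumulative sum; the test suite checks it against an independent
brute-force walk, exactly, over hundreds of random profiles.

## Permutation null and the iRAS

The preliminary score scale depends on *n* and *m*, so each sample's score
is normalized against a null of B = 1000 preliminary scores of uniformly
random gene sets of size *m* drawn from that sample's profile. Because a
random gene subset occupies uniformly random rank positions, the null is
generated directly from random position masks; this is an exact
reformulation, not an approximation. Nulls are drawn per sample from
independent seed streams spawned from one user seed, so results are
bitwise reproducible and samples are scored independently.

The signed null is approximately symmetric about zero, so its overall mean
is near zero and unusable as a denominator. Normalization is therefore
sign-stratified: a positive preliminary score is divided by the mean of
the positive null scores, a negative one by the absolute mean of the
negative null scores. This preserves sign, puts scores of either sign on a
comparable "times the random-set expectation" scale, and degenerates to
plain division by the absolute null mean when the null happens to be
one-signed. A literal single-denominator mode is available
(`sign_stratified=False`) for comparison. Degenerate cases are errors, not
silent: an empty required stratum suggests a larger B, and a signature
overlapping zero matrix genes (or all of them) cannot be scored.

## Normalization

Expression is expected on a log scale. `quantile_normalize` maps every
column onto the across-column mean of sorted values; within-column ties
all receive the mean of the reference values at their tied rank positions.
On tie-free data all columns end with bitwise-identical sorted values. The
operation short-circuits on an already-normalized matrix (the flag is part
of the container), which makes it exactly idempotent — re-averaging
already-identical columns would otherwise drift by floating-point ulps.

One-channel (intensity) data is then median-centered per gene row,
converting intensities into relative expression comparable to two-channel
log-ratios; this changes cross-gene rankings within a sample, which is the
point — without it, one-channel rankings are dominated by overall probe
brightness. Row-wise (per-gene) centering was chosen over column-wise
because the statistic ranks genes within a sample: subtracting a per-sample
constant would leave every ranking unchanged. Centering uses a short
fixed-point iteration (≤ 4 passes) so row medians are exactly zero even for
even-length rows where one subtraction can leave a one-ulp residual.

Probeset-level matrices are collapsed to gene symbols by keeping, for each
gene, the probeset with the highest mean intensity across samples (ties:
first in input order). Missing expression values are never imputed
silently; quantile normalization refuses them and instructs the caller.

## Stratification and evaluation

Mode-based stratification fits a Gaussian KDE (Silverman bandwidth, 512
grid points over the data range ± 3 bandwidths), locates local density
maxima, and thresholds at the most negative and most positive modes: low
below the negative mode, high above the positive mode, intermediate
between. Fewer than two modes is an error that recommends tertile
stratification — the intended fallback for unimodal reduced-panel scores.
Tertiles assign the first ⌈n/3⌉ sorted samples to low and the last ⌊n/3⌋
to high, with boundary ties falling to the lower stratum so labels depend
only on score values.

Stratum–response association uses the 3×2 χ² test without continuity
correction, plus an optional two-sided Fisher exact test of low versus
intermediate+high. Missing responses are excluded listwise and counted.

ROC curves come from the full threshold sweep — each observed score is a
cutoff, score ≤ cutoff predicts RD — with sentinel cutoffs anchoring
(0,0) and (1,1) and tied scores collapsing to one step. The trapezoidal
AUC then equals the all-pairs Mann–Whitney concordance with ties counted
one half; the test suite verifies this equality to 1e-12 against an
independent all-pairs oracle, along with the antisymmetry
AUC(−s) = 1 − AUC(s) and invariance under strictly monotone transforms.

## Panel reduction

Candidate target genes are selected by Pearson correlation (Spearman
optional) between their expression and the reference iRAS, strictly above
a threshold of 0.8 — "R" is read as Pearson because the downstream PCA
assumes linear structure. Selected genes are expressed relative to the
mean log expression of five housekeeping controls (ACTB, GAPDH, RPLP0,
GUSB, TFRC), which cancels per-sample offsets (the shift invariance is
tested). PC1 loadings are fit on the gene-wise mean-centered covariance
(no variance scaling, since the published score form applies loadings to
relative expression directly); the centering offsets are stored in the
model so out-of-cohort scoring is well defined, and the PC1 sign is fixed
by positive correlation with the reference score. Selection and loading
fits may use different cohorts (pass `panel_genes` explicitly).

At scoring time, panel genes missing from a sample contribute zero after
centering (mean imputation in effect) down to a hard coverage floor of
80%; genes entirely absent from a fitting matrix are dropped and the model
refit on the remainder, mirroring the panel's intended portability across
platforms. Models serialize to JSON and round-trip bitwise.

## Cross-validated integration

`repeated_cv_auc` evaluates a classifier on clinical covariates (age,
stage, grade, ER, PR, HER2, nodal status; categorical levels integer-
encoded, missing values imputed by mode/median with indicator columns)
with or without signature scores. Folds are stratified by response —
plain random folds at realistic ~20% pCR rates regularly produce folds
with a missing class — with a plain-random mode behind a flag. One AUC is
computed per repeat on pooled out-of-fold class scores rather than per
fold, because per-fold AUCs are unstable with few positives. Fold
assignments and per-fold model seeds depend only on the master seed, the
labels and the repeat index, so feature-set variants are compared on
identical splits (paired design) and duplicate variants reproduce
identical results. The default learner is a random forest at library
defaults; any estimator with `fit` and a continuous class score plugs in.

## Synthetic cohort generator

The generator emulates the statistical structure of a neoadjuvant breast
cancer expression cohort:

- latent activity `a_s ~ π·N(μ_low, σ²) + (1−π)·N(μ_high, σ²)` with
  defaults π = 0.5, μ = ∓2, σ = 0.7 — a clearly bimodal distribution;
- target genes `x_gs = λ_g·a_s + ε`, λ_g ~ U(0.5, 1.5), background genes
  pure noise (σ_g = 1), all shifted to a positive log-intensity baseline
  (8.0); five housekeeping controls at a higher baseline (10.0) with small
  noise (sd 0.2) and no activity loading;
- ER-negative probability 0.55 in the high mode versus 0.20 in the low
  mode, giving a realistic ~35–40% ER-negative marginal with clear
  enrichment;
- pCR ~ Bernoulli(logistic(γ0 + γ1·a_s)) with γ1 = 1 and γ0 solved by
  Gauss–Hermite quadrature and bisection so the marginal pCR rate is 0.20;
- stage and grade derived from latent Gaussians with mild positive
  dependence on activity (coefficients 0.3 and 0.5 — grade tracks
  proliferation more strongly than stage), age, nodal status, PR/HER2
  with conventional marginals, residual-burden classes skewed toward
  heavier burden at low activity, and optional exponential
  recurrence-free survival times with uniform censoring.

Defaults are 500 samples, 5000 genes, 199 targets. Cohorts are bitwise
reproducible for identical parameters and seed; ground truth (per-sample
activity and component, per-gene slope) ships with the data. A probeset
view expands each gene into k probesets with distinct negative offsets and
small noise, recording the planted best probeset per gene so the collapse
rule can be validated exactly.

What the generator does **not** emulate: probe-affinity and batch
effects, platform differences, correlated background co-expression
modules, down-regulated targets, or non-linear activity–expression
relationships. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated generative model, not
expected performance on any real cohort.

In the test suite and acceptance run, "strong" planted targets — used to
measure selection recovery — are defined as λ ≥ 1.0, where the population
correlation with the latent activity (≈ 0.90 at the default mixture) sits
comfortably above the 0.8 selection threshold; genes near the threshold
are excluded from the recovery denominator so the measurement reflects
the selector, not sampling noise at the boundary.

## Problem sizes and numerical choices

The full study conditions (n = 500, 5000 genes, 199 targets, B = 1000)
are used for recovery, stratification, reduction and CV checks; null
behavior checks use 100-sample, 2000-gene cohorts, and CV sanity checks
use 10-fold × 20 repeats (the repeat count is configurable up to the
conventional 100; the acceptance script uses 10 repeats). KDE mode
finding, χ²/Fisher tests, PCA/SVD, random forests and fold splitting use
scipy/scikit-learn/numpy primitives; the activity statistic, permutation
null, quantile normalization, median centering and ROC sweep are
implemented here and validated against independent oracles.

Known limitations: binary signatures only (no ChIP-signal weighting; the
data model leaves room for weights), no gene-level p-values, no survival
statistics (generated survival columns are for downstream users), and no
cross-platform batch correction. Scoring cost is O(B·n) per sample, about
0.15 s at default scale, so a 500-sample cohort scores in roughly a
minute on one CPU.
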