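# Methods

`protdx` implements a multi-task diagnostic pipeline for high-dimensional
plasma proteomics: six dementia-associated conditions (cognitively unimpaired
control, AD, PD, FTD, ALS, previous stroke/TIA) are predicted simultaneously
from a selected protein panel by a joint neural network, surrounded by the
preprocessing, feature-selection, validation, interpretation and clinical
calibration machinery a study of this kind needs.  Everything is exercised on
synthetic multi-site cohorts with known ground truth; this note records the
models, the tunable parameters and the design decisions.

## The joint classifier

### Model

The network is a shared multilayer perceptron: panel proteins → fully
connected hidden layers (default widths 256 and 64, GELU nonlinearity,
dropout after each hidden layer) → a linear *embedding* layer (default 32
dimensions) → six per-task linear heads with sigmoid outputs.  The embedding
is the pre-head activation vector and serves as a low-dimensional nonlinear
proteomic summary for transfer, interpretation and mapping.  Heads combine
the embedding strictly linearly, which is what licenses the covariance
(activation-pattern) interpretation of embedding importance.

A multi-task rather than multi-class design is essential because diagnostic
labels are ternary (positive / negative / never assessed): each task trains
only on participants with an observed label for that condition, and
co-pathologies (several positives at once) are representable.

### Loss

For probabilities p, labels y, label-smoothing α, margin ε and weight λ:

    L = L_BCE(α) + λ · L_rank(ε)

* `L_BCE` is binary cross-entropy against smoothed targets
  y(1−α) + α/2, averaged over **observed** (participant, condition) entries.
  Averaging over observed entries (rather than N×6) keeps the loss scale
  comparable across missingness patterns; a participant with no observed
  labels contributes nothing.
* `L_rank` is, per participant, Σ_{i<j} max(0, (p_i − p_j)(y_j − y_i) + ε)
  over condition pairs with both labels observed, averaged over participants
  with at least one observed label.  A positive condition's probability must
  exceed a negative one's by the margin ε (default 0.25).  Pairs with equal
  labels contribute the constant ε and exactly zero gradient; the literal
  form is kept so the computed loss matches its definition (a configuration
  switch could exclude such pairs, but the constant is harmless to
  optimization).

Probabilities are clipped to [1e−7, 1 − 1e−7] before logarithms.  The
vectorized implementation is pinned to an independent triple-loop oracle in
the test suite (max |Δ| < 1e−9 over 200 random instances with mixed missing
labels), and the analytic logit gradient is pinned to central finite
differences.

### Optimization

The network is implemented directly in numpy (forward, backward, Adam with
decoupled weight decay on weight matrices only).  This keeps training exactly
reproducible for a fixed seed, independent of thread count.  Defaults:
batch 256, learning rate 1e−3, weight decay 1e−5, at most 100 epochs with
early stopping on validation loss (patience 10, minimum improvement 1e-4).  Per-task probability
thresholds are selected on validation predictions by maximal F1 over
midpoints of sorted unique probabilities (ties → larger threshold;
single-class validation labels → 0.5 with a warning), always before any
test-set evaluation.

Hyperparameter search is a seeded random search (default budget 50 trials)
over hidden widths {64…512, 1–3 layers}, dropout [0, 0.5], α [0, 0.2],
λ {0, 0.25, 0.5, 1, 2} and log-uniform learning rate [1e−4, 1e−2], scored by
validation balanced accuracy averaged over tasks.

Predictive intervals come from 100 stochastic forward passes with dropout
active at inference; the reported interval is the (2.5, 97.5) percentile
range, whose width is a proxy for model instability.

## Preprocessing

Outlier masking (per protein, |z| > 6 on classical moments, single pass,
columns with < 3 observed values untouched) is a dataset-level curation step
applied before splitting.  The network chain proper is fit on the training
split only and applied unchanged to held-out rows:

1. per-participant division by the mean over all non-missing proteins
   (average-level normalization; stateless);
2. 10-nearest-neighbour imputation with training rows as the donor pool
   (nan-Euclidean distance over mutually observed proteins, scaled by shared
   count — scikit-learn's `KNNImputer`); a protein never observed in training
   aborts fitting rather than fabricating a feature;
3. rank-based inverse-normal transform: training values map to
   Φ⁻¹((r − 0.5)/n) with average ranks for ties; held-out values interpolate
   the training empirical quantile function linearly and are clipped to
   [Φ⁻¹(0.5/n), Φ⁻¹((n − 0.5)/n)].

The imputer and rank normalizer are fit on the selected panel columns (the
network's input space); imputing the full matrix would cost
O(n² × all proteins) per split without changing any network input.  Tree
baselines use training-split z-scoring instead (trees are invariant to
monotone per-feature maps, so the rank chain is unnecessary there).

## Feature selection

Per train+validation split, two stages per condition, union over conditions:

* **Association stage** — per protein, OLS of natural-log abundance on the
  condition indicator, age, sex and the participant's average log protein
  level; the condition coefficient is reported as a fold change exp(β), with
  BH adjustment across proteins within condition.  Proteins with fold change
  > 2 or < 0.5 survive; the top 5 by adjusted p are kept.  The log link makes
  the two thresholds symmetric multiplicative effects.  Missing abundance
  cells are mean-filled per protein within the fitted subset (the vectorized
  all-protein solver needs a complete response matrix; at the ≤ 2% default
  missingness this is inconsequential).
* **Predictive stage** — train+validation is resplit into ten stratified
  subfolds; one boosted-tree classifier per rotation; a protein is kept iff
  every rotation's model used it in at least one split.  The boosting
  configuration (learning rate 0.1, 200 rounds, depth 3, per-tree column
  subsample 0.1) is chosen so that split gradients stay alive on easily
  separable rare conditions and splits spread across the whole informative
  pool — without this the all-rotations intersection collapses onto a
  handful of dominant markers and discards redundant true signal.  A small
  depth/subsample grid is tuned on the first rotation's held-out subfold and
  reused for the remaining rotations.  A univariate screen keeps the top 250
  proteins by two-sample t statistic before any tree is grown; both reuse and
  screen are single-CPU scaling choices that leave strongly informative
  proteins untouched.

## Evaluation

Balanced classification accuracy (mean of sensitivity and specificity) is the
primary metric; rank-based AUC (ties half credit) is reported alongside.
Cross-validation is site-stratified: each site's participants are split into
k near-equal folds (round-robin after shuffling; sites smaller than k are
distributed with a warning), rotations use k−2/1/1 folds for
train/validation/test.  Leave-one-site-out reserves one whole contributor as
the test split and splits the rest site-stratified at 8:1.

Model comparisons use the variance-corrected resampled t-test
t = d̄ / sqrt((1/k + n_test/n_train) s²_d) with k−1 degrees of freedom; the
test/train ratio is 1/9 for the 9–1–1 ten-fold design (the validation fold
counts as training-side data) and the mean per-split ratio for
leave-one-site-out.  Multiple testing uses Benjamini–Hochberg throughout at
α = 0.05.

The two-model ensemble mixes the network's and the boosted-tree baseline's
probabilities per condition as w·p_net + (1−w)·p_tree, with w searched on the
validation split over {0, 0.01, …, 1} and an F1 threshold re-selected for
each candidate mixture (without which the mixture has no decision rule).
Because the grid contains both endpoints, the selected mixture's validation
BCA can never fall below either component's.

## Interpretation

* **Permutation importance** — per panel protein, the column of the
  *preprocessed* test matrix is shuffled across participants and the
  per-condition cross-entropy increase recorded over 100 shuffles; z =
  mean/sd, one-sided normal p (importance = loss increase), BH adjustment
  within condition.  Permuting after preprocessing keeps the imputer out of
  the feature under test.  Across splits, importances aggregate as fold
  counts (splits with adjusted p < 0.05) and mean z over the splits in which
  the protein was on the panel.
* **Embedding importance** — the sample covariance between each embedding
  dimension and each condition's predicted probability over a reference
  population (for a linear readout this equals head weight × embedding
  variance, which the tests verify in closed form).
* **Embedding signatures** — boosted-tree regression of one embedding
  dimension on the panel proteins with validation-based early stopping;
  proteins with cumulative split gain above 50 form the signature.  The gain
  threshold lives on the booster's native scale and assumes a roughly
  unit-scale target; it is exposed as a parameter for that reason.
* **Probability map** — t-SNE of the 6-D probability vectors of participants
  with exactly one positive label (all-negative and multi-positive excluded).
  Perplexity defaults to 1,000 but is capped at n/4 — the headline value
  assumes a consortium-scale population.  Out-of-sample points are placed by
  distance-weighted average of the coordinates of the 10 nearest reference
  participants in probability space (simple, deterministic, and adequate in
  6 dimensions).  Density contours per diagnosis are cut from a Gaussian KDE
  (Scott bandwidth) at level 0.01.
* **Subtyping** — k-means on one diagnosis's 2-D coordinates for k = 2…10,
  the silhouette-maximal k wins.  Clusters below 5 members are treated as map
  outliers: their members are excluded from the labeling and the silhouette
  is scored over the remaining clusters (plain silhouette otherwise rewards
  isolating two or three extreme points — e.g. rare unlabelled co-pathology
  profiles — and clusters that small support no differential abundance); the
  reported k is the number of retained clusters.  Cluster differential
  abundance fits, per
  protein, log abundance ~ cluster indicators + age + sex + site + average
  protein level on that diagnosis's positives (clusters under 5 members are
  excluded; exactly collinear columns are dropped).  Note that the
  average-protein-level covariate absorbs the shared fraction of any broad
  one-directional shift, so coefficients for m shifted proteins out of p are
  attenuated by roughly (1 − m/p).

## Clinical translation

* **K-shot transfer** — the frozen model embeds the new site's participants;
  a default-configuration logistic head is fit per condition on a stratified
  K-sample (K = 100, 20 repeats) and evaluated on the remainder
  ("FineTune"), against a logistic model on z-scored raw panel proteins
  ("Retrain").  Distributions over repeats are always reported.
* **Progression** — among baseline-CDR-0 participants with non-decreasing
  follow-up CDR, ten-fold CV of a default logistic head on baseline
  embeddings; each fold's call threshold is F1-selected on its training
  predictions (progressors are a small minority, so a fixed 0.5 cutoff would
  rarely call anyone).
* **Two-cutoff calibration** — on a derivation set, the lower cutoff is the
  largest probability threshold with NPV ≥ target below it and the upper the
  smallest with PPV ≥ target above it (candidates are midpoints of sorted
  unique probabilities; defaults 0.90/0.90, alternative PPV targets
  supported).  The zone between is indeterminate — confirmatory testing
  advised, no numeric claim attached.  Fully separable derivation sets make
  the zone empty; crossed cutoffs (possible under loose targets) are flagged.
* **Individual report** — per condition, sampling-based Shapley attribution
  (default 128 permutations, training participants as the background set;
  pinned to the closed form weight × (x − background mean) for a linear
  model) yields the top ±10 contributing proteins; probabilities are
  reported zero-centred as log(p / threshold); the participant is projected
  onto a fitted probability map; an optional user-supplied protein→trait
  table annotates contributors.

## Synthetic cohorts

The generator emulates the structure of a multi-site aptamer-proteomics
consortium.  Log-abundance is additive (multiplicative on the RFU scale):
per-protein baseline N(7, 1); per-condition planted effects (40 disjoint
proteins per condition by default, fold changes uniform in [1.5, 3], half
inverted to decreases) applied to that condition's positives; per-site,
per-protein batch shifts (sd 0.2) and noise-scale factors (sd 0.05); small
age and sex slopes; N(0, 0.3) measurement noise; 2% of cells missing
completely at random.  Labels are thresholded latent liabilities from a
multivariate normal with exchangeable correlation 0.1 (co-pathology), at
marginal prevalences 0.30/0.20/0.15/0.05/0.05/0.10 for
control/AD/PD/FTD/ALS/stroke-TIA — imbalanced the way dementia consortia
are; 10% of each condition's labels are masked per condition (never
imputed).  Cognition (MMSE, CDR) is generated consistently with dementia
status, and progression labels follow a logistic link on ten AD-planted
proteins with coefficients signed by each protein's planted direction, with
the intercept calibrated to the requested progressor fraction; longitudinal
CDR sequences are emitted consistently with the flags, and a 5% transient
CDR blip creates the non-monotone sequences the eligibility rule must
exclude.

Planted within-condition subtypes emulate an unassessed co-pathology:
subtype B of a condition's positives receives most of a second condition's
signature (16 of its planted proteins, factor 2.5 applied in each protein's
own disease direction) plus 8 shifted null proteins, and its label for the
second condition is set missing.  The direction-consistent shift matters:
shifting all markers upward regardless of their disease direction largely
cancels in the second condition's logit, and leaving the label observed
(negative) trains the model to discount exactly the profile the subtype
carries.

What the generator does **not** emulate: aptamer cross-reactivity,
plate/bridging artifacts, serum-vs-plasma modality differences, longitudinal
proteomic drift, non-Gaussian heavy-tailed noise, realistic linkage between
covariates and liability.  Passing tests therefore demonstrate that the
machinery recovers known structure under a fair generative model — not that
comparable accuracy would be reached on real consortium data.

## Problem sizes

The standard study conditions are 4,000 participants × 2,000 proteins × 10
sites with 40 planted proteins per condition, run through site-stratified
10-fold cross-validation.  The companion experiments use smaller dedicated
cohorts: site-generalization (1,500 × 400, 5 sites, site shift sd 1.0 —
deliberately strong batch effects), K-shot transfer (2,400 × 500, 6 sites,
one full site held out), subtype recovery (1,600 × 360, 4 sites).
`scripts/acceptance.py` runs the same pipeline end-to-end at 2,000 × 800
with 5-fold rotation.  These sizes are the package's own desk-scale choices;
all thresholds asserted in the tests are stated in the test suite itself.

## Known limitations

* The numpy network is CPU-only and modest in size by design; it is not a
  drop-in for GPU-scale training.
* t-SNE out-of-sample projection by kNN interpolation is a heuristic; points
  far from the reference distribution are pulled to its hull.
* The boosted-tree consensus is sensitive to its exploration settings (see
  above); with greedy defaults it under-selects redundant markers.
* The two-cutoff guarantees are exact on the derivation set only; held-out
  performance carries binomial error.
* Cognition and progression in the generator are simplistic (single blip
  mechanism, two-stage CDR); they exist to exercise eligibility logic and
  embedding transfer, not to model disease course.
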