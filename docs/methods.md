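# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic cohorts can and cannot establish.

## Value spaces and preprocessing

Methylation enters as beta values β ∈ [0, 1] (methylated fraction per CpG).
All modelling happens on M values, M = log2(β / (1 − β)), because the M
scale is variance-stabilized near 0 and 1 where beta compression hides small
changes.  Betas are clipped into [ε, 1 − ε] with ε = 1e-5 before the
transform, bounding |M| by log2((1 − ε)/ε) ≈ 16.61; ε is configurable for
sensitivity analyses.  The transform is applied before probe filtering —
the order does not affect results, but fixing it keeps runs deterministic.

Cell-type fractions (epithelial, neutrophil, other immune) are estimated per
sample by nonnegative least squares against reference beta profiles,
rescaled to sum to at most 1.  This is a deliberately simple estimator
behind a pluggable interface: the pipeline only needs the epithelial
fraction as an association covariate, and the robust-regression refinements
of published deconvolution tools do not change that contract.  Cell
fractions are never used as training inputs — they are derived from the
same methylation and would leak signal into the predictors.

## Feature selection

Each CpG is scored by Pearson correlation with the target (point-biserial
coding for binary targets), and the top K by |r| are kept.  Absolute rather
than signed correlation is used because hyper- and hypomethylation both
carry signal and the downstream models are sign-agnostic; the choice is
switchable.  Zero-variance probes receive r = 0 so the ranking is total,
and ties break lexicographically by probe ID for cross-platform
reproducibility.  For race/ethnicity the selection is the union of
per-class top-K lists against one-hot indicators over the five named
classes (the catch-all "Other" class contributes no list), giving a union
of size between K and 5K.

## Classifier protocol

Random forests are tuned by exhaustive search over tree counts
(20, 50, 100, 200, 500, 1000, 2000) and maximum depths (2–7), each cell
scored by mean accuracy over 5-fold cross-validation with one fixed fold
assignment shared across cells, so differences between cells are purely
hyperparameter effects.  Ties go to fewer trees, then shallower depth
(parsimony).  Folds are stratified by class by default: with the cohort's
most imbalanced ancestry class a plain split can leave a class unseen in
training.  At the winning cell the forest is re-run under the same CV
scheme to collect one out-of-fold prediction per sample; confusion
statistics (accuracy; Cohen's κ from row/column marginals; one-vs-rest
sensitivity, specificity and balanced accuracy) are computed on that pooled
vector, and the final model is refit on all data.  For smoking, the smoker
class is the declared positive class, so sensitivity reads as smoker
recall.  Forest hyperparameters other than tree count and depth follow
scikit-learn defaults and are recorded in the fit provenance.

## Regressor protocol

The regressors are feed-forward networks — linear layers with ReLU between
them, a scalar linear readout, full-batch Adam on the MSE loss.  The
reference protocol is learning rate 1e-6 for 2,500 epochs with hidden-layer
presets () / (2000) / (2000, 500) / (2000, 500, 50); these are the library
defaults.  Tests and the acceptance script use a desk-scale protocol
(hidden widths (64, 16), learning rate 0.01, 300–400 epochs) chosen so the
loss reaches its asymptote on cohorts of a few hundred samples; any
deviation from the reference settings is flagged in provenance.

Numerical choices that materially affect convergence:

* **Input standardization.** Each input is z-scored on the training fold.
  Raw M values have probe-dependent scales, and tiny-step optimization on
  unstandardized inputs stalls.
* **Target centering.** The network fits y − ȳ(train) and predictions add
  ȳ back.  Adam steps are bounded by the learning rate, so the output bias
  could not otherwise travel to a target mean of ~55 years in any
  reasonable epoch budget.
* **Initialization.** Weights are seeded uniform fan-in,
  U(−1/√fan_in, 1/√fan_in); biases start at +0.1 so every rectified unit is
  initially active.  With sparse (masked) fan-in, a zero-centered start
  leaves many units dead from epoch one and their gradients never recover.
* **No mini-batching.** Gradients are full-batch; training is exactly
  reproducible for a seed.

Alcohol is modelled on a 0–1 scale with the five weekly-consumption
categories mapped to 1, 0.75, 0.5, 0.25, 0 (1 = no alcohol, 0 = 15+
drinks).  Only the endpoints are externally fixed; even spacing of the
interior levels is this package's choice and custom weights can be passed.
Delta age is predicted minus chronological age, computed from out-of-fold
predictions so each sample's delta is not inflated by its own training.

## The explainable clock

The masked network is CpG → gene → gene set → age.  A CpG connects only to
genes it is annotated to; a gene connects only to sets containing it; the
set → age readout is dense.  Masks are binary matrices applied
multiplicatively to weights and gradients, so masked-zero weights are
exactly zero at initialization and after every optimizer step — sparsity is
structural, not a penalty.  Construction prunes unannotated probes, genes
absent from every set (they could never influence the output and would
unfairly widen the dense control), sets with no retained gene, and probes
left without a surviving gene.  A probe annotated to several genes fans out
to all of them.  The gene-set layer is rectified before the readout like
every other hidden layer.

Interpretability reads two quantities off the trained model: the absolute
readout weight per set (global ranking of processes the clock uses) and the
per-sample post-ReLU activations of the set layer (an individual's pathway
profile).  The control model uses fully-connected layers of identical
widths; since it strictly generalizes the masked hypothesis class, its
out-of-fold accuracy is the reference point for the cost of the biological
constraint.

## Importance, attribution, enrichment

Forest importance is normalized mean decrease in impurity with per-tree
standard deviations.  Network attribution is integrated gradients along the
straight path from a baseline to each sample, with the baseline the mean of
a background panel (first 100 samples by convention).  For ReLU networks
the path integrand is piecewise constant, so a midpoint Riemann sum
converges quickly and attributions satisfy completeness (they sum to
f(x) − f(baseline)); the implementation is checked against a much denser
Riemann oracle and against the exact closed form for linear models.
Per-sample attributions are averaged over all samples and ranked by
absolute value; the top 1,000 CpGs feed the enrichment analyses.

Both enrichment analyses are upper-tail hypergeometric tests with BH FDR
and a significance call at FDR < 0.1.  Gene-set ORA maps top probes to
their genes (deduplicated) against the universe of genes annotated to any
probe; an optional permutation null (redrawing equally many probes) guards
against probes-per-gene bias and is off by default.  Genomic-feature
enrichment tests each CpG-island-relation and regulatory-group category of
the top probes against the array background, with FDR within each family.

## QC and associations

Batch screening runs PCA on mean-centered M values (components ordered by
explained variance, sign fixed so the largest-|loading| element is
positive) and evaluates, for each component separately, the mean silhouette
width of each plate with absolute-difference distance in that 1-D
embedding.  The per-component reading is the primary one — a batch
"clustering across one of the principal components" is a statement about
single components — with a joint-space variant behind a flag.  Singleton
batches get width 0 by convention.  Because positive widths arise by chance
in finite samples, calibration is against a permutation null: labels are
shuffled, and observed widths are compared with the 95th percentile of the
null widths.

Associations are ordinary least squares of an outcome (delta age, or a
predicted phenotype) on chronological age, epithelial fraction, BMI, nine
0–1 lifestyle scores, sex, smoking, alcohol and race/ethnicity.
Categorical covariates expand to indicator contrasts against their largest
level (stabilizes contrasts under heavy imbalance); p-values are two-sided
t-tests, BH-adjusted across the covariates of one model; rank-deficient
designs raise an error naming the collinear columns.  Welch's
unequal-variance t-test with Welch–Satterthwaite degrees of freedom serves
pairwise category contrasts; two degenerate zero-variance groups with equal
means return p = 1.

## The synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
ages uniform on 18–93; smoking ~ Bernoulli(0.228); six race/ethnicity
classes with realistic imbalance (dominant class ≈ 67%, smallest ≈ 1.4%);
BMI ~ N(27, 5²) clipped to [16, 50]; alcohol from a latent Beta(3, 1.2)
healthiness score binned into the five categories; nine lifestyle scores
uniform on [0, 1].  Signals are planted on the M scale at disjoint probe
subsets — linear in age (default slope 0.02 M/year over 300 CpGs at the
default 5,000-probe size), a smoking mean shift (1.0 M), linear BMI and
alcohol effects, and per-class ancestry shifts — then Gaussian M-noise
(sd 0.1) is added and values map to beta through the inverse transform, so
betas are strictly inside (0, 1).  Effect sizes are not estimates of any
real cohort (no public data exists to calibrate them); they are set so that
planted signals are comfortably recoverable at desk scale, which is what
the recovery tests require.  Batch labels are assigned round-robin over
plates; a nonzero `batch_shift` adds a per-plate offset to a random 10% of
probes.  An optional nonlinear mode replaces the linear age signal with a
monotone quadratic of the same amplitude — informative at every age but
systematically biased for a linear readout — which is what makes the
architecture-sweep ordering testable.  For pathway-recovery scenarios,
`set_overlap=0` partitions genes into disjoint sets and `planted_set`
restricts age probes to probes annotated exclusively to that set's genes,
so all age signal funnels through one named pathway.

The annotation gives 60% of probes one to three genes (70/20/10%), spreads
genes round-robin plus random overlap into two collections ("pathways",
"tf_targets"), and draws island/regulatory categories from fixed
frequencies.  Everything is deterministic given the seed.

What passing tests therefore show: the pipeline recovers signals of the
planted form at these sizes and noise levels, its statistics match exact
oracles, and its structural contracts hold.  What they do not show:
performance on real buccal data, where effects are smaller and correlated,
probes are not independent given covariates, cell composition confounds
signal, and annotation is far denser — headline numbers from any real
cohort are not reproducible from synthetic data and are not asserted here.

## Problem sizes used in tests

The test and acceptance runs use cohorts of 200–500 samples with 600–5,000
probes, top-K selections of 100–1,000 CpGs, the (64, 16) hidden preset, and
reduced RF grids — the package's desk-scale protocol, chosen so the whole
suite exercises every stage end-to-end in about a minute while keeping
every recovery margin wide.
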