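# Methods

This note documents the statistical machinery of `glmaid`: the factorial
GLM and its tree-structured application (GLM-AID), the sigmoid perceptron
used for authentication, and the synthetic cohort generator that stands in
for the original, undeposited sample-level data.

## The problem

A tomato sample is described by 25 chemical parameters (sugars, organic
acids, hydroxycinnamic acids, minerals, protein, fibre, lycopene, total
phenolics; fresh-weight units) and three categorical factors: cultivar
(Dorothy, Boludo, Dominique, Thomas, Dunkan), agricultural practice
(conventional, organic, no-soil) and harvest date (October, December,
February, April). Two complementary questions are addressed:

1. **Characterization** — which parameters carry the main significant
   differences between factor levels? Answered by a recursive
   partitioning (AID) scheme driven by a factorial general linear model.
2. **Authentication** — can cultivar, practice and harvest date be
   predicted from the chemistry alone? Answered by small sigmoid
   multilayer perceptrons.

## Factorial GLM (glm module)

For each parameter the model is

    y = μ + c_i + p_j + h_k + (cp)_ij + (ch)_ik + (ph)_jk + (cph)_ijk + ε

fit by least squares with sum-to-zero level encoding. Terms are tested by
marginal (Type-III) F-tests: the extra residual sum of squares from
deleting the term's columns from the otherwise full design, divided by the
rank difference, against the full-model residual mean square. On balanced
designs this coincides with the sequential decomposition (asserted in
tests against `statsmodels.anova_lm`); on the unbalanced designs produced
by tree recursion it matches the behaviour of mainstream GLM software.
Parameters are standardized to zero mean and unit sample variance
(n − 1 denominator; the choice is immaterial at n = 167 but is fixed for
reproducibility) once, globally, before any fit — F statistics are
invariant to this, so node summaries report raw-scale means ± SD.

**Explained variance** is the unadjusted model R² × 100. Whether the
original analysis used raw or adjusted R² is not documented; unadjusted is
the default and the only value the tests assert.

**Degenerate designs.** Inside small subgroups some level combinations are
absent. Fully aliased terms (no rank gain over the rest of the model) are
pruned highest-order-first and reported as inestimable with a warning;
partially aliased terms keep their reduced degrees of freedom. Zero
residual degrees of freedom or a constant response abort the fit for that
parameter only.

**Bonferroni homogeneous subsets.** All L(L−1)/2 pairwise level contrasts
use t statistics on the pooled one-way ANOVA mean square (df = N − L) with
the family-adjusted threshold α/m. Pairwise non-significance is not
transitive, so the grouping is canonicalized by a compact letter display
over mean-ordered levels (maximal runs of mutually non-different levels);
overlapping runs are merged (union-find) into the disjoint blocks that
become child nodes. Any level with fewer than two samples raises a
dedicated error — means of singletons cannot be compared.

## GLM-AID tree (tree module)

At each node, the GLM (restricted to the factors still varying in the
node) is fitted to all 25 parameters, and the split parameter is chosen by
three criteria: (i) exactly one significant single-factor main effect —
the parameter "depends on one predictor", the predictors being the design
factors; (ii) lowest p-value of that main effect; (iii) ties broken by
highest explained variance, then canonical parameter order. Interaction
terms do not define predictors: an incidental interaction hit (expected
at a few percent per null term) does not disqualify an otherwise
single-factor parameter, which keeps the candidate set stable under
resampling — the stated purpose of criterion (i). Parameters with
interaction-only significance (ascorbic acid in the reference pattern)
have no significant main effect and are excluded either way, and the
criterion reproduces the reference selection (p-coumaric acid first, by
the explained-variance tie-break at 73.6%). The selected factor's Bonferroni blocks define the
children; if a candidate yields a single block the next-ranked candidate
is tried, and a factor may be re-split further down while more than one of
its levels remains in a node. Recursion stops (with a machine-readable
reason) on: no significant term anywhere, no parameter satisfying
criterion (i), a singleton level, all factors reduced to one level, or no
candidate producing more than one block. Depth is capped at three splits
per path — one per factor. Node ids follow breadth-first creation order.
Alpha defaults to 0.05 (the reference table prints only sub-0.05
p-values, consistent with that threshold); it is a parameter of every
entry point.

On default synthetic cohorts the root reliably splits on p-coumaric acid
by harvest into four month-pure children, mirroring the reference
analysis; deeper structure (practice splits on glucose/P/Na/Mg, cultivar
splits where possible) is qualitatively similar but not node-for-node
identical — per-node membership of the original data is unrecoverable.

## Sigmoid perceptron (nn module)

Three layers, "input-intermediate-output" (e.g. 10-18-1): propagation
S_i = Σ w_ni x_n + b_i and activation y = 1/(1+e^(−S)) applied uniformly
at both layers; error E = ½ Σ (d − y)². Inputs are min-max scaled to
[0, 1] on training ranges; each categorical output variable occupies one
neuron with equally spaced codes k/(K−1) (decoding snaps to the nearest
code, ties to the lower index) — forced by the reference topologies, which
use 3 output neurons for the joint model and 1 for single-variable models,
not one-hot blocks.

Training is per-example (online) gradient descent with momentum; one cycle
is one seeded-shuffled pass over the training rows, and `train` runs an
exact cycle count with no early stopping (overfitting is controlled by the
cycle budget). Weights initialize uniformly in [−0.5, 0.5]. Defaults are
learning rate 0.6 and momentum 0.8; both are logged in every artifact and
the analyses here are not sensitive to moderate changes. The analytic
backpropagation gradient is verified against central finite differences in
the test suite. `train_until_plateau` wraps `train` for budgeted sweeps,
stopping once the best chunk-final error of the last 8 checks (250 cycles
each) is no longer 1% better than the best before them.
`train_ensemble` trains seed replicates in lockstep on a shared shuffled
order, vectorizing the identical per-example update across networks; it is
how the best-of-5-seeds evaluation protocol is run at tolerable cost.

**Evaluation.** The Average Percentage of Success, APS = 100 × matches/N,
is computed separately for the training (151) and validation (16) phases;
the pooled "average" merges both sample sets (sample-weighted; a plain
mean of the two phase values is available behind a flag — which convention
the original table used is not documented). Per-class success percentages
are pooled over both phases. Reported values are rounded to one decimal,
half-up.

**Variable importance and reduction.** Importance of an input is the sum
of absolute input→hidden weights, normalized to percent shares. The
reduction step averages shares over the best joint 25-input model and the
three single-output 25-input models (which 25-input models feed the
average is configurable) and keeps the top k = 10, ties broken by
canonical parameter order. The packaged constant `REDUCED_INPUTS` records
the reference study's selection (glucose, lycopene, P, Na, K, Mg, Fe,
chlorogenic, caffeic, p-coumaric acids), which the authentication
surrogates use directly as printed input data.

**Model selection** picks, per output variable, the catalog entry with the
highest validation APS (ties: higher pooled average, then smaller hidden
layer) — validation, not training, performance is the criterion.

## Synthetic cohort generator (cohort module)

No sample-level data are deposited, so every pipeline stage is exercised
on synthetic cohorts drawn from an explicit generative model:

    value = grand_mean + Σ active-term offsets + N(0, residual_sd),

clipped at a lower bound (0 for all concentrations) and left-censored to
exactly 0 below a detection limit. The default configuration encodes the
published per-parameter summary:

- grand means and SDs as printed for all 25 parameters;
- active terms exactly those printed as significant; offsets of each term
  sum to zero (interaction offsets are additionally margin-free, so
  planted interactions do not leak into main effects);
- the explained-variance share of each parameter is divided equally among
  its active terms and the residual SD absorbs the remainder, so the
  full-model R² of a large generated cohort approximates the published
  explained variance;
- four practice main effects are anchored to published per-level means
  instead of random directions: glucose (conventional ≈ 1.21% vs 0.85%),
  P (no-soil ≈ 300 vs 226 mg/kg), Na (conventional ≈ 146, no-soil ≈ 82
  mg/kg) and Mg (organic highest, no-soil lowest). Without these anchors
  the production systems would be nearly inseparable, contradicting the
  reference analysis, which classifies production correctly within every
  harvest date;
- p-coumaric acid is special-cased: harvest offsets reproduce the
  published month means (0.52, 0.17, 0.02 mg/100 g, and April as a
  non-detect); its residual SD is the published within-February SD (0.01)
  and its detection limit 0.002 mg/100 g, a realistic HPLC quantification
  floor. The published grand "content" (0.02 ± 0.03) is inconsistent with
  those month means under any zero-sum decomposition; the generator keeps
  the grand mean at 0.02 and lets the April offset balance the term far
  below zero, where clipping and censoring produce the non-detects.

The default design allocates 167 samples over the 60 cells (every cell at
least 2; 47 cells of 3, chosen by a seeded round-robin — the original
allocation is unpublished). A single master seed drives sampling;
per-parameter substreams are derived by stable-hashing the parameter name,
so adding a parameter never perturbs the others. The effect-offset draws
use a separate fixed entropy constant: they are part of the packaged
default configuration, not of the sampling seed.

**What the generator does not emulate.** Measurement-method error
structure (HPLC vs atomic absorption), heteroscedasticity across factor
levels (the model is homoscedastic per parameter, while e.g. the published
October p-coumaric SD is 0.23 vs 0.01 in February), skewness of trace
concentrations, climate covariates, and any cultivar structure beyond the
printed significance pattern. Two visible consequences: the synthetic
explained variance of p-coumaric acid (≈99%) exceeds the published 73.6%
— the month means and the non-detect behaviour are preserved instead, as
they drive the tree — and a small fraction (~3–4%) of synthetic February
samples fall below the detection limit through the Gaussian tail, whereas
the original data report February as fully detected. Passing tests on
synthetic cohorts therefore demonstrate correctness of the machinery and
qualitative reproduction of the published structure, not quantitative
re-analysis of the original samples.

## Problem sizes and numerical choices

Worked examples on the published summary run instantly; cohort-level
checks use the 167-sample default; calibration/recovery properties use an
inflated ~10,000-sample design; the null-uniformity property of the GLM
p-values uses 2,000 simulated fits at n = 60. The authentication
surrogates follow the published protocol at desk scale: 151/16 stratified
split, 10-18-1 for harvest at exactly 1,000 cycles, and 10-9-3 for the
joint model trained with the plateau rule inside a 400,000-cycle budget
(in practice it stops near 8,000–20,000 cycles), each taking the best of
5 training seeds. Least-squares fits use `numpy.linalg.lstsq` with a
rank tolerance of 1e-10; sigmoid evaluation is branch-split to avoid
overflow; all randomness flows through `numpy.random.default_rng` with
explicit seeds.

## Known limitations

- Criterion (i) is sensitive to incidental significance: with seven terms
  per parameter, a truly single-factor parameter shows a second
  significant term in a few percent of nodes, and is then excluded there.
  This matches the literal selection rule of the reference analysis.
- Compact-letter merging can join levels that differ significantly when
  non-significance is non-transitive (a, b alike; b, c alike; a, c
  different); the merged block is the canonical resolution documented
  above.
- The homogeneous-subset partition, not the letter display itself, drives
  child creation; the display is retained in the node for reporting.
- Validation APS on 16 samples is quantized to 6.25-point steps; small
  differences between models are not meaningful at that resolution.
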