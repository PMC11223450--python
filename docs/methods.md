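# Methods

This note documents the models and procedures implemented in `cvdhybrid`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that fix otherwise
ambiguous quantities.

## Cleaning rules

Missing handling is row deletion, not imputation: any row containing the
missing marker is dropped. Duplicates are exact matches on all attribute
values *and* the label; the first occurrence is kept. Cleveland-style
severity labels 0–4 are binarized at > 0 (the standard presence/absence
convention for that dataset); Statlog labels 1/2 map to 0/1. Normalization
is min-max to [0, 1]; its statistics are computed on the training split
only and re-applied (with clipping) to held-out data, so no test
information leaks into the transform. A constant attribute maps to 0 with
a warning.

## Feature extraction

The extraction semantics were genuinely open — the defining expression
only names the four symbol families — and we fixed them as: **descriptor
families are computed row-wise** (one value per sample, summarizing its
normalized attribute profile), **symmetric uncertainty is computed
column-wise** (one relevance score per attribute). Column-wise descriptor
constants would be useless as classifier inputs, and SU requires the class
vector, so this is the only reading under which every family is both
well-defined and informative. The assembled matrix is
F = [X | F_CT | F_D | F_QV]; with 13 attributes it has 13 + 12 + 9 + 8
= 42 columns. SU scores are additionally computed for every assembled
column (`su_all`) so the selection fitness can reward relevance uniformly
over its whole search space.

Numerical conventions:

* **Quartiles** use linear interpolation on sorted order statistics (the
  "inclusive" scheme, numpy's default). This fixes the interquartile mean,
  midhinge `(C1+C3)/2`, trimean `(C1+2·C2+C3)/4` and the quartile
  coefficient of dispersion `(P3−P1)/(P3+P1)`.
* **Interquartile mean** is implemented exactly as its printed summation
  form, `(2/n) Σ sorted[i]` over 1-based indices `⌊n/4⌋+1 … ⌊3n/4⌋`. It is
  listed among the central-tendency descriptors; the conventional
  `IQR = P3 − P1` lives separately in the dispersion family.
* **4-level discretization** of [0,1] values: `[0,0.25]→1, (0.25,0.5]→2,
  (0.5,0.75]→3, (0.75,1]→4`. The level boundaries are printed with
  overlapping endpoints, so the upper-inclusive tie rule (ties go to the
  lower level, 0 to level 1) is fixed here once.
* **Mode of continuous data** is the modal 4-level bin of the min-max
  normalized vector mapped back to the bin midpoint on the original scale
  (a continuous mode is otherwise ill-defined on 13 points).
* **Undefined descriptors** (geometric/harmonic mean with a nonpositive
  entry, CV with zero mean, quartile fields at n < 4) are `nan` in the
  descriptor dataclasses and 0.0 in the assembled matrix.
* **Trim/winsorization proportion** defaults to 0.1 per tail
  (configurable); no value is prescribed anywhere, and 10% is the common
  textbook default.
* **Descriptor SD** uses the population divisor n; the multi-run accuracy
  summary uses the sample divisor n−1. Both choices are stated at the
  definition site.
* The **B index** of qualitative variation is Wilcox's form
  `1 − sqrt(1 − (K·gm(f)/n)²)` with `gm` the geometric mean of the level
  counts: 0 at zero variation, 1 at the uniform distribution. Of the
  larger historical catalogue of qualitative-variation indices only the
  eight named in the README are implemented; the ecology-specific ones
  (rarefaction, Fisher's alpha, taxonomic distinctness, …) do not apply to
  a fixed 4-level discretization of clinical attributes.
* **Symmetric uncertainty** uses base-2 entropies of empirical joint
  frequencies with `0·log 0 := 0`, and is defined as
  `2·I/(H(Q)+H(P))` — the sum in the denominator is the standard
  normalization (and the only one for which identical vectors score
  exactly 1); SU := 0 when both marginal entropies vanish.
* `continuous_entropy` is an equal-width histogram estimate of
  differential entropy with `⌈√n⌉` bins, used to verify the scale law
  `H(c·x) = H(x) + log c` that motivates treating entropy as a
  scale-free dispersion measure.

## The SIAO optimizer

Baseline Aquila Optimization with population N, T iterations, four phases
switched at `t ≤ (2/3)T` and a fair coin:

* `X1 = X_best(1−t/T) + (X_M − X_best·rand)` (expanded exploration),
* `X2 = X_best·LF(D) + X_R + (y−x)·rand` (narrowed exploration; `X_R` a
  uniformly chosen population member, excluding the current individual;
  Lévy steps by the Mantegna scheme `s·u·σ/|v|^{1/K}` with K = 1.5,
  s = 0.01, `σ(K=1.5) ≈ 0.6966`; spiral terms `r = r1 + 0.00565·D1`,
  `φ = −ω·D1 + 3π/2`, ω = 0.005, r1 drawn uniformly from {1,…,20}),
* `X3 = (X_best−X_M)·α − rand + ((UB−LB)·r + LB)·δ` with α = δ = 0.1
  (expanded exploitation),
* `X4 = QF·X_best − G1·X·rand − G2·LF(D) + rand·G1`,
  `QF = t^{(2·rand−1)/(1−T)²}`, `G1 = 2·rand−1`, `G2 = 2(1−t/T)`
  (narrowed exploitation).

Several of these update rules are printed in garbled form in the
literature; the forms above are the standard published AO equations and
are the ones implemented. `rand` is drawn fresh per use and per dimension,
except QF, G1, G2 which are scalars per candidate. Bound handling is
clamping. Acceptance is greedy (strict `<`) against both the individual's
current position and the global best, so the best-so-far history is
non-increasing by construction. Non-finite fitness values reject the
candidate and are counted.

The **self-improved** variant changes the `X3` phase only: the scalar
random number feeding the descent term is a logistic-map iterate
(`x ← μx(1−x)`, μ = 4; states at the fixed points {0, 1−1/μ} or outside
(0,1) are reseeded with a warning), and each `X3` step is followed by an
arithmetic crossover — two distinct members a, b, offspring
`λa+(1−λ)b` and `(1−λ)a+λb` with λ ~ U(0,1), each greedily replacing its
parent. With `self_improved=False` the optimizer is baseline AO; on shared
seeds the two produce identical traces until the first exploitation
iteration, which the test suite checks.

**Feature-selection wrapper.** Positions live in [0,1]^n_columns and are
thresholded at 0.5 (a hard transfer, not a sigmoid: the bounds are already
the unit box and a hard rule is deterministic and testable). Fitness is
`w_err·err(S) + w_card·|S|/n − w_su·meanSU(S)` with defaults
(0.94, 0.05, 0.01); the empty subset costs 1. The weights are module
defaults, overridable; the SU term is how the relevance scores enter the
selection stage.

**Known limitation.** On the unit box the printed AO updates are poorly
scaled: the spiral term `(y−x)` has magnitude ≈ r1 ∈ [1,20], so clamped
`X2` candidates concentrate near the all-ones corner, and `X3` is almost
surely negative, clamping to the all-zero (empty) subset. On fitness
landscapes with informative error gradients (the pipeline benchmark) the
wrapper works well, but on flat 0/1 oracle landscapes its coverage of the
subset lattice is limited — with a needle-in-a-haystack oracle over 8
columns (N = 20, T = 100) the planted 3-column target is recovered in
roughly 57% of runs (17/30 seeds measured); once evaluated, the target is
never lost. The strict `<` acceptance also forbids neutral drift across
equal-fitness plateaus. Both behaviours follow the printed algorithm and
are left as is; one end-to-end recovery test documents the shortfall.

## Classifiers

**LSTM.** Standard gated recurrence; a tabular sample is presented as a
univariate sequence — its selected feature values in fixed column order
(fixed order makes runs reproducible; order sensitivity is a documented
property of the architecture, and the tests verify that permuting the
sequence *can* change the output). Hidden size defaults to 8. Training is
full-batch gradient descent on cross-entropy with analytic
backpropagation through time, global-norm gradient clipping at 5, default
learning rate 1.0 for 200 epochs (full-batch gradients are sample means,
hence the relatively large step; the defaults reach ≥ 95% training
accuracy on a linearly separable toy problem, which the suite asserts).
Training is deterministic given the seed; a non-finite loss raises with
advice to lower the rate.

**SIAO weight tuning.** After gradient training the forget-gate
parameters (W_f, b_f; optionally all gates) are flattened into a SIAO
search vector with bounds ±max(2, 1.05·max|w|). The population starts at
the trained values — one member exactly there, the rest jittered
(σ = 0.05) — and fitness is the misclassification error on a validation
fold, so greedy elitism guarantees the tuned weights are never worse
there. Zero iterations is an exact no-op.

**QNN.** Hidden activation `b_r = (1/n_s) Σ_s σ(β(W_r·x − θ_rs))` with
n_s = 3 levels, slope β = 1, 8 hidden units by default, and a single
sigmoid readout (only the hidden layer is prescribed by the multi-level
construction; a sigmoid readout is the minimal binary head). W, θ, the
readout weights and bias are all trained by gradient descent on
cross-entropy — θ is differentiable through the shifted sigmoids — and θ
rows are re-sorted ascending after every update to keep the quantum
intervals ordered. Analytic gradients match central differences to
< 1e-4 relative error (tested). With n_s = 1 and θ = 0 the network is
exactly a one-hidden-layer sigmoid MLP, which the suite uses as an oracle.

**Hybrid.** The prediction is the arithmetic mean of the two
probabilities (averaging probabilities rather than hard labels keeps
MCC/precision non-degenerate), thresholded at 0.5 with ties going to the
positive class.

## Pipeline and evaluation

Each repeat k uses seed `base_seed + k` for data generation, splitting and
all training. The selection fitness trains an **inner** hybrid with
reduced epochs (default 25 LSTM epochs, proportionally scaled QNN epochs)
on at most 300 training rows and scores it on an inner 20% validation
fold — training the full hybrid inside the wrapper would make selection
quadratic in cost. The selected columns then get a full training run, the
forget gate is SIAO-tuned on the validation fold, and the hybrid is scored
on the untouched test split. Metrics with zero denominators are flagged
undefined (`nan`; MCC → 0 with a flag). "Recall" is an alias of
sensitivity — they are the same quantity, and the report exposes one
value under both names.

Multi-run summaries report mean, median, sample SD (n−1), worst and best
accuracy over repeats. The default benchmark sizes — n = 1000 samples,
5 informative of 13 attributes, effect size 2, 90/10 split, 5 repeats,
selection budget 8×12 — are the package's standard desk-scale conditions;
they are what the acceptance script and the heavy end of the test suite
run.

## The synthetic generator

Class-conditional Gaussians: informative attributes have class means at
±effect/2 (unit variance), noise attributes are standard normal; labels
are Bernoulli(class_balance). The last three attributes are quartile-binned
to four ordinal levels to mimic cp/slope/thal-style fields. Missing
markers (one `?` cell in each of ⌊n·missing_rate⌋ distinct rows) and exact
duplicate rows (⌊n·duplicate_rate⌋ verbatim copies, label included) are
injected so the cleaning rules are exercised; defaults are 2% each, with a
balanced class prior and the first five attributes informative. The
generator is deterministic per seed and returns the planted ground truth.

What it deliberately does **not** emulate: the marginal distributions,
attribute correlations and label noise of real clinical tables — it is an
analytic control with known effect sizes, so passing the recovery and
chance-level tests shows the machinery is correct and calibrated, not that
any particular accuracy will transfer to real heart-disease data. A null
variant (effect 0, no injection) provides the independence control: every
attribute's SU tends to 0 and classifier accuracy to chance.

## Degenerate inputs and edge rules

Empty files, malformed row arity (reported with line number), labels
outside the dialect's domain, all-rows-dropped cleaning, single-class
results (flagged, not fatal), stratification with a class of < 2 members
(falls back to unstratified with a warning), constant attributes,
fewer than 4 attributes (quartile-based row descriptors excluded with a
warning) and empty selected subsets (fall back to all columns with a
warning) are all handled explicitly and tested.
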