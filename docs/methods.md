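# Methods

## Selection model and score scale

The package models a pooled competition assay: Ba/F3-style cells carrying
one library variant each grow under IL-3 withdrawal in a vehicle (DMSO)
condition and a panel of inhibitor conditions dosed so that wild-type
growth is the same everywhere — `d` doublings per sampling interval,
`d = 2` by default (harvests every two wild-type doublings, ~72 h). A
variant `v` with fitness `β_vc` in condition `c` multiplies its abundance
by `2**(d + β_vc)` per interval. On this scale `β = 0` is wild-type-like
growth, `β = −d` is a fully arrested ("dead") variant and `β = 1` is one
extra doubling per interval. Because wild-type growth is pinned at `d` in
every condition, β values are directly comparable across conditions and
the recentered score `γ = β_inh − β_DMSO` isolates inhibitor-specific
effects from folding/expression effects shared with the vehicle.

## Scoring

Scoring estimates β from sequencing counts in three steps, each per
condition independently:

1. **Filtering.** Over the condition's replicate × timepoint grid
   (missing cells counted as zeros and flagged), keep a variant iff mean
   count ≥ 4, zero-cell fraction ≤ 10/12, and T0 zero fraction ≤ 2/3. All
   thresholds are inclusive; the fractions (not the integer counts) are
   the configuration, so designs with other grid sizes work unchanged.
2. **Wild-type normalization.** `m = log2(count + pseudocount)` minus a
   per-sample center, the median (configurably the mean) of the same
   quantity over the synonymous variants, whose pooled growth carries the
   wild-type reference — no separate wild-type species is tracked. log2
   (not natural log) keeps the doubling-rate scale. Each trajectory is
   additionally anchored at its own first time point, which changes
   nothing about slopes but makes trajectories translation-free.
3. **Regression.** `m` is regressed by ordinary least squares on the time
   point index t = 1..T (not the fractional time span), one slope per
   replicate; β is the replicate-mean slope and its uncertainty the
   standard error across replicates (infinite sentinel for single-
   replicate designs). This deliberately replaces a full Bayesian
   shrinkage scorer with its frequentist skeleton: the estimand — the
   per-interval slope of wild-type-normalized log2 counts — is identical,
   the replicate SE supplies the test statistic, and every worked example
   and recovery property is defined at this level. Posterior shrinkage,
   priors and local false-sign rates are out of scope.

The pseudocount default is 0.5 (continuity correction for zero cells that
survive filtering). Exact depth invariance of β under per-sample count
rescaling holds at pseudocount 0; with a positive pseudocount it is
approximate at low counts — the property test pins the exact case.

## Classification

A **resistance mutation** for an inhibitor satisfies both:

- a one-sided test of `β_inh > 0.5`: the upper-tail normal probability of
  `(β − 0.5)/se` is ≤ 0.1. The normal approximation on the replicate SE
  preserves the published decision boundary without posterior machinery; a
  SE-free mode (pure effect-size rule `β > 0.5`) serves single-replicate
  designs.
- the vehicle effect-size rule `β_DMSO ≤ 0` (no test, inclusive), which
  discards variants that simply grow faster than wild-type everywhere.

Together these force `γ > 0.5` for every resistance call — asserted as an
output invariant. A **resistance position** is any position with ≥ 1
resistance mutation for that inhibitor. On the recentered scale,
**gain-of-function** is `γ > 0.75` and **loss-of-function** `γ < 0`, both
strict, used for differential-sensitivity pairs (GOF under inhibitor A and
LOF under B, and vice versa; the two sets are disjoint by construction).
The pair analysis defaults to the threshold-only rule; an optional
statistical mode additionally requires one-sided significance of the γ
thresholds at the same 0.1 level. Hotspot tables sum (mutation, inhibitor)
resistance events per position within inhibitor type (I, II, I½, with the
panel's type map shipped as configuration); Venn regions partition the
distinct resistance mutations by type membership.

Condition similarity is pairwise-complete Pearson correlation (so filter
differences between conditions do not null out the matrix), with an
`n_pairs` companion matrix; both raw β and vehicle-recentered γ modes are
exposed, the latter dropping the vehicle column.

## Synthetic data

The generator's default conditions mirror the experimental design: a
saturation library over positions 1059–1345 (20 substitutions per
position, one synonymous each, and an early-stop control every 11
positions anchored at the first position — 5740 + 27 = 5767 variants; the
enumeration convention is pinned by a brute-force oracle in the tests), 11
inhibitors + DMSO, 3 replicates, 4 time points with a shared T0, depth 10⁶
reads per sample, and a uniform starting pool of 200 cell-equivalents per
variant. The design arithmetic (2 libraries × 3 replicates × shared T0 +
12 conditions × 3 harvests = 222 sequencing samples) is encoded and
tested, though simulation runs one library at a time.

Ground truth: synonymous variants are 0 in every condition (the
normalization convention), stop controls sit at −d everywhere, missense
vehicle fitness is a two-component mixture — 60% wild-type-like
(N(0, 0.2)) and 40% loss-of-function (N(−d, 0.4)) — giving the
characteristic bimodal vehicle distribution, and inhibitor fitness is
`min(β_DMSO, sensitive_level)` with `sensitive_level = −d` by default
(inhibitor-arrested), except planted resistance entries which receive
their stated β. Planted entries also carry a vehicle fitness (−0.2 by
default, mildly deleterious): a ground-truth resistance mutation must
itself satisfy the `β_DMSO ≤ 0` arm of the definition, and planting on a
synonymous variant is rejected outright. The wild-type protein sequence
defaults to a fixed synthetic sequence (the real one can be supplied);
nothing downstream depends on residue identities beyond the
synonymous/missense distinction.

Sampling is multinomial per (condition, replicate, timepoint) sample at
the configured expected depth (Poisson per variant as an option), with
stable per-sample random streams spawned from one master seed, and the T0
draw shared across conditions within a replicate. Noiseless mode emits
exact expected counts as floats rather than rounded integers so that the
end-to-end oracle — simulate → filter → score recovers the planted β — is
exact to ~1e−15; integer counts are enforced for sampled data only.

What the generator does **not** emulate: growth-rate stochasticity and
bottlenecks between passages, PCR amplification bias and index hopping,
library composition skew at T0, dose–response (IC50) pharmacology,
epistasis with secondary mutations, and condition-correlated measurement
error. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated sampling model, not robustness to every
artifact of real screens.

## ML protocol

The fitness-prediction scaffolding is deliberately the experiment-design
part of the modeling, not the feature science: real structure-derived and
protein-language-model features are out of scope and replaced by a seeded
synthetic feature table with a planted monotone signal (labelled synthetic
in its docstring).

- **Features.** One always-present evolutionary-likelihood feature
  (positively monotone) plus 13 optional interpretable features; the
  stability-difference feature is negatively monotone. The 12 optional
  features other than the stability difference are binned to 4–5
  quantile-edged bins, each value replaced by its bin median (the two
  monotone-constrained features stay continuous — they are the "12
  remaining" of 14). Out-of-range values at transform time clamp to the
  nearest bin with a warning. Which feature carries the negative
  constraint is configurable, since the role assignment is a modeling
  choice.
- **Splits.** Test rows are whole blocks: two named inhibitors (one type
  I, one type II by default), floor(20% of positions), and 2 amino-acid
  identities; a row is in test iff any of its blocks is held out, so no
  (position, amino acid, inhibitor) leaks. On the 287-position,
  20-amino-acid, 11-inhibitor scale this leaves 230 training positions and
  18 amino acids. Vehicle and the lone type I½ inhibitor are excluded from
  ML data entirely (one dataset each would be memorized). CV uses the same
  blocking: positions partitioned into k near-equal disjoint parts (23 per
  part at k = 10) and an amino-acid block of 2 drawn per fold, uniformly
  without replacement within a fold and with re-use across folds (the
  protocol needs k × 2 > 18 draws; the re-sampling scheme within that
  constraint is a documented choice).
- **Models.** All 2^13 = 8192 feature subsets can be enumerated (a sampled
  subset plus the full model is the desk-scale default in the CLI). The
  regressor is a contract: it must accept per-feature monotone constraints
  and the nine tuned knobs (booster type, tree depth, tree count, learning
  rate, minimum split loss, column subsample, two regularization
  strengths, growth policy). xgboost is the shipped backend; sklearn's
  histogram gradient booster is accepted where its parameter surface
  overlaps. Hyperparameters are searched by seeded random draws from the
  stated space — the first trial is always the default configuration — on
  an internal 80/20 split of the training rows minimizing MSE; each
  feature set is then scored by blocked-CV mean Pearson r and MSE, sets
  ranked by CV correlation, the winner refit on the full training set and
  reported per-inhibitor on the held-out rows.

## Numerical and scale choices

- OLS slopes are computed in closed form (centered cross-products), which
  is exact for the 4-point trajectories involved.
- Zero replicate spread gives SE 0 and a degenerate test (p ∈ {0, ½, 1});
  infinite/missing SE yields an "unclassified" label rather than a call.
- Test and acceptance runs use the full 287-position library at depth 10⁶
  with 3 replicates for recovery checks, and a vehicle + two-inhibitor
  condition subset (one carrying 20 planted resistance mutations at
  β = 1.5, one clean null for the false-positive check); these problem
  sizes are the package's validation scale and run in seconds.
- Random streams everywhere derive from a single master seed through
  `numpy` `SeedSequence` spawn keys, so replicates, conditions and
  timepoints have distinct, stable streams and all results are
  reproducible bit-for-bit under a fixed seed.

## Known limitations

- The scorer is the frequentist skeleton of the published Bayesian
  framework; at very low counts its SE estimates are noisy (3 replicates
  give 2 degrees of freedom) and the normal tail is approximate. Deeply
  null true effects make the realized false-positive rate conservative in
  practice.
- Whether the zero-fraction filter should pool conditions is ambiguous in
  general; it is applied per condition here (T0 is shared, so the T0 rule
  is condition-independent either way).
- The library total (5767) reflects the package's stop-placement
  convention; real libraries differ in fill-in stops and failed-synthesis
  positions, and the simulator does not force any particular published
  total.
- Correlation structure between inhibitors in the generator comes only
  from the shared vehicle fitness; chemically similar inhibitors in real
  screens correlate through shared binding modes the generator does not
  model.
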