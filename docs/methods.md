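# Methods

## Decision model

A model is a finite option set `D`, a vectorised utility `f_d(θ)` per option,
and a distribution spec per input parameter.  Marginal families are normal,
log-normal, logit-normal, beta and constant; the log-normal and logit-normal
are parameterised by the mean and variance of the *underlying* normal (no
moment-matched alternative is offered — the underlying-normal space is also
the space in which thresholds are iterated and reported).  Pairs of
parameters may be correlated through an underlying bivariate normal block;
the block members' marginal parameters must equal the block's marginals, and
a parameter may belong to at most one block.  General s-dimensional copulas
and Markov cohort engines are out of scope, though the utility contract
(option, n×s matrix → n utilities) admits arbitrary user models.

Conditional sampling given a fixed component `θj` draws a correlated partner
from the exact conditional univariate normal of the underlying bivariate
normal and everything else from its prior.  Exactness here matters: the
pairwise regression functions whose roots are sought are conditional
expectations, and an approximate conditional would shift every
correlation-mediated crossing.

### The built-in three-treatment model

The shipped test bed compares a cost-free standard of care `d1` (no side
effects, relatively high probability of a critical event) against two costly
treatments `d2`, `d3` that lower the event odds but may cause side effects.
Twelve random inputs: remaining lifetime `L ~ N(30, 25)`; QALY weight after
the event `Q_E ~ logit-N(0.6, 1/36)`; QALY decrement from side effects
`Q_SE ~ N(0.7, 0.01)`; event and side-effect costs
`C_E ~ N(2e5, 1e8)`, `C_SE ~ N(1e5, 1e8)`; treatment costs
`(C_T,d2, C_T,d3)` bivariate normal with means `(1.5e4, 2e4)` and covariance
`[[300, 100], [100, 500]]`; baseline event probability
`P_E,d1 ~ Beta(15, 85)`; event odds ratios `(OR_E,d2, OR_E,d3)` bivariate
log-normal (underlying means `(−1.5, −1.75)`, covariance
`[[0.11, 0.02], [0.02, 0.06]]`); side-effect probabilities
`(P_SE,d2, P_SE,d3)` bivariate logit-normal (underlying means
`(−1.4, −1.1)`, covariance `[[0.10, 0.05], [0.05, 0.25]]`).  Constants:
`C_T,d1 = 0`, `P_SE,d1 = 0`, willingness-to-pay `λ = 75 000` per QALY.  The
treatment-cost covariance is implemented verbatim even though it implies
standard deviations of only ~17 and ~22 on means of 15 000 and 20 000; that
tightness is what pushes the cost thresholds hundreds of marginal standard
deviations into the tails and makes the model a sharp stress test.

The net benefit weighs the four outcome combinations (side effect × critical
event) by their joint probabilities, converts QALYs to money at `λ`, and
subtracts the treatment cost.  Event probabilities for `d2`/`d3` derive from
the baseline probability and the option's odds ratio.  The function is
multilinear in `L`, `Q_E`, `Q_SE`, `C_E`, `C_SE` and `C_T,d`; these form the
plug-in registry, and requesting plug-in replaces them by exact means (the
logit-normal mean of `Q_E` has no closed form and is computed once by
adaptive quadrature; a plug-in-eligible partner of the conditioned variable
is replaced by its exact *conditional* mean).  The event-probability
variables enter nonlinearly and are always sampled.

What the synthetic model does not emulate about real cost-effectiveness
analyses: structural model uncertainty, time discounting and cohort
dynamics, non-Gaussian dependence beyond pairwise normal-copula blocks, and
estimation error in the distribution parameters themselves.  Passing tests
therefore demonstrate correctness of the estimators under a fully specified
stochastic model, not robustness to misspecified inputs.

## Pairwise stochastic approximation

For options `d1 ≠ d2` the engine iterates, in the variable's transformed
space (log / logit / identity),

    x_{t+1} = x_t − sign · α_t · ĝ(x_t),   ĝ = M-sample conditional MC
    α_t = multiplier · 3 σ_j / (2·10⁴) · t^(−γ),   γ = 1/2 by default

with `σ_j` the transformed-space marginal standard deviation, `M = 1`,
`T = 10⁴` iterations, the initial point drawn from the marginal, and the
Polyak–Ruppert running mean reported as the estimate.  `γ = 1/2` violates
the classical square-summability condition on the steps; it is admissible
under iterate averaging, and a warning is emitted if averaging is disabled
with `γ ≤ 1/2`.  Iterating in transformed space keeps log/logit-family
supports respected automatically; mapping back for sampling clips the
exponent at ±700 so that far-out excursions produce huge finite utilities
rather than overflow.  A chain whose iterate becomes non-finite anyway (or
exceeds 10¹² in magnitude) is frozen at its last finite value and flagged.
`ĝ = 0` leaves the iterate unchanged; no tie-breaking is needed.

The step multiplier (default 1) exists because crossings far from the
initialisation region need proportionally larger steps to settle within the
iteration budget; the far-out treatment-cost threshold of the built-in model
is found with multiplier ≈ 10.  Since the multiplier choice is
configuration-sensitive, that threshold is checked only at order-of-magnitude
level in the tests.

### Recursion direction

The recursion sign (whether the pairwise difference rises or falls through
its root) is probed by pilot estimates at two marginal quantiles (defaults
0.01/0.99, 1000 samples each).  Confident opposite signs give ±1; confident
equal signs report "no crossing", which callers treat as advisory — the
crossing may simply lie outside the probed range, so campaigns still run and
divergence detection arbitrates.  Ambiguous probes fall back to the sign of
the probe difference.  Limitation: when the marginal spread of the variable
is tiny relative to the scale on which the difference varies (the built-in
treatment costs: a ±2.3σ probe window spans ~100 monetary units), the slope
signal drowns in pilot noise and the sign must be supplied from model
structure.

### Empty-set detection

A pairwise crossing set may be empty, in which case the chains drift without
settling.  From `R ≥ 2` independent runs the campaign is judged empty when
any of:

1. a run overflowed;
2. the across-run standard error of the averaged iterate fails to shrink by
   a factor 1.5 between `t = T/10` and `t = T` (a genuine root contracts it
   roughly like `t^(−1/2)`) — unless the run finals form at least two tight,
   well-separated clusters (separation > 10× within-cluster spread, each
   with ≥ 2 runs), the signature of a multi-root set reached from different
   initialisations rather than of divergence;
3. the across-run mean moves monotonically away from the marginal mean,
   ends beyond 8 marginal standard deviations, *and* is still moving at the
   end (final checkpoint step > 3 across-run SEs).  Distance alone is not
   disqualifying because genuine thresholds of this problem class routinely
   sit 10–400σ out in the tails; the settledness clause separates a
   converged far-out root from an unbounded drift.  The guard width is
   configurable and must be widened for deliberate far-root searches.

The shrink factor (1.5), guard (8σ) and settledness multiplier (3) are
artifact choices formalising a qualitative judgement; they were fixed by the
behaviour of the drift-vs-far-root toy cases, not tuned to any reference
number.

### Clustering of run finals

Run finals are clustered by recursive largest-gap splitting: a gap splits
two clusters only if it exceeds `max(5 × pooled within-side SD, 0.05 σ_j)`.
Heavy-tailed unimodal campaigns (slowly contracting chains) thus stay in one
cluster, while genuinely multi-root campaigns split cleanly.  Each cluster
becomes one root estimate: mean, across-run SE and the member finals.

## Membership screening and set assembly

With `|D| ≥ 3`, a pairwise root `θ̂` of `(d1, d2)` belongs to the full
threshold set only if no third option dominates there.  The null — for every
competitor `d`, `E[f_d − f_d1 | θ̂] ≤ 0` and `E[f_d − f_d2 | θ̂] ≤ 0` — is
tested with one-sided one-sample t-tests (Wilcoxon signed-rank available) on
`N = 10⁴` common conditional samples; a candidate is retained iff every
p-value stays at or above the significance level.  The level defaults to
0.05; on clear-cut cases the p-values saturate at 0 or 1 so the exact level
(and any multiplicity correction) is immaterial, and no correction is
applied.  Each of the `R` runs' candidates is tested separately, and the
*maximum* p-value per (competitor, side) over runs is the aggregate —
robust against a single unlucky run in either direction.  With two options
the screening step is vacuous and candidates are retained outright.

Retained elements are sorted and the open intervals between them labelled
with the dominant option at a representative point — interval midpoints, and
3σ_j beyond the extreme elements for the unbounded tails (how to place
representative points is genuinely open; midpoints are a conservative
choice).  Dominance is decided on `N = 10⁴` common samples with a 2-SE
margin; near-ties are labelled by the larger mean and flagged.  If two
adjacent intervals receive the same label, the separating element is
spurious and dropped with a warning, and the labelling repeats.  An empty
retained set yields one unbounded interval labelled with its dominant
option, which then coincides with the prior optimum.

## Sensitivity measures

**Prior optimum and EVPI.**  `d_opt(∅)` comes from common-random-number
Monte Carlo means (a warning fires if the top two options overlap within
3 SE).  EVPI uses the paired summand `max_d f_d(θ) − f_{d*}(θ)` on common
samples; the estimand equals the unpaired definition
`E[max_d f_d] − max_d E[f_d]`, but the pairing cancels the dominant shared
variation across options — utilities here have standard deviations of order
10⁵ while the EVPI is of order 10³, so pairing is what makes 2^18 samples
sufficient.

**EVPPI.**  Standard nested Monte Carlo: 2^18 outer marginal draws of `θj`,
2^10 inner conditional draws each (partner conditioned exactly, plug-in
means substituted for the linear variables), summand
`max_d m_d(θj) − m_{d*}(θj)` with `m_d` the inner means.  The finite inner
sample makes the estimator upward-biased wherever options nearly tie; the
bias decays with the inner sample size and is documented, not corrected (no
multilevel or regression correction is attempted).  Outer sampling is
chunked (256 outer draws × 1024 inner = ~2.6e5 model rows per chunk) to keep
memory flat.

**DSP.**  With the interval labels in hand,
`P_j = Σ P[θj ∈ interval with label ≠ d_opt(∅)]`, computed from closed-form
CDFs in the transformed space — normal for log/logit families (where the
transformed marginal is exactly normal), beta for beta marginals.  No
resampling is involved, so DSP costs microseconds given a threshold set, and
monotone-transform invariance holds to full precision.

**Reference curves.**  `E[f_d | θj]` on a grid, with the conditional sample
stream replayed at every grid point (common random numbers) and optional
plug-in means; used for visual checks and as an independent root oracle in
the tests (sign-change bracketing plus linear interpolation).

## Nested Monte Carlo baseline

The double-loop comparison estimator draws `N` outer marginal samples,
estimates each option's conditional mean from `M` inner samples, sorts the
outer samples, and reports a threshold at the midpoint of every consecutive
pair whose estimated optimum differs.  Cost is exactly `|D|·M·N` utility
evaluations.  Inner argmax ties break by option order with a logged warning;
near crossings this fabricates occasional spurious switches — a known
pathology of the estimator that is preserved deliberately.  Its structural
blindness to thresholds outside the sampled marginal range is what the
stochastic-approximation search is designed to fix.

## Reproducibility and problem sizes

All campaign randomness derives from one master seed through labelled
substreams (CRC-hashed coordinate labels fed to a seed sequence), so any
single run can be reproduced in isolation and whole campaigns are
bit-identical.  The test suite runs the full reference protocol (20 runs ×
10⁴ iterations) for the campaign-level checks, and scales down where the
check is qualitative: empty-set detection repetitions use 6 runs × 2000
iterations, the nested EVPPI check 2^14 outer samples (with tolerances
widened to match the larger outer noise), and the baseline comparison 5
repetitions at M = 10⁴, N = 10².  The acceptance script always runs the
full-scale protocol.

## Known limitations

* Thresholds are univariate; joint thresholds for parameter groups are not
  attempted.
* No variance reduction (Latin hypercube / quasi-Monte Carlo) in the
  stochastic-approximation estimator, although any unbiased conditional
  estimator could be substituted.
* The pilot sign probe is unreliable for variables whose marginal spread is
  tiny relative to the utility-difference scale; supply the sign explicitly
  for such variables.
* The EVPPI inner bias is reported, not corrected.
* Step-size multipliers for far-out roots are a manual knob; there is no
  automatic step adaptation.
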