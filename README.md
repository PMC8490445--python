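# threshsa

Probabilistic parameter threshold analysis for decision-making under
uncertainty, by pairwise stochastic approximation.

## The problem

Health-economic evaluations compare a finite set of options
`D = {d1, d2, ...}` (e.g. alternative treatments) through uncertain utilities
`f_d(θ)` — typically the monetary net benefit as a function of a random
parameter vector `θ = (θ1, ..., θs)` of costs, event probabilities and QALY
weights.  The option maximising the *expected* utility,
`d_opt(∅) = argmax_d E[f_d(θ)]`, is the rational prior choice, but learning a
single parameter `θj` exactly can flip the conditionally optimal option
`d_opt(θj) = argmax_d E[f_d | θj]`.

The **probabilistic parameter threshold** `K_j` is the set of values of `θj`
at which `d_opt(θj)` is not unique — the crossing points of the conditional
expected-utility curves.  For each option pair the crossings are the roots of

    g(θj) = E[(f_d1 − f_d2)(θ) | θj] ,

and `K_j` is contained in the union of these pairwise root sets.  This
package estimates each root with the Robbins–Monro recursion

    θj^{t+1} = θj^t − α_t · ĝ(θj^t) ,     α_t = 3 σ(θj) / (2·10⁴ √t) ,

where `ĝ` is an unbiased M-sample conditional Monte Carlo estimate (`M = 1`
suffices), and reports the Polyak–Ruppert average `Θj^t = (1/t) Σ_u θj^u`.
Unlike the nested (double-loop) Monte Carlo search, which only sees the range
covered by marginal samples of `θj`, the recursion walks to crossings that
lie many standard deviations into the tails, at total cost `O(|D|² ε⁻²)` for
accuracy `ε`.  With three or more options, each estimated pairwise root is
screened by one-sided t-tests (or Wilcoxon signed-rank tests) against every
remaining option before it is accepted into `K_j`.

On top of the threshold sets the package computes decision-theoretic
sensitivity measures:

* **DSP** — the decision switching probability
  `P_j = P[d_opt(θj) ≠ d_opt(∅)]`, obtained in closed form from the marginal
  CDF of `θj` and the interval labels of `K_j`;
* **EVPI / EVPPI** — the expected value of (partial) perfect information,
  via paired Monte Carlo and nested Monte Carlo with plug-in means.

A fully specified synthetic three-treatment cost-effectiveness model (twelve
random inputs with log-normal / logit-normal / beta marginals and three
correlated pairs, willingness-to-pay 75 000 per QALY) ships as the built-in
test bed; user models plug in through a small config format plus a vectorised
utility callable.

## Worked example

```python
import numpy as np
from threshsa import (
    three_treatment_model, find_thresholds, prior_optimal, evpi,
    decision_switching_probability,
)

model = three_treatment_model()
prior = prior_optimal(model, 2**16, np.random.default_rng(7))
print(f"prior optimal option: {prior.option}")

total = evpi(model, 2**18, np.random.default_rng(7))
print(f"EVPI: {total.value:.1f} +/- {total.se:.1f}")

j = model.index("P_SE_d3")  # side-effect probability of treatment d3
analysis = find_thresholds(model, j, R=20, rng=np.random.default_rng(7))
tset = analysis.threshold_set
print(f"thresholds (logit space): {[round(e, 3) for e in tset.elements]}")
print(f"optimal option per interval: {' | '.join(tset.labels)}")
dsp = decision_switching_probability(model, j, tset, prior.option)
print(f"decision switching probability: {dsp:.3f}")
```

prints

```
prior optimal option: d2
EVPI: 4051.0 +/- 14.1
thresholds (logit space): [-1.414, 2.376]
optimal option per interval: d3 | d2 | d1
decision switching probability: 0.265
```

Read: without further information, treatment `d2` is optimal.  If the
side-effect probability of `d3` were known exactly, the optimum would switch
to `d3` below logit⁻¹(−1.414) ≈ 0.20 and to `d1` above logit⁻¹(2.376) ≈ 0.91;
under the current uncertainty that switch happens with probability 0.265, so
this parameter matters a great deal — consistent with its EVPPI being a large
fraction of the total EVPI of ~4050 monetary units.

The same campaigns are available from the shell:

```bash
threshsa thresholds --variable P_SE_d3 --runs 20 --iters 10000 --seed 7 --out out/
threshsa sensitivity --variables P_SE_d3 --outer 262144 --inner 1024 --seed 7
threshsa nested-baseline --variable P_SE_d3 --inner 10000 --outer 100 --seed 7
threshsa export-model --out model.yaml
```

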