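"""Nested (double-loop) Monte Carlo threshold search — the comparison baseline.

The outer loop draws ``N`` marginal samples of the examined variable; for each
outer sample an inner loop of ``M`` conditional samples estimates every
option's conditional expected utility.  A threshold is reported at the
midpoint between consecutive *sorted* outer samples whose estimated optimal
option differs.  The estimator spends ``|D| * M * N`` utility evaluations per
variable and can only find thresholds inside the range actually covered by
the outer marginal samples — the structural weakness the
stochastic-approximation search removes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import DecisionModel, sample_conditional

__all__ = ["NestedMCResult", "nested_mc_thresholds"]

log = logging.getLogger(__name__)


@dataclass
class NestedMCResult:
    variable: int
    outer_sorted: np.ndarray  # transformed space, ascending
    optimal_options: list[str]  # estimated optimum per outer sample
    switch_midpoints: np.ndarray  # transformed space
    M: int
    N: int
    n_options: int
    tie_warnings: int = 0

    @property
    def n_evaluations(self) -> int:
        """Total utility evaluations spent: |D| * M * N."""
        return self.n_options * self.M * self.N

    def summary(self) -> dict:
        return {
            "variable": self.variable,
            "M": self.M,
            "N": self.N,
            "switch_midpoints": [float(v) for v in self.switch_midpoints],
            "tie_warnings": self.tie_warnings,
        }


def nested_mc_thresholds(
    model: DecisionModel,
    j: int,
    M: int,
    N: int,
    rng: np.random.Generator | None = None,
    outer_chunk: int = 64,
) -> NestedMCResult:
    """Double-loop threshold estimate for variable ``j`` with ``M`` inner and
    ``N`` outer samples; midpoints are reported in the transformed space.

    Inner argmax ties are broken by option order (with a logged warning) —
    near-crossing noise can therefore fabricate spurious extra switches, a
    known pathology of the estimator that is preserved, not patched.
    """
    if M < 1 or N < 1:
        raise ValueError("M and N must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    spec = model.spec(j)
    outer = np.sort(spec.to_transformed(spec.sample(rng, N)))
    n_opts = len(model.options)
    best = np.empty(N, dtype=int)
    ties = 0
    for start in range(0, N, outer_chunk):
        chunk = outer[start : start + outer_chunk]
        k = len(chunk)
        nat = spec.to_natural(np.repeat(chunk, M))
        smp = sample_conditional(model, j, nat, k * M, rng)
        means = np.column_stack(
            [model.evaluate(d, smp).reshape(k, M).mean(axis=1) for d in model.options]
        )
        top = means.max(axis=1, keepdims=True)
        tied = (means == top).sum(axis=1) > 1
        ties += int(tied.sum())
        best[start : start + k] = means.argmax(axis=1)
    if ties:
        log.warning("%d inner argmax ties broken by option order", ties)
    switches = np.nonzero(np.diff(best) != 0)[0]
    midpoints = (outer[switches] + outer[switches + 1]) / 2.0
    return NestedMCResult(
        variable=j,
        outer_sorted=outer,
        optimal_options=[model.options[b] for b in best],
        switch_midpoints=midpoints,
        M=M,
        N=N,
        n_options=n_opts,
        tie_warnings=ties,
    )
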