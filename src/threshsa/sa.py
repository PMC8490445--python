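"""Robbins-Monro root finding for pairwise conditional utility differences.

For a variable ``theta_j`` and two options ``d1 != d2`` the regression function

    g(theta_j) = E[ f_d1(theta) - f_d2(theta) | theta_j ]

changes sign exactly at the pairwise threshold values where the two options'
conditional expected utilities cross.  The engine iterates

    x_{t+1} = x_t - sign * alpha_t * ghat(x_t),      alpha_t = a * t^{-gamma}

in the variable's transformed space (log / logit / identity), where ``ghat``
is an unbiased M-sample Monte Carlo estimate of ``g``, and reports the
Polyak-Ruppert average of the iterates.  With the default ``gamma = 1/2`` the
square-summability condition on the steps is violated, which is admissible
only in combination with iterate averaging (Ruppert-Juditsky); a warning is
emitted if averaging is switched off.

If the pairwise threshold set is empty the iterates drift without settling;
:func:`detect_divergence` formalises that judgement from a bundle of
independent runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import DecisionModel, sample_conditional

__all__ = [
    "StepSchedule",
    "SAConfig",
    "SATrace",
    "SignProbe",
    "default_schedule",
    "pairwise_diff_estimate",
    "robbins_monro_step",
    "determine_sign",
    "run_sa",
    "run_sa_batch",
    "detect_divergence",
]

# transformed-space iterates beyond this absolute size count as numerical
# overflow (natural-space magnitudes are already astronomical long before)
_OVERFLOW_BOUND = 1.0e12


@dataclass(frozen=True)
class StepSchedule:
    """Step-size rule ``alpha_t = scale * t**(-gamma)``."""

    scale: float
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("step scale must be positive")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must lie in (0, 1]")

    def alpha(self, t) -> np.ndarray:
        return self.scale * np.asarray(t, dtype=float) ** (-self.gamma)

    @property
    def robbins_monro_valid(self) -> bool:
        """True iff sum(alpha_t) = inf and sum(alpha_t^2) < inf."""
        return 0.5 < self.gamma <= 1


def default_schedule(sigma: float, multiplier: float = 1.0) -> StepSchedule:
    """``alpha_t = 3 sigma / (2e4 sqrt(t))`` scaled by an optional multiplier.

    ``sigma`` is the transformed-space marginal standard deviation of the
    iterated variable.  The multiplier supports far-from-init roots where the
    base schedule moves too slowly to settle within the iteration budget.
    """
    return StepSchedule(scale=multiplier * 3.0 * sigma / 2.0e4, gamma=0.5)


@dataclass
class SAConfig:
    """Settings of one stochastic-approximation campaign."""

    T: int = 10_000
    M: int = 1
    schedule: StepSchedule | None = None  # None -> default_schedule(sigma_j)
    sign: int | str = "auto"  # +1 | -1 | "auto"
    averaging: bool = True
    init: float | None = None  # transformed space; None -> marginal draw
    step_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 1 or self.M < 1:
            raise ValueError("T and M must be >= 1")
        if self.sign not in (1, -1, "auto"):
            raise ValueError("sign must be +1, -1 or 'auto'")

    def resolve_schedule(self, sigma: float) -> StepSchedule:
        sched = self.schedule or default_schedule(sigma, self.step_multiplier)
        if not sched.robbins_monro_valid and not self.averaging:
            warnings.warn(
                "step exponent <= 1/2 violates the Robbins-Monro summability "
                "condition; acceptable only with Polyak-Ruppert averaging",
                stacklevel=2,
            )
        return sched


@dataclass
class SATrace:
    """One run: raw iterates, Polyak-Ruppert averages and diagnostics."""

    raw: np.ndarray
    averaged: np.ndarray
    final: float
    diverged: bool  # numerical overflow of the iterates
    center: float  # transformed marginal mean of theta_j
    sigma: float  # transformed marginal sd of theta_j
    seed: object = None

    def to_frame(self):
        import pandas as pd

        t = np.arange(1, len(self.raw) + 1)
        return pd.DataFrame({"t": t, "raw": self.raw, "averaged": self.averaged})

    def summary(self) -> dict:
        return {
            "final": self.final,
            "diverged": bool(self.diverged),
            "T": int(len(self.raw)),
            "seed": str(self.seed),
        }


def pairwise_diff_estimate(
    model: DecisionModel,
    j: int,
    d1: str,
    d2: str,
    theta_j: float,
    M: int,
    rng: np.random.Generator,
) -> float:
    """Unbiased M-sample estimate of ``E[f_d1 - f_d2 | theta_j]``.

    ``theta_j`` is given in the variable's transformed space.
    """
    if d1 == d2:
        raise ValueError("the two options of a pair must differ")
    spec = model.spec(j)
    nat = spec.to_natural(theta_j)
    smp = sample_conditional(model, j, nat, M, rng)
    return float(np.mean(model.evaluate(d1, smp) - model.evaluate(d2, smp)))


def robbins_monro_step(theta_t: float, alpha_t: float, g_hat: float, sign: int) -> float:
    """One recursion step ``theta - sign * alpha * ghat`` (sign=-1 flips it)."""
    if alpha_t <= 0:
        raise ValueError("alpha_t must be positive")
    return theta_t - sign * alpha_t * g_hat


@dataclass(frozen=True)
class SignProbe:
    """Pilot estimates of the regression function at two marginal quantiles."""

    result: int | str  # +1 | -1 | "no-crossing"
    g_low: float
    g_high: float
    se_low: float
    se_high: float

    @property
    def slope_sign(self) -> int:
        return 1 if self.g_high >= self.g_low else -1

    @property
    def resolved(self) -> int:
        """A usable recursion sign even when no crossing was detected."""
        return self.result if self.result in (1, -1) else self.slope_sign


def determine_sign(
    model: DecisionModel,
    j: int,
    d1: str,
    d2: str,
    probe_quantiles: tuple[float, float] = (0.01, 0.99),
    M_pilot: int = 1000,
    rng: np.random.Generator | None = None,
) -> SignProbe:
    """Estimate the direction of the pairwise regression function.

    Probes ``E[f_d1 - f_d2 | theta_j]`` at two marginal quantiles.  Returns +1
    when the function confidently rises through zero (standard recursion), -1
    when it falls, and ``"no-crossing"`` when both probes share a confident
    sign; in the remaining ambiguous cases the probe-difference slope decides.
    A confident shared sign does not prove emptiness when the crossing lies
    outside the probed quantile range, so callers should still let divergence
    detection arbitrate.
    """
    lo_q, hi_q = probe_quantiles
    if not 0 < lo_q < hi_q < 1:
        raise ValueError("probe quantiles must be strictly ordered in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    spec = model.spec(j)
    dist = spec.transformed_dist()
    stats_ = []
    for q in (lo_q, hi_q):
        x = float(dist.ppf(q))
        nat = spec.to_natural(x)
        smp = sample_conditional(model, j, nat, M_pilot, rng)
        diff = model.evaluate(d1, smp) - model.evaluate(d2, smp)
        stats_.append((float(diff.mean()), float(diff.std(ddof=1) / np.sqrt(M_pilot))))
    (g_lo, se_lo), (g_hi, se_hi) = stats_
    k = 3.0
    lo_neg, lo_pos = g_lo < -k * se_lo, g_lo > k * se_lo
    hi_neg, hi_pos = g_hi < -k * se_hi, g_hi > k * se_hi
    if lo_neg and hi_pos:
        result: int | str = 1
    elif lo_pos and hi_neg:
        result = -1
    elif (lo_neg and hi_neg) or (lo_pos and hi_pos):
        result = "no-crossing"
    else:
        result = 1 if g_hi >= g_lo else -1
    return SignProbe(result, g_lo, g_hi, se_lo, se_hi)


def run_sa_batch(
    model: DecisionModel,
    j: int,
    d1: str,
    d2: str,
    config: SAConfig,
    rng: np.random.Generator,
    R: int = 1,
) -> list[SATrace]:
    """Run ``R`` independent SA chains in lockstep (shared iteration clock).

    Vectorising across runs keeps a 20-run campaign at the cost of a single
    run's Python loop.  Chains that overflow are frozen at their last finite
    iterate and flagged.
    """
    if d1 == d2:
        raise ValueError("the two options of a pair must differ")
    if config.sign not in (1, -1):
        probe = determine_sign(model, j, d1, d2, rng=rng)
        sign = probe.resolved
    else:
        sign = config.sign
    spec = model.spec(j)
    sigma = spec.transformed_sd()
    if sigma == 0:
        raise ValueError(f"{spec.name!r} is degenerate; nothing to iterate")
    sched = config.resolve_schedule(sigma)
    T, M = config.T, config.M

    if config.init is not None:
        x = np.full(R, float(config.init))
    else:
        x = np.asarray(spec.to_transformed(spec.sample(rng, R)), dtype=float)

    alphas = sched.alpha(np.arange(1, T + 1))
    raw = np.empty((T, R))
    active = np.ones(R, dtype=bool)
    diverged = np.zeros(R, dtype=bool)
    for t in range(T):
        raw[t] = x
        nat = spec.to_natural(x)
        smp = sample_conditional(model, j, np.repeat(nat, M), R * M, rng)
        with np.errstate(over="ignore", invalid="ignore"):
            diff = model.evaluate(d1, smp) - model.evaluate(d2, smp)
            g = diff.reshape(R, M).mean(axis=1)
            x_new = x - sign * alphas[t] * g
        bad = ~np.isfinite(x_new) | (np.abs(x_new) > _OVERFLOW_BOUND)
        diverged |= bad & active
        active &= ~bad
        x = np.where(active, x_new, x)

    averaged = np.cumsum(raw, axis=0) / np.arange(1, T + 1)[:, None]
    traces = []
    for r in range(R):
        final = averaged[-1, r] if config.averaging else raw[-1, r]
        traces.append(
            SATrace(
                raw=raw[:, r].copy(),
                averaged=averaged[:, r].copy(),
                final=float(final),
                diverged=bool(diverged[r]),
                center=spec.transformed_mean(),
                sigma=sigma,
            )
        )
    return traces


def run_sa(
    model: DecisionModel,
    j: int,
    d1: str,
    d2: str,
    config: SAConfig,
    rng: np.random.Generator,
) -> SATrace:
    """One stochastic-approximation run; see :func:`run_sa_batch`."""
    return run_sa_batch(model, j, d1, d2, config, rng, R=1)[0]


def gap_cluster_indices(values: np.ndarray, tol: float) -> list[np.ndarray]:
    """Single-linkage clustering: sort and split at gaps larger than ``tol``.

    Returns index arrays into ``values``, ordered by cluster location.
    """
    order = np.argsort(values)
    v = values[order]
    groups, start = [], 0
    for i in range(1, len(v)):
        if v[i] - v[i - 1] > tol:
            groups.append(order[start:i])
            start = i
    groups.append(order[start:])
    return groups


def _final_clusters(finals: np.ndarray, sigma: float) -> list[np.ndarray]:
    """Cluster run finals by recursive largest-gap splitting.

    A gap is a genuine cluster boundary only when it clearly exceeds the
    run-to-run scatter on both sides: the split requires
    ``gap > max(5 x pooled within-side sd, 0.05 sigma)``.  Heavy-tailed but
    unimodal campaigns therefore stay in one cluster, while well-separated
    multi-root campaigns split cleanly.
    """
    order = np.argsort(finals)

    def pooled_sd(sides: list[np.ndarray]) -> float:
        parts = [s for s in sides if len(s) >= 2]
        if not parts:
            return 0.0
        dev = np.concatenate([s - s.mean() for s in parts])
        dof = sum(len(s) - 1 for s in parts)
        return float(np.sqrt(np.sum(dev**2) / dof))

    def split(idx: np.ndarray) -> list[np.ndarray]:
        if len(idx) < 2:
            return [idx]
        v = finals[idx]
        gaps = np.diff(v)
        k = int(np.argmax(gaps))
        left, right = idx[: k + 1], idx[k + 1 :]
        threshold = max(5.0 * pooled_sd([finals[left], finals[right]]), 0.05 * sigma)
        if gaps[k] > threshold:
            return split(left) + split(right)
        return [idx]

    return split(order)


def detect_divergence(
    traces: list[SATrace],
    shrink_factor: float = 1.5,
    guard: float = 8.0,
) -> bool:
    """Judge from ``R`` independent runs whether the pairwise set is empty.

    Empty is declared when any of:

    * a run overflowed numerically;
    * the across-run standard error of the averaged iterate fails to shrink
      by ``shrink_factor`` between ``t = T/10`` and ``t = T`` (for a genuine
      root it contracts roughly like ``t^{-1/2}``).  One rescue applies: runs
      split between several genuine roots also keep the pooled SE large, so
      a campaign whose finals form at least two tight, well-separated
      clusters (separation > 10x the within-cluster spread, each cluster
      holding >= 2 runs) is treated as multi-root, not divergent;
    * the across-run mean drifts monotonically beyond ``guard`` marginal
      standard deviations from the marginal mean *and* is still moving at the
      end of the run.  Genuine roots of this problem class routinely sit 10+
      standard deviations out in the tails, so distance alone is not used:
      a converged far-out root is settled, a drifting chain is not.
    """
    if len(traces) < 2:
        raise ValueError("divergence assessment needs at least two runs")
    T = len(traces[0].averaged)
    if any(len(tr.averaged) != T for tr in traces):
        raise ValueError("runs must share a common iteration count")
    if any(tr.diverged for tr in traces):
        return True

    A = np.stack([tr.averaged for tr in traces])  # (R, T)
    R = A.shape[0]
    t_early = max(T // 10, 1)
    center, sigma = traces[0].center, traces[0].sigma

    se = A.std(axis=0, ddof=1) / np.sqrt(R)
    se_early, se_late = se[t_early - 1], se[-1]
    shrunk = se_late == 0 or se_early / se_late >= shrink_factor
    if not shrunk:
        finals = A[:, -1]
        big = [c for c in _final_clusters(finals, sigma) if len(c) >= 2]
        if len(big) >= 2:
            centers = sorted(float(finals[c].mean()) for c in big)
            within = max(float(finals[c].std(ddof=1)) for c in big)
            sep = min(b - a for a, b in zip(centers, centers[1:]))
            if within == 0 or sep > 10.0 * within:
                shrunk = True  # reproducible multi-root split, not drift
    if not shrunk:
        return True

    checkpoints = np.unique(np.linspace(t_early, T, 10).astype(int)) - 1
    mean_path = A.mean(axis=0)[checkpoints]
    dist = np.abs(mean_path - center)
    monotone = np.all(np.diff(dist) > 0)
    beyond = dist[-1] > guard * sigma
    se_all = A.std(axis=0, ddof=1)[-1] / np.sqrt(R)
    step = abs(mean_path[-1] - mean_path[-2])
    still_moving = step > 3.0 * max(se_all, 1e-12 * max(sigma, 1.0))
    return bool(monotone and beyond and still_moving)
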