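"""Shared fixtures: the built-in model, analytic toy models and a grid oracle."""

from __future__ import annotations

import numpy as np
import pytest

from threshsa.model import (
    DecisionModel,
    MarginalSpec,
    sample_conditional,
    three_treatment_model,
)


@pytest.fixture(scope="session")
def builtin() -> DecisionModel:
    return three_treatment_model()


def make_linear_toy(a=0.3, noise=1.0, mu0=0.0, sd0=1.0) -> DecisionModel:
    """Two options whose utility difference is ``(x - a) + noise`` — the
    conditional regression function is exactly linear with root ``a``."""

    def util(model, d, th):
        x, e = th[:, 0], th[:, 1]
        if d == "A":
            return np.zeros(len(x))
        return -(x - a) - noise * e

    return DecisionModel(
        "linear_toy",
        ("A", "B"),
        (
            MarginalSpec.normal("x", mu0, sd0**2),
            MarginalSpec.normal("eps", 0.0, 1.0),
        ),
        util,
    )


def make_cubic_toy(noise=0.5) -> DecisionModel:
    """Pairwise difference ``clip((x+1)x(x-1), +-6) + noise``: three crossings,
    of which x = -1 and x = +1 attract the standard recursion while x = 0
    repels it — a two-root target for multi-start campaigns.  The clip bounds
    the drift far from the roots without adding or moving any crossing."""

    def util(model, d, th):
        x, e = th[:, 0], th[:, 1]
        if d == "A":
            return np.zeros(len(x))
        return -np.clip((x + 1.0) * x * (x - 1.0), -6.0, 6.0) - noise * e

    return DecisionModel(
        "cubic_toy",
        ("A", "B"),
        (
            MarginalSpec.normal("x", 0.0, 1.5**2),
            MarginalSpec.normal("eps", 0.0, 1.0),
        ),
        util,
    )


def make_three_option_toy(noise=0.5) -> DecisionModel:
    """Three options with linear conditional differences and analytic
    thresholds: f_A = 0, f_B = x - 1, f_C = 2(x - 2) in conditional mean, so
    the full threshold set is {1, 3} (A | B | C) while the pairwise (A, C)
    crossing at x = 2 lies strictly below the optimum and must be rejected."""

    def util(model, d, th):
        x, e1, e2 = th[:, 0], th[:, 1], th[:, 2]
        if d == "A":
            return np.zeros(len(x))
        if d == "B":
            return (x - 1.0) + noise * e1
        return 2.0 * (x - 2.0) + noise * e2

    return DecisionModel(
        "three_option_toy",
        ("A", "B", "C"),
        (
            MarginalSpec.normal("x", 2.0, 1.0),
            MarginalSpec.normal("e1", 0.0, 1.0),
            MarginalSpec.normal("e2", 0.0, 1.0),
        ),
        util,
    )


def make_drift_toy(c=5.0) -> DecisionModel:
    """Constant pairwise difference ``c`` (no root): iterates must drift."""

    def util(model, d, th):
        x = th[:, 0]
        if d == "A":
            return np.full(len(x), c)
        return np.zeros(len(x))

    return DecisionModel(
        "drift_toy",
        ("A", "B"),
        (
            MarginalSpec.normal("x", 0.0, 1.0),
            MarginalSpec.normal("eps", 0.0, 1.0),
        ),
        util,
    )


def grid_oracle_roots(
    model: DecisionModel,
    j: int,
    d1: str,
    d2: str,
    lo: float,
    hi: float,
    n_grid: int = 60,
    M: int = 20_000,
    seed: int = 0,
):
    """Brute-force root bracketing of ``E[f_d1 - f_d2 | theta_j]``.

    Estimates the pairwise difference on a transformed-space grid with common
    random numbers (the same conditional stream replayed at every point),
    brackets sign changes and interpolates linearly.  Returns a list of
    ``(root, se)`` with the root's standard error propagated from the local
    estimate noise and slope.  Independent of the stochastic-approximation
    path it is used to check.
    """
    spec = model.spec(j)
    grid = np.linspace(lo, hi, n_grid)
    g = np.empty(n_grid)
    se = np.empty(n_grid)
    for i, x in enumerate(grid):
        rng = np.random.default_rng(seed)  # replayed stream -> CRN
        smp = sample_conditional(model, j, spec.to_natural(float(x)), M, rng)
        diff = model.evaluate(d1, smp) - model.evaluate(d2, smp)
        g[i] = diff.mean()
        se[i] = diff.std(ddof=1) / np.sqrt(M)
    roots = []
    for i in range(n_grid - 1):
        if g[i] == 0.0:
            roots.append((float(grid[i]), float(se[i])))
        elif g[i] * g[i + 1] < 0:
            frac = g[i] / (g[i] - g[i + 1])
            root = grid[i] + frac * (grid[i + 1] - grid[i])
            slope = abs(g[i + 1] - g[i]) / (grid[i + 1] - grid[i])
            roots.append((float(root), float(max(se[i], se[i + 1]) / slope)))
    return roots
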