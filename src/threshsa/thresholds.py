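"""Assembly of parameter threshold sets from pairwise root-finding campaigns.

For a variable ``theta_j`` the threshold set ``K_j`` collects the values where
the conditionally optimal option is not unique.  With ``|D| >= 3`` it is
covered by the union of the pairwise crossing sets over all option pairs; the
pipeline here

1. runs ``R`` independent stochastic-approximation chains per pair,
2. declares a pair empty or clusters the per-run finals into root candidates,
3. tests each candidate's membership in ``K_j`` with one-sided tests against
   every remaining competitor option (skipped when ``|D| = 2``),
4. sorts the retained elements and labels the intervals between them with
   their optimal option.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import DecisionModel, sample_conditional
from .sa import (
    SAConfig,
    SATrace,
    _final_clusters,
    detect_divergence,
    run_sa_batch,
)

__all__ = [
    "PairwiseRootEstimate",
    "MembershipTest",
    "ThresholdSet",
    "ThresholdAnalysis",
    "estimate_pairwise_roots",
    "test_membership",
    "aggregate_membership",
    "assemble_threshold_set",
    "find_thresholds",
]

log = logging.getLogger(__name__)


@dataclass
class PairwiseRootEstimate:
    """Multi-run summary of one estimated element of a pairwise crossing set."""

    variable: int
    pair: tuple[str, str]
    finals: np.ndarray  # per-run final estimates in this cluster (transformed)
    empty: bool = False
    traces: list[SATrace] = field(default_factory=list, repr=False)

    @property
    def mean(self) -> float | None:
        return None if self.empty else float(np.mean(self.finals))

    @property
    def se(self) -> float | None:
        if self.empty:
            return None
        if len(self.finals) < 2:
            return 0.0
        return float(np.std(self.finals, ddof=1) / np.sqrt(len(self.finals)))

    def summary(self) -> dict:
        return {
            "pair": list(self.pair),
            "empty": self.empty,
            "mean": self.mean,
            "se": self.se,
            "n_runs": int(len(self.finals)),
            "finals": [float(v) for v in np.atleast_1d(self.finals)],
        }


@dataclass
class MembershipTest:
    """One-sided tests of a candidate root against every competitor option."""

    candidate: float
    pair: tuple[str, str]
    p_values: dict[tuple[str, str], float]  # (competitor, reference) -> p
    level: float
    family: str
    retained: bool

    def summary(self) -> dict:
        return {
            "candidate": self.candidate,
            "pair": list(self.pair),
            "p_values": {f"{c}|{r}": p for (c, r), p in self.p_values.items()},
            "level": self.level,
            "family": self.family,
            "retained": self.retained,
        }


@dataclass
class ThresholdSet:
    """Sorted retained elements of ``K_j`` with interval-wise optimal options."""

    variable: int
    elements: tuple[float, ...]  # transformed space, strictly increasing
    labels: tuple[str, ...]  # len(elements) + 1 interval labels
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.elements) + 1:
            raise ValueError("need one label per interval")
        if any(b <= a for a, b in zip(self.elements, self.elements[1:])):
            raise ValueError("elements must be strictly sorted")

    def intervals(self):
        edges = (-np.inf,) + tuple(self.elements) + (np.inf,)
        return [
            (edges[i], edges[i + 1], self.labels[i]) for i in range(len(self.labels))
        ]

    def summary(self) -> dict:
        return {
            "variable": self.variable,
            "elements": [float(e) for e in self.elements],
            "labels": list(self.labels),
            "warnings": list(self.warnings),
        }


def estimate_pairwise_roots(
    model: DecisionModel,
    j: int,
    d1: str,
    d2: str,
    config: SAConfig,
    R: int = 20,
    rng: np.random.Generator | None = None,
    shrink_factor: float = 1.5,
    guard: float = 8.0,
    keep_traces: bool = False,
) -> list[PairwiseRootEstimate]:
    """Run ``R`` marginally initialised SA chains for one pair and cluster them.

    Returns a single estimate flagged ``empty`` when the run bundle is judged
    divergent, otherwise one estimate per cluster of run finals (several
    clusters signal a multi-root pairwise set reached from different
    initialisations).  Cluster tolerance: ``max(5 x pooled SE, 0.05 sigma_j)``.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    traces = run_sa_batch(model, j, d1, d2, config, rng, R=R)
    kept = traces if keep_traces else []
    if detect_divergence(traces, shrink_factor=shrink_factor, guard=guard):
        log.info("pair (%s,%s) on variable %d judged empty", d1, d2, j)
        return [
            PairwiseRootEstimate(j, (d1, d2), np.array([]), empty=True, traces=kept)
        ]
    finals = np.array([tr.final for tr in traces])
    sigma = model.spec(j).transformed_sd()
    return [
        PairwiseRootEstimate(j, (d1, d2), finals[idx], traces=kept)
        for idx in _final_clusters(finals, sigma)
    ]


def test_membership(
    model: DecisionModel,
    j: int,
    candidate: float,
    d1: str,
    d2: str,
    N: int = 10_000,
    level: float = 0.05,
    family: str = "t",
    rng: np.random.Generator | None = None,
) -> MembershipTest:
    """Test whether a candidate pairwise root belongs to the full threshold set.

    ``candidate`` lives in the variable's transformed space.  The null — the
    candidate is a genuine element of ``K_j`` — requires every competitor
    ``d`` to satisfy ``E[f_d - f_d1 | theta_j] <= 0`` and likewise against
    ``d2``; each inequality gets a one-sided test (``t`` or Wilcoxon
    signed-rank) on ``N`` common conditional samples, and the candidate is
    retained iff no p-value falls below ``level``.  With two options there is
    no competitor and the candidate is retained trivially.
    """
    if N < 30:
        raise ValueError("N >= 30 required for the normality-based test")
    if family not in ("t", "wilcoxon"):
        raise ValueError("family must be 't' or 'wilcoxon'")
    competitors = [d for d in model.options if d not in (d1, d2)]
    if not competitors:
        return MembershipTest(candidate, (d1, d2), {}, level, family, retained=True)
    rng = np.random.default_rng() if rng is None else rng
    spec = model.spec(j)
    smp = sample_conditional(model, j, spec.to_natural(candidate), N, rng)
    f = {d: model.evaluate(d, smp) for d in set(competitors) | {d1, d2}}
    p_values: dict[tuple[str, str], float] = {}
    for d in competitors:
        for ref in (d1, d2):
            diff = f[d] - f[ref]
            if family == "t":
                p = stats.ttest_1samp(diff, 0.0, alternative="greater").pvalue
            else:
                p = stats.wilcoxon(diff, alternative="greater").pvalue
            p_values[(d, ref)] = float(p)
    retained = all(p >= level for p in p_values.values())
    return MembershipTest(candidate, (d1, d2), p_values, level, family, retained)


def aggregate_membership(
    model: DecisionModel,
    j: int,
    estimate: PairwiseRootEstimate,
    N: int = 10_000,
    level: float = 0.05,
    family: str = "t",
    rng: np.random.Generator | None = None,
) -> MembershipTest:
    """Membership decision for a clustered root: test every run's final
    estimate and keep, per (competitor, side), the *maximum* p-value.

    Maximising over runs makes the decision robust to a single unlucky run:
    a genuine element yields saturated p-values in every run, a spurious one
    small p-values in every run.
    """
    if estimate.empty:
        raise ValueError("cannot test membership of an empty pairwise set")
    rng = np.random.default_rng() if rng is None else rng
    d1, d2 = estimate.pair
    agg: dict[tuple[str, str], float] = {}
    for final in estimate.finals:
        mt = test_membership(model, j, float(final), d1, d2, N, level, family, rng)
        if not mt.p_values:
            return MembershipTest(
                float(estimate.mean), (d1, d2), {}, level, family, retained=True
            )
        for key, p in mt.p_values.items():
            agg[key] = max(agg.get(key, 0.0), p)
    retained = all(p >= level for p in agg.values())
    return MembershipTest(float(estimate.mean), (d1, d2), agg, level, family, retained)


def _dominant_option(
    model: DecisionModel,
    j: int,
    x: float,
    N: int,
    rng: np.random.Generator,
    margin: float = 2.0,
):
    """Optimal option at transformed value ``x`` by common-sample means.

    Returns ``(option, tie_flag)``; a tie is flagged when the runner-up is
    within ``margin`` standard errors of the leader.
    """
    spec = model.spec(j)
    smp = sample_conditional(model, j, spec.to_natural(x), N, rng)
    U = model.utilities(smp)
    means = U.mean(axis=0)
    order = np.argsort(means)[::-1]
    lead, second = order[0], order[1]
    gap = U[:, lead] - U[:, second]
    se = gap.std(ddof=1) / np.sqrt(N)
    return model.options[lead], bool(gap.mean() < margin * se)


def assemble_threshold_set(
    model: DecisionModel,
    j: int,
    retained: list[float],
    N: int = 10_000,
    rng: np.random.Generator | None = None,
    tail_sd: float = 3.0,
) -> ThresholdSet:
    """Sort retained candidates and label every interval with its optimum.

    Representative points are interval midpoints; the unbounded tails are
    probed ``tail_sd`` marginal standard deviations beyond the extreme
    elements.  A separator between two intervals that turn out to share the
    same optimal option is dropped with a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    sigma = model.spec(j).transformed_sd()
    elements = sorted(float(v) for v in retained)
    notes: list[str] = []
    while True:
        if not elements:
            reps = [model.spec(j).transformed_mean()]
        else:
            reps = [elements[0] - tail_sd * sigma]
            reps += [(a + b) / 2.0 for a, b in zip(elements, elements[1:])]
            reps += [elements[-1] + tail_sd * sigma]
        labels = []
        for x in reps:
            opt, tie = _dominant_option(model, j, x, N, rng)
            if tie:
                notes.append(f"near-tie when labelling the interval at {x:.4g}")
            labels.append(opt)
        dup = next(
            (i for i in range(len(labels) - 1) if labels[i] == labels[i + 1]), None
        )
        if dup is None:
            return ThresholdSet(j, tuple(elements), tuple(labels), tuple(notes))
        notes.append(
            f"dropped element {elements[dup]:.6g}: both sides optimal for "
            f"{labels[dup]}"
        )
        log.warning(notes[-1])
        del elements[dup]


@dataclass
class ThresholdAnalysis:
    """Full per-variable result: pairwise estimates, tests, assembled set."""

    variable: int
    pairwise: dict[tuple[str, str], list[PairwiseRootEstimate]]
    memberships: list[MembershipTest]
    threshold_set: ThresholdSet

    def summary(self) -> dict:
        return {
            "variable": self.variable,
            "pairwise": {
                f"{a},{b}": [e.summary() for e in ests]
                for (a, b), ests in self.pairwise.items()
            },
            "memberships": [m.summary() for m in self.memberships],
            "threshold_set": self.threshold_set.summary(),
        }


def find_thresholds(
    model: DecisionModel,
    j: int,
    config: SAConfig | None = None,
    R: int = 20,
    N_test: int = 10_000,
    level: float = 0.05,
    family: str = "t",
    rng: np.random.Generator | None = None,
    keep_traces: bool = False,
) -> ThresholdAnalysis:
    """End-to-end threshold estimation for one variable over all option pairs.

    Pairs are canonicalised (each unordered pair runs once); the campaign cost
    therefore scales with ``|D| (|D| - 1) / 2`` stochastic-approximation runs
    per variable.
    """
    rng = np.random.default_rng() if rng is None else rng
    config = config or SAConfig()
    pairwise: dict[tuple[str, str], list[PairwiseRootEstimate]] = {}
    memberships: list[MembershipTest] = []
    retained_values: list[float] = []
    for d1, d2 in itertools.combinations(model.options, 2):
        ests = estimate_pairwise_roots(
            model, j, d1, d2, config, R=R, rng=rng, keep_traces=keep_traces
        )
        pairwise[(d1, d2)] = ests
        for est in ests:
            if est.empty:
                continue
            mt = aggregate_membership(
                model, j, est, N=N_test, level=level, family=family, rng=rng
            )
            memberships.append(mt)
            if mt.retained:
                retained_values.append(float(est.mean))
    tset = assemble_threshold_set(model, j, retained_values, N=N_test, rng=rng)
    return ThresholdAnalysis(j, pairwise, memberships, tset)
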