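"""Decision-model abstraction for threshold analysis under parameter uncertainty.

A decision problem compares a finite option set ``D``; each option ``d`` carries
a utility ``f_d(theta)`` (monetary net benefit) of a common random parameter
vector ``theta = (theta_1, ..., theta_s)``.  Marginals may be normal,
log-normal, logit-normal (both parameterised by the mean/variance of the
*underlying* normal), beta, or constant, and pairs of variables may be
correlated through an underlying bivariate normal block.

The module also ships a fully specified synthetic cost-effectiveness model
comparing a cost-free standard of care ``d1`` against two costly new
treatments ``d2``/``d3`` that trade a lower probability of a critical event
against a risk of side effects (see :func:`three_treatment_model`).
"""

from __future__ import annotations

import functools
import json
import pathlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy import integrate, stats
from scipy.special import expit, logit

__all__ = [
    "ModelConfigError",
    "MarginalSpec",
    "CorrelatedBlock",
    "DecisionModel",
    "sample_prior",
    "sample_conditional",
    "odds_to_prob",
    "net_benefit",
    "three_treatment_model",
    "model_to_config",
    "save_config",
    "load_model",
    "samples_to_frame",
]

_FAMILIES = ("normal", "lognormal", "logitnormal", "beta", "constant")
_TRANSFORMS = ("identity", "log", "logit")

# exp() overflows past ~709; clip so far-out stochastic-approximation iterates
# map to huge-but-finite natural values instead of inf
_EXP_CLIP = 700.0


class ModelConfigError(ValueError):
    """Raised for invalid distribution families, parameters or model configs."""


@functools.lru_cache(maxsize=64)
def _logitnormal_mean(mu: float, var: float) -> float:
    # E[expit(Z)], Z ~ N(mu, var); no closed form -> adaptive quadrature
    sd = np.sqrt(var)
    val, _ = integrate.quad(
        lambda z: expit(z) * stats.norm.pdf(z, mu, sd), mu - 12 * sd, mu + 12 * sd
    )
    return float(val)


@dataclass(frozen=True)
class MarginalSpec:
    """One scalar input parameter: distribution family plus iteration transform.

    ``params`` are family specific: ``(mean, var)`` for ``normal`` and for the
    underlying normal of ``lognormal``/``logitnormal``; ``(a, b)`` shapes for
    ``beta``; ``(value,)`` for ``constant``.  ``transform`` names the space in
    which stochastic-approximation iterates live and thresholds are reported.
    """

    name: str
    family: str
    params: tuple[float, ...]
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ModelConfigError(f"unknown family {self.family!r} for {self.name!r}")
        if self.transform not in _TRANSFORMS:
            raise ModelConfigError(f"unknown transform {self.transform!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.family in ("normal", "lognormal", "logitnormal"):
            if len(p) != 2 or p[1] <= 0:
                raise ModelConfigError(f"{self.name}: need (mean, var>0), got {p}")
        elif self.family == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ModelConfigError(f"{self.name}: beta shapes must be > 0")
        elif len(p) != 1:
            raise ModelConfigError(f"{self.name}: constant takes a single value")
        allowed = {
            "normal": ("identity",),
            "lognormal": ("log", "identity"),
            "logitnormal": ("logit",),
            "beta": ("identity",),
            "constant": ("identity",),
        }[self.family]
        if self.transform not in allowed:
            raise ModelConfigError(
                f"{self.name}: transform {self.transform!r} not supported for "
                f"family {self.family!r}"
            )

    # -- factory helpers -------------------------------------------------
    @classmethod
    def normal(cls, name: str, mean: float, var: float) -> "MarginalSpec":
        return cls(name, "normal", (mean, var))

    @classmethod
    def lognormal(cls, name: str, mu: float, var: float) -> "MarginalSpec":
        return cls(name, "lognormal", (mu, var), transform="log")

    @classmethod
    def logitnormal(cls, name: str, mu: float, var: float) -> "MarginalSpec":
        return cls(name, "logitnormal", (mu, var), transform="logit")

    @classmethod
    def beta(cls, name: str, a: float, b: float) -> "MarginalSpec":
        return cls(name, "beta", (a, b))

    @classmethod
    def constant(cls, name: str, value: float) -> "MarginalSpec":
        return cls(name, "constant", (value,))

    # -- natural-space quantities ----------------------------------------
    def mean(self) -> float:
        """Exact natural-space mean (quadrature for the logit-normal)."""
        a, b = (self.params + (0.0,))[:2]
        if self.family == "normal":
            return a
        if self.family == "lognormal":
            return float(np.exp(a + b / 2.0))
        if self.family == "logitnormal":
            return _logitnormal_mean(a, b)
        if self.family == "beta":
            return a / (a + b)
        return self.params[0]

    def in_support(self, value: float) -> bool:
        if not np.isfinite(value):
            return False
        if self.family == "lognormal":
            return value > 0
        if self.family in ("logitnormal", "beta"):
            return 0 < value < 1
        if self.family == "constant":
            return value == self.params[0]
        return True

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        a, b = (self.params + (0.0,))[:2]
        if self.family == "normal":
            return rng.normal(a, np.sqrt(b), n)
        if self.family == "lognormal":
            return np.exp(rng.normal(a, np.sqrt(b), n))
        if self.family == "logitnormal":
            return expit(rng.normal(a, np.sqrt(b), n))
        if self.family == "beta":
            return rng.beta(a, b, n)
        return np.full(n, self.params[0])

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Natural-space quantile function (enables common-random-number reuse)."""
        a, b = (self.params + (0.0,))[:2]
        if self.family == "normal":
            return stats.norm.ppf(u, a, np.sqrt(b))
        if self.family == "lognormal":
            return np.exp(stats.norm.ppf(u, a, np.sqrt(b)))
        if self.family == "logitnormal":
            return expit(stats.norm.ppf(u, a, np.sqrt(b)))
        if self.family == "beta":
            return stats.beta.ppf(u, a, b)
        return np.full_like(np.asarray(u, dtype=float), self.params[0])

    # -- transform space -------------------------------------------------
    def to_transformed(self, value):
        if self.transform == "log":
            return np.log(value)
        if self.transform == "logit":
            return logit(value)
        return value

    def to_natural(self, x):
        if self.transform == "log":
            return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))
        if self.transform == "logit":
            return expit(x)
        return x

    def transformed_mean(self) -> float:
        if self.transform in ("log", "logit"):
            return self.params[0]
        return self.mean()

    def transformed_sd(self) -> float:
        """Marginal standard deviation in the iteration (transformed) space."""
        a, b = (self.params + (0.0,))[:2]
        if self.family == "constant":
            return 0.0
        if self.family == "beta":
            return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))
        if self.transform in ("log", "logit"):
            return float(np.sqrt(b))
        if self.family == "lognormal":  # identity transform on a lognormal
            return float(np.sqrt((np.exp(b) - 1.0) * np.exp(2 * a + b)))
        return float(np.sqrt(b))

    def transformed_dist(self):
        """Frozen scipy distribution of the transformed variable."""
        a, b = (self.params + (0.0,))[:2]
        if self.family == "beta":
            return stats.beta(a, b)
        if self.family == "lognormal" and self.transform == "identity":
            return stats.lognorm(s=np.sqrt(b), scale=np.exp(a))
        if self.family == "constant":
            raise ModelConfigError(f"{self.name}: constant has no distribution")
        return stats.norm(a, np.sqrt(b))


@dataclass(frozen=True)
class CorrelatedBlock:
    """Two variables coupled through an underlying bivariate normal.

    ``mu``/``sigma`` are the mean and covariance of the underlying normal pair;
    members are mapped to natural space through their family transform
    (identity / exp / inverse-logit).
    """

    indices: tuple[int, int]
    mu: tuple[float, float]
    sigma: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.shape != (2, 2) or abs(s[0, 1] - s[1, 0]) > 1e-12:
            raise ModelConfigError("block covariance must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(s) <= 0):
            raise ModelConfigError("block covariance must be positive definite")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        object.__setattr__(self, "mu", tuple(float(m) for m in self.mu))
        object.__setattr__(
            self, "sigma", tuple(tuple(float(v) for v in row) for row in s)
        )

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(np.asarray(self.sigma))

    def conditional(self, fixed_pos: int, x):
        """Exact conditional (mean, var) of the partner's underlying normal
        given the fixed member's underlying value ``x``."""
        other = 1 - fixed_pos
        s = np.asarray(self.sigma)
        slope = s[other, fixed_pos] / s[fixed_pos, fixed_pos]
        mean = self.mu[other] + slope * (x - self.mu[fixed_pos])
        var = s[other, other] - s[other, fixed_pos] ** 2 / s[fixed_pos, fixed_pos]
        return mean, float(var)


# utility contract: (model, option, (n, s) natural-space matrix) -> (n,) array
UtilityFn = Callable[["DecisionModel", str, np.ndarray], np.ndarray]


@dataclass
class DecisionModel:
    """Finite option set, vectorised utility, and parameter distributions."""

    name: str
    options: tuple[str, ...]
    variables: tuple[MarginalSpec, ...]
    utility: UtilityFn
    blocks: tuple[CorrelatedBlock, ...] = ()
    constants: dict[str, float] = field(default_factory=dict)
    plugin_vars: tuple[str, ...] = ()
    utility_name: str = "custom"

    def __post_init__(self) -> None:
        self.options = tuple(self.options)
        self.variables = tuple(self.variables)
        self.blocks = tuple(self.blocks)
        if len(self.options) < 2:
            raise ModelConfigError("a decision model needs at least two options")
        seen: set[int] = set()
        for blk in self.blocks:
            for pos, idx in enumerate(blk.indices):
                if idx in seen:
                    raise ModelConfigError(f"variable {idx} appears in two blocks")
                seen.add(idx)
                spec = self.variables[idx]
                if spec.family not in ("normal", "lognormal", "logitnormal"):
                    raise ModelConfigError(
                        f"{spec.name}: only normal-underlying families may be "
                        "block members"
                    )
                if (
                    abs(spec.params[0] - blk.mu[pos]) > 1e-9
                    or abs(spec.params[1] - blk.sigma[pos][pos]) > 1e-9
                ):
                    raise ModelConfigError(
                        f"{spec.name}: marginal params disagree with its block"
                    )
        unknown = set(self.plugin_vars) - {v.name for v in self.variables}
        if unknown:
            raise ModelConfigError(f"plug-in names not in model: {sorted(unknown)}")

    # -- lookups ---------------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        for i, v in enumerate(self.variables):
            if v.name == name:
                return i
        raise KeyError(name)

    def spec(self, j: int) -> MarginalSpec:
        return self.variables[j]

    def block_of(self, j: int):
        """Return ``(block, position_of_j)`` or ``None``."""
        for blk in self.blocks:
            if j in blk.indices:
                return blk, blk.indices.index(j)
        return None

    def partner_of(self, j: int):
        hit = self.block_of(j)
        if hit is None:
            return None
        blk, pos = hit
        return blk.indices[1 - pos]

    # -- evaluation ------------------------------------------------------
    def evaluate(self, option: str, theta: np.ndarray) -> np.ndarray:
        if option not in self.options:
            raise KeyError(f"unknown option {option!r}")
        return np.asarray(self.utility(self, option, np.atleast_2d(theta)))

    def utilities(self, theta: np.ndarray) -> np.ndarray:
        """(n, |D|) matrix of utilities on common samples."""
        theta = np.atleast_2d(theta)
        return np.column_stack([self.evaluate(d, theta) for d in self.options])


def _underlying(spec: MarginalSpec, value):
    """Map a natural value of a normal-underlying family to its normal scale."""
    if spec.family == "lognormal":
        return np.log(value)
    if spec.family == "logitnormal":
        return logit(value)
    return value


def _from_underlying(spec: MarginalSpec, z):
    if spec.family == "lognormal":
        return np.exp(np.clip(z, -_EXP_CLIP, _EXP_CLIP))
    if spec.family == "logitnormal":
        return expit(z)
    return z


def sample_prior(model: DecisionModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` parameter vectors from the prior; returns an ``(n, s)`` array.

    Block members are drawn jointly from the underlying bivariate normal; all
    other components are mutually independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty((n, model.n_vars))
    handled: set[int] = set()
    for blk in model.blocks:
        z = rng.standard_normal((n, 2)) @ blk.cholesky().T + np.asarray(blk.mu)
        for pos, idx in enumerate(blk.indices):
            out[:, idx] = _from_underlying(model.variables[idx], z[:, pos])
            handled.add(idx)
    for idx, spec in enumerate(model.variables):
        if idx not in handled:
            out[:, idx] = spec.sample(rng, n)
    return out


def sample_conditional(
    model: DecisionModel,
    j: int,
    theta_j,
    n: int,
    rng: np.random.Generator,
    plug_in: bool = False,
) -> np.ndarray:
    """Draw ``n`` vectors with component ``j`` fixed at ``theta_j`` (natural space).

    ``theta_j`` may be a scalar or an ``(n,)`` array pairing one conditioning
    value per output row.  A correlated partner of ``j`` is drawn from the
    exact conditional univariate normal of the underlying bivariate normal.
    With ``plug_in`` enabled, variables in ``model.plugin_vars`` (other than
    ``j`` itself) are replaced by their exact means — the partner of ``j``, if
    plug-in eligible, by its exact conditional mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec_j = model.spec(j)
    theta_j = np.broadcast_to(np.asarray(theta_j, dtype=float), (n,)).copy()
    if spec_j.family == "lognormal":
        ok = np.all(theta_j > 0)
    elif spec_j.family in ("logitnormal", "beta"):
        ok = np.all((theta_j > 0) & (theta_j < 1))
    else:
        ok = np.all(np.isfinite(theta_j))
    if not ok:
        raise ValueError(f"value outside the support of {spec_j.name!r}")

    plugged = set(model.plugin_vars) if plug_in else set()
    plugged.discard(spec_j.name)

    out = np.empty((n, model.n_vars))
    out[:, j] = theta_j
    handled = {j}

    hit = model.block_of(j)
    if hit is not None:
        blk, pos = hit
        partner = blk.indices[1 - pos]
        p_spec = model.variables[partner]
        mean, var = blk.conditional(pos, _underlying(spec_j, theta_j))
        if p_spec.name in plugged:
            # exact conditional mean of the partner (valid: it enters linearly)
            if p_spec.family == "normal":
                out[:, partner] = mean
            elif p_spec.family == "lognormal":
                out[:, partner] = np.exp(mean + var / 2.0)
            else:
                raise ModelConfigError(
                    f"{p_spec.name}: no closed-form conditional mean for plug-in"
                )
        else:
            z = mean + np.sqrt(var) * rng.standard_normal(n)
            out[:, partner] = _from_underlying(p_spec, z)
        handled.add(partner)

    for blk in model.blocks:
        if j in blk.indices:
            continue
        members = [model.variables[i] for i in blk.indices]
        if all(m.name in plugged for m in members):
            for idx, m in zip(blk.indices, members):
                out[:, idx] = m.mean()
        else:
            z = rng.standard_normal((n, 2)) @ blk.cholesky().T + np.asarray(blk.mu)
            for pos2, idx in enumerate(blk.indices):
                m = model.variables[idx]
                if m.name in plugged:
                    out[:, idx] = m.mean()
                else:
                    out[:, idx] = _from_underlying(m, z[:, pos2])
        handled.update(blk.indices)

    for idx, spec in enumerate(model.variables):
        if idx in handled:
            continue
        if spec.name in plugged:
            out[:, idx] = spec.mean()
        else:
            out[:, idx] = spec.sample(rng, n)
    return out


def odds_to_prob(p_base, odds_ratio):
    """Event probability under an option given the baseline probability and odds ratio.

    Solves ``OR = [p/(1-p)] / [p_base/(1-p_base)]`` for ``p``.
    """
    p_base = np.asarray(p_base, dtype=float)
    odds_ratio = np.asarray(odds_ratio, dtype=float)
    if np.any((p_base <= 0) | (p_base >= 1)):
        raise ValueError("p_base must lie strictly in (0, 1)")
    if np.any(odds_ratio <= 0):
        raise ValueError("odds_ratio must be positive")
    q = odds_ratio * p_base / (1.0 - p_base)
    out = q / (1.0 + q)
    return float(out) if out.ndim == 0 else out


# column order of the built-in model
_L, _QE, _QSE, _CE, _CSE, _CT2, _CT3, _PE1, _OR2, _OR3, _PSE2, _PSE3 = range(12)


def net_benefit(model: DecisionModel, option: str, theta: np.ndarray) -> np.ndarray:
    """Monetary net benefit of a treatment for the built-in three-treatment model.

    Four outcome terms (side effect x critical event) weighted by their joint
    probabilities, minus the treatment cost; QALYs converted to money at the
    willingness-to-pay ``lambda``.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    lam = model.constants["lambda"]
    L, q_e, q_se = theta[:, _L], theta[:, _QE], theta[:, _QSE]
    c_e, c_se = theta[:, _CE], theta[:, _CSE]
    p_e1 = theta[:, _PE1]
    if option == "d1":
        p_se = np.full(L.shape, model.constants["P_SE_d1"])
        c_t = np.full(L.shape, model.constants["C_T_d1"])
        p_e = p_e1
    elif option == "d2":
        p_se, c_t = theta[:, _PSE2], theta[:, _CT2]
        p_e = odds_to_prob(p_e1, theta[:, _OR2])
    elif option == "d3":
        p_se, c_t = theta[:, _PSE3], theta[:, _CT3]
        p_e = odds_to_prob(p_e1, theta[:, _OR3])
    else:
        raise KeyError(f"unknown option {option!r}")
    half_life = L * (1.0 + q_e) / 2.0
    return (
        p_se * p_e * (lam * (half_life - q_se) - (c_se + c_e))
        + p_se * (1.0 - p_e) * (lam * (L - q_se) - c_se)
        + (1.0 - p_se) * p_e * (lam * half_life - c_e)
        + (1.0 - p_se) * (1.0 - p_e) * lam * L
        - c_t
    )


def three_treatment_model() -> DecisionModel:
    """The synthetic three-treatment cost-effectiveness model.

    Twelve random inputs (lifetimes, QALY weights, costs, event/side-effect
    probabilities and odds ratios, with three correlated pairs), constants
    ``C_T_d1 = 0``, ``P_SE_d1 = 0`` and willingness-to-pay 75 000 per QALY.
    """
    variables = (
        MarginalSpec.normal("L", 30.0, 25.0),
        MarginalSpec.logitnormal("Q_E", 0.6, 1.0 / 36.0),
        MarginalSpec.normal("Q_SE", 0.7, 0.01),
        MarginalSpec.normal("C_E", 2.0e5, 1.0e8),
        MarginalSpec.normal("C_SE", 1.0e5, 1.0e8),
        MarginalSpec.normal("C_T_d2", 1.5e4, 300.0),
        MarginalSpec.normal("C_T_d3", 2.0e4, 500.0),
        MarginalSpec.beta("P_E_d1", 15.0, 85.0),
        MarginalSpec.lognormal("OR_E_d2", -1.5, 0.11),
        MarginalSpec.lognormal("OR_E_d3", -1.75, 0.06),
        MarginalSpec.logitnormal("P_SE_d2", -1.4, 0.10),
        MarginalSpec.logitnormal("P_SE_d3", -1.1, 0.25),
    )
    blocks = (
        CorrelatedBlock((5, 6), (1.5e4, 2.0e4), ((300.0, 100.0), (100.0, 500.0))),
        CorrelatedBlock((8, 9), (-1.5, -1.75), ((0.11, 0.02), (0.02, 0.06))),
        CorrelatedBlock((10, 11), (-1.4, -1.1), ((0.10, 0.05), (0.05, 0.25))),
    )
    return DecisionModel(
        name="three_treatment",
        options=("d1", "d2", "d3"),
        variables=variables,
        utility=net_benefit,
        blocks=blocks,
        constants={"C_T_d1": 0.0, "P_SE_d1": 0.0, "lambda": 7.5e4},
        # variables entering every net benefit linearly and independently of
        # the sampled nonlinear ones; their exact means may be substituted
        plugin_vars=("L", "Q_E", "Q_SE", "C_E", "C_SE", "C_T_d2", "C_T_d3"),
        utility_name="three_treatment_net_benefit",
    )


_UTILITY_REGISTRY: dict[str, UtilityFn] = {
    "three_treatment_net_benefit": net_benefit,
}


def model_to_config(model: DecisionModel) -> dict:
    """Serialise a model to a plain dict (YAML/JSON-ready)."""
    return {
        "name": model.name,
        "options": list(model.options),
        "variables": [
            {
                "name": v.name,
                "family": v.family,
                "params": list(v.params),
                "transform": v.transform,
            }
            for v in model.variables
        ],
        "blocks": [
            {
                "members": list(b.indices),
                "mu": list(b.mu),
                "sigma": [list(row) for row in b.sigma],
            }
            for b in model.blocks
        ],
        "constants": dict(model.constants),
        "plugin_vars": list(model.plugin_vars),
        "utility": model.utility_name,
    }


def save_config(model: DecisionModel, path) -> None:
    path = pathlib.Path(path)
    cfg = model_to_config(model)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))


def load_model(source, utility: UtilityFn | None = None) -> DecisionModel:
    """Build a model from a config dict or a YAML/JSON/TOML file.

    User models must either name a registered utility in the config or pass a
    callable implementing the vectorised utility contract.
    """
    if isinstance(source, (str, pathlib.Path)):
        path = pathlib.Path(source)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            cfg = tomllib.loads(text)
        elif path.suffix in (".yaml", ".yml"):
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    else:
        cfg = dict(source)
    util_name = cfg.get("utility", "custom")
    if utility is None:
        utility = _UTILITY_REGISTRY.get(util_name)
        if utility is None:
            raise ModelConfigError(
                f"utility {util_name!r} is not registered; pass a callable"
            )
    return DecisionModel(
        name=cfg.get("name", "model"),
        options=tuple(cfg["options"]),
        variables=tuple(
            MarginalSpec(
                v["name"], v["family"], tuple(v["params"]), v.get("transform", "identity")
            )
            for v in cfg["variables"]
        ),
        utility=utility,
        blocks=tuple(
            CorrelatedBlock(
                tuple(b["members"]),
                tuple(b["mu"]),
                tuple(tuple(row) for row in b["sigma"]),
            )
            for b in cfg.get("blocks", [])
        ),
        constants=dict(cfg.get("constants", {})),
        plugin_vars=tuple(cfg.get("plugin_vars", ())),
        utility_name=util_name,
    )


def samples_to_frame(model: DecisionModel, theta: np.ndarray):
    """Samples as a DataFrame, one column per variable (CSV-export ready)."""
    import pandas as pd

    return pd.DataFrame(np.atleast_2d(theta), columns=[v.name for v in model.variables])
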