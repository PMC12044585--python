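"""Synthetic study-area panels from a fully specified structural causal model.

The generator emulates the shape of the boreal-caribou evidence base — by
default 58 study areas carrying about 159 observation-years in total, with
covariates in field-plausible ranges — while making the causal ground
truth exactly computable.  The structural outcome model is additive on the
log-odds scale: the probability that a subpopulation is declining is

    logit P(Y=1) = baseline + sum_j beta_j * 1[covariate_j beyond cutpoint_j]

with every beta_j >= 0, so the effect of each exposure is monotone
(never protective) by construction.  Recruitment is then drawn as a
continuous calves:100-cows value on the matching side of 29, so the
dichotomization stage downstream is genuinely exercised rather than
bypassed.

Two anthropogenic covariates (linear-feature density and cutblock cover)
share a latent "industrial development" factor, giving them a realistic
positive correlation; the remaining covariates are independent.  Because
the exposure indicators' joint law is known in closed form (given the
one-dimensional latent), :func:`true_probabilities` returns exact p1, p0,
PN, PS, and PNS for any query, serving as ground truth in parameter
recovery tests.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import ConfigError
from .estimators import (
    CausalQueryResult,
    prob_necessity,
    prob_necessity_sufficiency,
    prob_sufficiency,
)

__all__ = [
    "ScmConfig",
    "default_config",
    "null_config",
    "single_exposure_config",
    "simulate_panel",
    "true_probabilities",
    "check_monotonic",
]

_JURISDICTIONS = ("BC", "AB", "SK", "MB", "ON", "QC", "NT", "YT", "NL")

#: Observation-years per area, 1..10; mean ~2.72 so 58 areas carry ~158 years.
_DEFAULT_WEIGHT_PROBS = {
    1: 0.38, 2: 0.24, 3: 0.12, 4: 0.08, 5: 0.06,
    6: 0.04, 7: 0.03, 8: 0.03, 9: 0.01, 10: 0.01,
}

#: Marginal models: scaled Beta draws, or a mixture with the shared
#: development latent (kind "dev_mix": value = low + (high-low) *
#: (rho*latent + (1-rho)*uniform)).
_DEFAULT_COVARIATES = {
    "agg_disturbance": {"kind": "beta", "a": 1.8, "b": 1.2, "low": 0.0, "high": 100.0},
    "linear_density": {"kind": "dev_mix", "rho": 0.5, "low": 0.0, "high": 0.6},
    "cutblock_pct": {"kind": "dev_mix", "rho": 0.5, "low": 0.0, "high": 30.0},
    "burned_pct": {"kind": "beta", "a": 1.0, "b": 3.0, "low": 0.0, "high": 80.0},
    "mean_evi": {"kind": "beta", "a": 2.0, "b": 2.0, "low": 2000.0, "high": 4500.0},
}

_DEFAULT_CUTPOINTS = {
    "agg_disturbance": 35.0,
    "linear_density": 0.2,
    "cutblock_pct": 10.0,
    "burned_pct": 40.0,
    "mean_evi": 3500.0,
}

#: Log-odds increments of decline per active exposure (all >= 0: monotone).
_DEFAULT_EFFECTS = {
    "agg_disturbance": 0.9,
    "linear_density": 1.2,
    "cutblock_pct": 0.8,
    "burned_pct": 0.2,
    "mean_evi": 0.7,
}


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class ScmConfig:
    """Full generative specification for a synthetic study-area panel."""

    n_areas: int = 58
    weight_probs: Mapping[int, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHT_PROBS))
    covariate_models: Mapping[str, Mapping] = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_COVARIATES.items()
    })
    exposure_cutpoints: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_CUTPOINTS))
    baseline_logit: float = _logit(0.55)
    effects: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    recruitment_threshold: float = 29.0
    seed: int = 0

    def __post_init__(self):
        if self.n_areas < 1:
            raise ConfigError("n_areas must be >= 1")
        total = sum(self.weight_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"weight_probs must sum to 1, got {total}")
        if any(w < 1 or w != int(w) for w in self.weight_probs):
            raise ConfigError("weight_probs keys must be positive integers")
        for col, model in self.covariate_models.items():
            low, high = model.get("low"), model.get("high")
            if low is None or high is None or not low < high:
                raise ConfigError(f"covariate {col!r}: needs a valid [low, high) range")
            kind = model.get("kind")
            if kind == "beta":
                if model.get("a", 0) <= 0 or model.get("b", 0) <= 0:
                    raise ConfigError(f"covariate {col!r}: beta shapes must be positive")
            elif kind == "dev_mix":
                if not 0.0 <= model.get("rho", -1) <= 1.0:
                    raise ConfigError(f"covariate {col!r}: rho must lie in [0, 1]")
            else:
                raise ConfigError(f"covariate {col!r}: unknown kind {kind!r}")
        unknown = set(self.effects) - set(self.covariate_models)
        if unknown:
            raise ConfigError(f"effects reference unmodeled covariates: {sorted(unknown)}")
        unknown = set(self.exposure_cutpoints) - set(self.covariate_models)
        if unknown:
            raise ConfigError(f"cutpoints reference unmodeled covariates: {sorted(unknown)}")

    @property
    def exposure_columns(self) -> tuple[str, ...]:
        return tuple(sorted(self.exposure_cutpoints))


def default_config(seed: int = 0, **overrides) -> ScmConfig:
    """The standard caribou-like configuration."""
    return ScmConfig(seed=seed, **overrides)


def null_config(seed: int = 0, **overrides) -> ScmConfig:
    """All exposure effects zero: every probability of causation is 0."""
    effects = {k: 0.0 for k in _DEFAULT_EFFECTS}
    return ScmConfig(seed=seed, effects=effects, **overrides)


def single_exposure_config(p1: float, p0: float, exposure: str = "agg_disturbance",
                           seed: int = 0, **overrides) -> ScmConfig:
    """A config in which only one exposure acts, with exact conditionals.

    ``P(Y=1 | exposure=1) = p1`` and ``P(Y=1 | exposure=0) = p0`` hold
    exactly, so e.g. ``p1=0.9, p0=0.6`` gives true PNS = 0.3, PN = 1/3,
    PS = 0.75.  Requires ``p1 >= p0`` for a monotone model.
    """
    if not (0 < p0 <= p1 < 1):
        raise ConfigError("need 0 < p0 <= p1 < 1 for a monotone single-exposure model")
    effects = {k: 0.0 for k in _DEFAULT_EFFECTS}
    effects[exposure] = _logit(p1) - _logit(p0)
    return ScmConfig(seed=seed, baseline_logit=_logit(p0), effects=effects, **overrides)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, order-insensitive random stream per stage name."""
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, sub])


def _draw_covariate(model: Mapping, n: int, rng: np.random.Generator,
                    latent: np.ndarray) -> np.ndarray:
    low, high = model["low"], model["high"]
    if model["kind"] == "beta":
        u = rng.beta(model["a"], model["b"], size=n)
    else:  # dev_mix
        rho = model["rho"]
        u = rho * latent + (1.0 - rho) * rng.random(n)
    return low + (high - low) * u


def simulate_panel(config: ScmConfig) -> pd.DataFrame:
    """Draw a synthetic study-area table (the canonical CSV schema).

    Deterministic for a fixed ``config.seed``; per-covariate random
    streams are keyed by name, so adding a covariate does not perturb the
    draws of the others.
    """
    n = config.n_areas
    seed = config.seed
    latent = _stream(seed, "development_latent").random(n)

    cols: dict[str, np.ndarray] = {}
    for name in sorted(config.covariate_models):
        cols[name] = _draw_covariate(config.covariate_models[name], n,
                                     _stream(seed, f"cov:{name}"), latent)

    logits = np.full(n, config.baseline_logit)
    for name, beta in config.effects.items():
        cut = config.exposure_cutpoints.get(name)
        if cut is None or beta == 0.0:
            continue
        logits = logits + beta * (cols[name] > cut)
    p_decline = 1.0 / (1.0 + np.exp(-logits))
    y = _stream(seed, "outcome").random(n) < p_decline

    rng_rec = _stream(seed, "recruitment")
    thr = config.recruitment_threshold
    below = thr * rng_rec.beta(2.0, 2.0, size=n)            # declining: in (0, 29)
    above = thr + (60.0 - thr) * rng_rec.beta(1.5, 3.0, size=n)  # stable: in (29, 60)
    recruitment = np.where(y, below, above)

    weights_support = np.array(sorted(config.weight_probs))
    weights_p = np.array([config.weight_probs[k] for k in weights_support], dtype=float)
    weight = _stream(seed, "weights").choice(weights_support, size=n, p=weights_p)

    jurisdiction = _stream(seed, "jurisdiction").choice(_JURISDICTIONS, size=n)

    frame = pd.DataFrame({
        "area_id": [f"SA{i:06d}" for i in range(n)],
        "jurisdiction": jurisdiction,
        "recruitment": recruitment,
        "weight": weight.astype(np.int64),
    })
    for name in ("agg_disturbance", "linear_density", "cutblock_pct", "burned_pct", "mean_evi"):
        frame[name] = cols.get(name, np.zeros(n))
    return frame


def _exceed_prob_independent(model: Mapping, cut: float) -> float:
    """P(value > cut) for a covariate not tied to the development latent."""
    low, high = model["low"], model["high"]
    z = (cut - low) / (high - low)
    if z <= 0:
        return 1.0
    if z >= 1:
        return 0.0
    return float(stats.beta.sf(z, model["a"], model["b"]))


def _exceed_prob_given_latent(model: Mapping, cut: float, d: float) -> float:
    low, high = model["low"], model["high"]
    z = (cut - low) / (high - low)
    rho = model["rho"]
    if rho >= 1.0:
        return float(d > z)
    return float(np.clip(1.0 - (z - rho * d) / (1.0 - rho), 0.0, 1.0))


def _config_probability(config: ScmConfig, assignment: Mapping[str, int]) -> float:
    """Exact P(joint exposure-indicator configuration) under the generative law."""
    indep = 1.0
    dev_cols = []
    for name, val in assignment.items():
        model = config.covariate_models[name]
        cut = config.exposure_cutpoints[name]
        if model["kind"] == "beta":
            q = _exceed_prob_independent(model, cut)
            indep *= q if val == 1 else 1.0 - q
        else:
            dev_cols.append((model, cut, val))
    if not dev_cols:
        return indep

    def integrand(d: float) -> float:
        prod = 1.0
        for model, cut, val in dev_cols:
            q = _exceed_prob_given_latent(model, cut, d)
            prod *= q if val == 1 else 1.0 - q
        return prod

    dev_mass, _ = integrate.quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-12)
    return indep * dev_mass


def _outcome_prob(config: ScmConfig, assignment: Mapping[str, int]) -> float:
    logit = config.baseline_logit
    for name, beta in config.effects.items():
        if name in assignment:
            logit += beta * assignment[name]
    return _sigmoid(logit)


def true_probabilities(config: ScmConfig, exposures,
                       stratum: Mapping[str, int] | None = None) -> CausalQueryResult:
    """Exact PN/PS/PNS implied by the generative law for a query.

    Marginalizes the non-queried exposure indicators over their exact
    joint distribution (one-dimensional quadrature over the development
    latent where needed).  The returned ``n_*_weight`` fields hold the
    probability mass of the factual / counterfactual conditioning events.
    """
    exposures = tuple(exposures)
    unknown = [e for e in exposures if e not in config.covariate_models]
    unknown += [s for s in (stratum or {}) if s not in config.covariate_models]
    if unknown:
        raise ConfigError(f"unmodeled exposure(s): {sorted(set(unknown))}")
    all_cols = config.exposure_columns
    others = [c for c in all_cols if c not in exposures and c not in (stratum or {})]

    def side(value: int) -> tuple[float, float]:
        fixed = {e: value for e in exposures}
        fixed.update(stratum or {})
        mass = 0.0
        mass_y = 0.0
        for rest in itertools.product((0, 1), repeat=len(others)):
            assignment = dict(fixed)
            assignment.update(zip(others, rest))
            p_cfg = _config_probability(config, assignment)
            mass += p_cfg
            mass_y += p_cfg * _outcome_prob(config, assignment)
        return (mass_y / mass if mass > 0 else float("nan")), mass

    p1, m1 = side(1)
    p0, m0 = side(0)
    pns = prob_necessity_sufficiency(p1, p0)
    pn = prob_necessity(p1, p0)
    ps = prob_sufficiency(p1, p0)
    return CausalQueryResult(
        exposures=exposures, stratum=dict(stratum) if stratum else None,
        p1=p1, p0=p0, pn=pn, ps=ps, pns=pns,
        n_exposed_weight=m1, n_unexposed_weight=m0,
        clipped=p0 > p1, valid=True, label="ground_truth",
    )


def check_monotonic(config: ScmConfig) -> bool:
    """True iff no exposure is protective in any context.

    Enumerates the full binary lattice of exposure indicators and checks
    P(Y=1 | exposure=1, rest) >= P(Y=1 | exposure=0, rest) for every
    exposure and every configuration of the others.
    """
    cols = config.exposure_columns
    for j, name in enumerate(cols):
        others = [c for c in cols if c != name]
        for rest in itertools.product((0, 1), repeat=len(others)):
            base = dict(zip(others, rest))
            hi = _outcome_prob(config, {**base, name: 1})
            lo = _outcome_prob(config, {**base, name: 0})
            if hi < lo - 1e-12:
                return False
    return True
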