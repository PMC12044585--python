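"""Probabilities of necessary, sufficient, and necessary-and-sufficient causation.

For a binary exposure X and binary outcome Y, the factual probability is
p1 = P(Y=1 | X=1) and the counterfactual probability is p0 = P(Y=1 | X=0).
Under exogeneity (the exposure has no causes inside the model) and
monotonicity (the exposure never protects any unit), Tian & Pearl's point
identification gives

    PN  = max(1 - p0/p1, 0)            (necessity)
    PS  = max(1 - (1-p1)/(1-p0), 0)    (sufficiency)
    PNS = max(p1 - p0, 0)              (necessity and sufficiency)

Whenever p1 >= p0 these satisfy PN * p1 = PNS = PS * (1 - p0).

Multi-factor queries condition on ALL listed exposures being 1 (factual)
versus ALL being 0 (counterfactual); units with a mixed exposure
configuration belong to neither conditioning set.  Strata condition both
sides on additional binary variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigError, UndefinedProbabilityError
from .panel import BinaryPanel

__all__ = [
    "CausalQueryResult",
    "CausalAttribution",
    "conditional_outcome_prob",
    "prob_necessity",
    "prob_sufficiency",
    "prob_necessity_sufficiency",
    "attribution_query",
    "bootstrap_interval",
]


@dataclass(frozen=True)
class CausalQueryResult:
    """Point estimates for one attribution query.

    ``pn``/``ps`` are ``None`` when unidentified (p1 = 0 or p0 = 1, or an
    empty conditioning set); ``valid`` is False in those cases.  ``clipped``
    records whether any max(., 0) clip fired, i.e. p0 > p1.
    """

    exposures: tuple[str, ...]
    stratum: Mapping[str, int] | None
    p1: float | None
    p0: float | None
    pn: float | None
    ps: float | None
    pns: float | None
    n_exposed_weight: float
    n_unexposed_weight: float
    clipped: bool
    valid: bool
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "exposures": list(self.exposures),
            "stratum": dict(self.stratum) if self.stratum else None,
            "p1": self.p1, "p0": self.p0,
            "pn": self.pn, "ps": self.ps, "pns": self.pns,
            "n_exposed_weight": self.n_exposed_weight,
            "n_unexposed_weight": self.n_unexposed_weight,
            "clipped": self.clipped, "valid": self.valid,
            "label": self.label,
        }


def conditional_outcome_prob(panel: BinaryPanel, exposures, exposure_value: int,
                             stratum: Mapping[str, int] | None = None) -> tuple[float, float]:
    """Weighted P(Y=1 | all exposures = value, stratum) and the conditioning weight.

    Returns ``(probability, weight_sum)``.  Raises
    :class:`UndefinedProbabilityError` when the conditioning set carries
    zero weight.
    """
    exposures = list(exposures)
    for name in exposures + list(stratum or {}):
        if name not in panel.frame.columns:
            raise ConfigError(f"unknown panel variable {name!r}")
    mask = np.ones(len(panel.frame), dtype=bool)
    for name in exposures:
        mask &= panel.column(name) == exposure_value
    for name, val in (stratum or {}).items():
        mask &= panel.column(name) == val
    w = panel.column("weight")[mask].astype(float)
    wsum = float(w.sum())
    if wsum <= 0:
        raise UndefinedProbabilityError(
            f"empty conditioning set: exposures={exposures}={exposure_value}, stratum={stratum}"
        )
    y = panel.column(panel.outcome_name)[mask]
    return float(np.sum(w * (y == 1)) / wsum), wsum


def prob_necessity(p1: float, p0: float) -> float:
    """PN = max(1 - p0/p1, 0); undefined when p1 = 0 (no exposed cases)."""
    if p1 <= 0:
        raise UndefinedProbabilityError("PN undefined: p1 = 0")
    return max(1.0 - p0 / p1, 0.0)


def prob_sufficiency(p1: float, p0: float) -> float:
    """PS = max(1 - (1-p1)/(1-p0), 0); undefined when p0 = 1."""
    if p0 >= 1:
        raise UndefinedProbabilityError("PS undefined: p0 = 1")
    return max(1.0 - (1.0 - p1) / (1.0 - p0), 0.0)


def prob_necessity_sufficiency(p1: float, p0: float) -> float:
    """PNS = max(p1 - p0, 0); always defined."""
    return max(p1 - p0, 0.0)


def attribution_query(panel: BinaryPanel, exposures,
                      stratum: Mapping[str, int] | None = None,
                      label: str = "") -> CausalQueryResult:
    """Full PN/PS/PNS query on a weighted binary panel.

    Composes the factual (all exposures = 1) and counterfactual (all = 0)
    conditional outcome probabilities with the identification formulas.
    Undefined components are carried as ``None`` with ``valid=False``
    rather than raised, so query batches and sweeps degrade gracefully.
    """
    exposures = tuple(exposures)
    if not exposures:
        raise ConfigError("attribution_query needs at least one exposure")
    p1 = p0 = None
    w1 = w0 = 0.0
    try:
        p1, w1 = conditional_outcome_prob(panel, exposures, 1, stratum)
    except UndefinedProbabilityError:
        pass
    try:
        p0, w0 = conditional_outcome_prob(panel, exposures, 0, stratum)
    except UndefinedProbabilityError:
        pass

    pn = ps = pns = None
    clipped = False
    valid = p1 is not None and p0 is not None
    if valid:
        clipped = p0 > p1
        pns = prob_necessity_sufficiency(p1, p0)
        try:
            pn = prob_necessity(p1, p0)
        except UndefinedProbabilityError:
            valid = False
        try:
            ps = prob_sufficiency(p1, p0)
        except UndefinedProbabilityError:
            valid = False
    return CausalQueryResult(
        exposures=exposures, stratum=dict(stratum) if stratum else None,
        p1=p1, p0=p0, pn=pn, ps=ps, pns=pns,
        n_exposed_weight=w1, n_unexposed_weight=w0,
        clipped=clipped, valid=valid, label=label,
    )


def bootstrap_interval(panel: BinaryPanel, exposures,
                       stratum: Mapping[str, int] | None = None,
                       n_resamples: int = 2000, seed: int = 0,
                       alpha: float = 0.05) -> dict:
    """Percentile bootstrap intervals for p1, p0, PN, PS, PNS.

    Units (rows) are resampled with replacement, each keeping its weight.
    Resamples on which a quantity is undefined are skipped for that
    quantity and counted in ``n_undefined``.  Deterministic for a fixed
    seed.
    """
    if n_resamples < 1:
        raise ConfigError("n_resamples must be >= 1")
    n = len(panel.frame)
    if n < 2:
        raise ConfigError("bootstrap needs at least 2 units")
    rng = np.random.default_rng(seed)
    quantities = {"p1": [], "p0": [], "pn": [], "ps": [], "pns": []}
    n_undefined = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        res = attribution_query(panel.subset(idx), exposures, stratum)
        if not res.valid:
            n_undefined += 1
        for q in quantities:
            v = getattr(res, q)
            if v is not None:
                quantities[q].append(v)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out = {
        q: (float(np.percentile(v, lo)), float(np.percentile(v, hi))) if v else None
        for q, v in quantities.items()
    }
    out["n_undefined"] = n_undefined
    return out


class CausalAttribution(BaseEstimator):
    """Estimator interface for one attribution query.

    Parameters
    ----------
    exposures : sequence of str
        Exposure columns conditioned jointly (all 1 vs all 0).
    stratum : mapping or None
        Additional binary conditions applied to both sides.

    Attributes (after :meth:`fit`)
    ------------------------------
    p1_, p0_ : float or None
        Factual / counterfactual outcome probabilities.
    pn_, ps_, pns_ : float or None
        Probabilities of necessary / sufficient / necessary-and-sufficient
        causation.
    clipped_, valid_ : bool
    result_ : CausalQueryResult
    """

    def __init__(self, exposures: Sequence[str] = (), stratum: Mapping[str, int] | None = None):
        self.exposures = exposures
        self.stratum = stratum

    def fit(self, X: BinaryPanel, y=None):
        res = attribution_query(X, self.exposures, self.stratum)
        self.result_ = res
        self.p1_, self.p0_ = res.p1, res.p0
        self.pn_, self.ps_, self.pns_ = res.pn, res.ps, res.pns
        self.clipped_, self.valid_ = res.clipped, res.valid
        return self

    def bootstrap(self, X: BinaryPanel, n_resamples: int = 2000, seed: int = 0,
                  alpha: float = 0.05) -> dict:
        return bootstrap_interval(X, self.exposures, self.stratum, n_resamples, seed, alpha)
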