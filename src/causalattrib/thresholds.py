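"""Empirical cutpoint selection and the dichotomization sensitivity sweep.

Because the probabilities of causation are computed from binarized data,
they inherit the choice of cutpoints.  Two tools address that here:

* :func:`select_exposure_threshold` picks, for one covariate, the smallest
  candidate cutpoint above which (strictly) at most ``max_exceptions``
  stable-increasing areas remain — the data-driven rule that maximizes the
  factual probability p1 while keeping the exposed set non-empty.
* :func:`sensitivity_sweep` re-binarizes and re-runs the attribution query
  over a grid of aggregate-disturbance cutpoints (default: the policy 35%
  plus/minus 30 percentage points in 5-point steps) so the dependence of
  PN/PS/PNS on the threshold is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ThresholdNotFoundError
from .estimators import CausalQueryResult, attribution_query
from .panel import (
    DEFAULT_OUTCOME_SPEC,
    ThresholdSpec,
    binarize,
    records_to_frame,
)

__all__ = ["SweepResult", "select_exposure_threshold", "sensitivity_sweep"]


@dataclass
class SweepResult:
    """One attribution result per cutpoint, cutpoints strictly increasing."""

    rows: list[tuple[float, CausalQueryResult]]

    def __post_init__(self):
        cuts = [c for c, _ in self.rows]
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ConfigError("sweep cutpoints must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        records = []
        for cut, res in self.rows:
            records.append({
                "cutpoint": cut,
                "p1": res.p1, "p0": res.p0,
                "pn": res.pn, "ps": res.ps, "pns": res.pns,
                "valid": res.valid,
            })
        return pd.DataFrame(records)


def _as_frame(records):
    return records if isinstance(records, pd.DataFrame) else records_to_frame(records)


def select_exposure_threshold(records, column: str,
                              outcome_spec: ThresholdSpec = DEFAULT_OUTCOME_SPEC,
                              max_exceptions: int = 0,
                              grid: Sequence[float] | None = None,
                              weighted: bool = False) -> float:
    """Smallest cutpoint whose exceedance set holds at most ``max_exceptions``
    stable-increasing areas.

    With the default ``grid=None`` the candidates are the sorted distinct
    observed values of ``column``; at ``max_exceptions=0`` the selected
    cutpoint is then the largest observed value among stable-increasing
    (Y=0) areas, so strictly-greater coding exposes no Y=0 area.  At least
    one area must exceed the returned cutpoint.  Exceptions are counted in
    areas by default (``weighted=True`` counts observation-years instead).

    Raises :class:`ThresholdNotFoundError` when no candidate qualifies.
    """
    frame = _as_frame(records)
    if column not in frame.columns:
        raise ConfigError(f"unknown column {column!r}")
    if max_exceptions < 0:
        raise ConfigError("max_exceptions must be >= 0")
    values = frame[column].to_numpy(dtype=float)
    y = outcome_spec.apply(frame[outcome_spec.column].to_numpy())
    counts = frame["weight"].to_numpy(dtype=float) if weighted else np.ones(len(frame))
    if grid is None:
        grid = np.unique(values)
    else:
        grid = np.asarray(sorted(grid), dtype=float)
    if len(grid) == 0:
        raise ConfigError("candidate grid is empty")
    for cut in grid:
        exceed = values > cut
        if not exceed.any():
            continue
        exceptions = float(counts[exceed & (y == 0)].sum())
        if exceptions <= max_exceptions:
            return float(cut)
    raise ThresholdNotFoundError(
        f"no cutpoint in the grid leaves <= {max_exceptions} stable-increasing "
        f"area(s) above it with a non-empty exposed set"
    )


def sensitivity_sweep(records, base_cutpoint: float = 35.0,
                      half_range: float = 30.0, step: float = 5.0,
                      outcome_spec: ThresholdSpec = DEFAULT_OUTCOME_SPEC,
                      column: str = "agg_disturbance",
                      exposure_name: str | None = None) -> SweepResult:
    """Re-run the single-exposure attribution query across a cutpoint grid.

    The grid spans ``base_cutpoint`` plus/minus ``half_range`` in absolute
    percentage points with spacing ``step``.  Cutpoints where a
    conditioning set is empty yield rows with ``valid=False`` rather than
    being dropped, so the sweep always has one row per grid point.
    """
    if base_cutpoint - half_range <= 0:
        raise ConfigError("base_cutpoint - half_range must be positive")
    if step <= 0:
        raise ConfigError("step must be positive")
    frame = _as_frame(records)
    name = exposure_name or column
    n_steps = int(round(half_range / step))
    cuts = [base_cutpoint + step * k for k in range(-n_steps, n_steps + 1)]
    rows = []
    for cut in cuts:
        panel = binarize(frame, outcome_spec,
                         [ThresholdSpec(column, cut, "greater", strict=True)], [name])
        rows.append((float(cut), attribution_query(panel, [name], label=f"{column}>{cut:g}")))
    return SweepResult(rows)
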