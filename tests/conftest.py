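"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from causalattrib import BinaryPanel, StudyAreaRecord


@pytest.fixture
def four_unit_panel() -> BinaryPanel:
    """The hand-enumerable reference panel: p1 = 3/4, p0 = 1/2."""
    frame = pd.DataFrame({
        "unit_id": ["a", "b", "c", "d"],
        "X": [1, 1, 0, 0],
        "Y": [1, 0, 1, 0],
        "weight": [3, 1, 2, 2],
    })
    return BinaryPanel(frame, ["X"], "Y")


@pytest.fixture
def aggregate_quadrant_records() -> list[StudyAreaRecord]:
    """Four study areas whose quadrant weights give p1=0.848, p0=0.672.

    Built so binarizing at disturbance > 35% and recruitment < 29 lands
    848/152 weight in the exposed Y=1/Y=0 quadrants and 672/328 in the
    unexposed ones.
    """
    spec = [
        ("hiD_loR", 80.0, 10.0, 848),
        ("hiD_hiR", 80.0, 40.0, 152),
        ("loD_loR", 10.0, 10.0, 672),
        ("loD_hiR", 10.0, 40.0, 328),
    ]
    return [
        StudyAreaRecord(area_id=aid, jurisdiction="BC", recruitment=rec, weight=w,
                        agg_disturbance=dist, linear_density=0.1, cutblock_pct=5.0,
                        burned_pct=10.0, mean_evi=3000.0)
        for aid, dist, rec, w in spec
    ]


def random_panel(rng: np.random.Generator, n_units: int, columns: list[str],
                 max_weight: int = 5) -> BinaryPanel:
    """A random weighted binary panel over the given exposure columns + Y."""
    frame = pd.DataFrame({"unit_id": [f"u{i}" for i in range(n_units)]})
    for col in columns:
        frame[col] = rng.integers(0, 2, size=n_units)
    frame["Y"] = rng.integers(0, 2, size=n_units)
    frame["weight"] = rng.integers(1, max_weight + 1, size=n_units)
    return BinaryPanel(frame, columns, "Y")


def brute_force_conditional(panel: BinaryPanel, exposures: list[str], value: int,
                            stratum: dict | None = None) -> tuple[float, float] | None:
    """Oracle: weighted P(Y=1 | ...) by explicit unit-by-unit accumulation."""
    num = den = 0.0
    for _, row in panel.frame.iterrows():
        if any(row[e] != value for e in exposures):
            continue
        if stratum and any(row[k] != v for k, v in stratum.items()):
            continue
        den += row["weight"]
        if row[panel.outcome_name] == 1:
            num += row["weight"]
    if den == 0:
        return None
    return num / den, den


def brute_force_cmi(panel: BinaryPanel, factor: str, target: str,
                    given: list[str]) -> float:
    """Oracle: I(F;T|G) by direct summation over the full joint lattice."""
    cols = [factor, target, *given]
    total = float(panel.frame["weight"].sum())

    def p(assign: dict) -> float:
        mask = np.ones(len(panel.frame), dtype=bool)
        for k, v in assign.items():
            mask &= panel.frame[k].to_numpy() == v
        return float(panel.frame.loc[mask, "weight"].sum()) / total

    info = 0.0
    for values in itertools.product((0, 1), repeat=len(cols)):
        assign = dict(zip(cols, values))
        p_ftg = p(assign)
        if p_ftg == 0:
            continue
        g = {k: assign[k] for k in given}
        p_g = p(g) if given else 1.0
        p_fg = p({factor: assign[factor], **g})
        p_tg = p({target: assign[target], **g})
        info += p_ftg * math.log(p_ftg * p_g / (p_fg * p_tg))
    return max(info, 0.0)
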