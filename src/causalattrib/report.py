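"""Rounded, table-shaped rendering of attribution results.

All arithmetic upstream is full precision; rounding (half-up, as tables in
the applied literature print) happens only here.  Probabilities are
printed to 3 decimals and PN/PS/PNS as percentages to 1 decimal by
default; unidentified quantities render as ``NA``.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .estimators import CausalQueryResult

__all__ = ["round_half_up", "attribution_table", "write_attribution_table"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (0.53658 -> 53.7% at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt_prob(p: float | None, decimals: int = 3) -> str:
    return "NA" if p is None else f"{round_half_up(p, decimals):.{decimals}f}"


def _fmt_pct(p: float | None, decimals: int = 1) -> str:
    return "NA" if p is None else f"{round_half_up(100.0 * p, decimals):.{decimals}f}"


def _stratum_str(res: CausalQueryResult) -> str:
    if not res.stratum:
        return "None"
    return ", ".join(f"{k}={v}" for k, v in sorted(res.stratum.items()))


def attribution_table(results: Iterable[CausalQueryResult], decimals: int = 1) -> pd.DataFrame:
    """Render results as rows (model, conditioning, evidence, p1, p0, PN%, PS%, PNS%)."""
    rows = []
    for res in results:
        rows.append({
            "model": res.label or ", ".join(res.exposures),
            "conditioning": _stratum_str(res),
            "evidence": ", ".join(res.exposures),
            "p1": _fmt_prob(res.p1),
            "p0": _fmt_prob(res.p0),
            "PN%": _fmt_pct(res.pn, decimals),
            "PS%": _fmt_pct(res.ps, decimals),
            "PNS%": _fmt_pct(res.pns, decimals),
        })
    return pd.DataFrame(rows, columns=["model", "conditioning", "evidence",
                                       "p1", "p0", "PN%", "PS%", "PNS%"])


def write_attribution_table(results: Sequence[CausalQueryResult], path,
                            decimals: int = 1) -> Path:
    """Write the rendered attribution table to CSV and return the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    attribution_table(results, decimals).to_csv(path, index=False)
    return path
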