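"""Study-area tables, dichotomization rules, and the weighted binary panel.

A *study area* is one row of the input table: a caribou range with a mean
recruitment rate (calves per 100 adult females), the number of
observation-years behind that mean (the analysis weight), and continuous
habitat covariates (aggregate disturbance %, linear-feature density in
km/km^2, cutblock %, burned %, mean MODIS EVI on the integer-scaled
convention).

Dichotomization turns the continuous table into a :class:`BinaryPanel`:
the outcome Y = 1 codes "declining" (recruitment strictly below 29
calves:100 cows) and each exposure X_j = 1 codes "exposed" (covariate
strictly beyond its cutpoint).  All downstream probabilities are weighted
relative frequencies on this panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, ParseError, SchemaError

__all__ = [
    "REQUIRED_COLUMNS",
    "COVARIATE_COLUMNS",
    "DEFAULT_OUTCOME_SPEC",
    "StudyAreaRecord",
    "ThresholdSpec",
    "BinaryPanel",
    "ThresholdBinarizer",
    "read_study_table",
    "write_study_table",
    "records_to_frame",
    "frame_to_records",
    "binarize",
    "expand_weights",
]

#: Columns every study table must provide (before any user column mapping).
REQUIRED_COLUMNS = (
    "area_id",
    "jurisdiction",
    "recruitment",
    "weight",
    "agg_disturbance",
    "linear_density",
    "cutblock_pct",
    "burned_pct",
    "mean_evi",
)

#: The continuous covariates eligible as exposures.
COVARIATE_COLUMNS = (
    "agg_disturbance",
    "linear_density",
    "cutblock_pct",
    "burned_pct",
    "mean_evi",
)

_NUMERIC_COLUMNS = ("recruitment", "weight") + COVARIATE_COLUMNS
_PERCENT_COLUMNS = ("agg_disturbance", "cutblock_pct", "burned_pct")


@dataclass(frozen=True)
class StudyAreaRecord:
    """One study area with validated fields.

    Raises :class:`ValueError` on construction if an invariant is violated
    (negative recruitment, percent outside [0, 100], weight below one year,
    or a fractional weight).
    """

    area_id: str
    jurisdiction: str
    recruitment: float
    weight: int
    agg_disturbance: float
    linear_density: float
    cutblock_pct: float
    burned_pct: float
    mean_evi: float

    def __post_init__(self):
        if not isinstance(self.weight, (int, np.integer)):
            raise ValueError(
                f"weight must be an integer number of observation-years, got {self.weight!r}"
            )
        if self.weight < 1:
            raise ValueError(f"weight must be >= 1, got {self.weight}")
        for name in ("recruitment", "linear_density", "mean_evi"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        for name in _PERCENT_COLUMNS:
            v = getattr(self, name)
            if not math.isfinite(v) or not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percent in [0, 100], got {v}")


@dataclass(frozen=True)
class ThresholdSpec:
    """A dichotomization rule for one continuous column.

    ``direction`` names which side of ``cutpoint`` codes 1: ``"greater"``
    means values beyond the cutpoint are coded 1, ``"less"`` the reverse.
    With ``strict=True`` (the default) equality codes 0, matching the
    ">35%" / "<29 calves:100 cows" conventions.
    """

    column: str
    cutpoint: float
    direction: str = "greater"
    strict: bool = True

    def __post_init__(self):
        if self.direction not in ("greater", "less"):
            raise ConfigError(f"direction must be 'greater' or 'less', got {self.direction!r}")
        if not math.isfinite(self.cutpoint):
            raise ConfigError(f"cutpoint must be finite, got {self.cutpoint!r}")

    def apply(self, values) -> np.ndarray:
        """Binary-code an array of values under this rule."""
        v = np.asarray(values, dtype=float)
        if self.direction == "greater":
            hit = v > self.cutpoint if self.strict else v >= self.cutpoint
        else:
            hit = v < self.cutpoint if self.strict else v <= self.cutpoint
        return hit.astype(np.int64)

    def describe(self) -> str:
        op = {"greater": ">" if self.strict else ">=", "less": "<" if self.strict else "<="}
        return f"{self.column} {op[self.direction]} {self.cutpoint:g}"


#: Outcome rule used throughout: declining (Y=1) iff recruitment < 29.
DEFAULT_OUTCOME_SPEC = ThresholdSpec("recruitment", 29.0, direction="less", strict=True)


@dataclass
class BinaryPanel:
    """Weighted units with binary exposures and a binary outcome.

    ``frame`` holds one row per unit with columns ``unit_id``, one 0/1
    column per exposure, the outcome column, and an integer ``weight``.
    """

    frame: pd.DataFrame
    exposure_names: list[str] = field(default_factory=list)
    outcome_name: str = "Y"

    def __post_init__(self):
        cols = set(self.frame.columns)
        missing = [c for c in ["unit_id", "weight", self.outcome_name, *self.exposure_names] if c not in cols]
        if missing:
            raise SchemaError(f"panel frame missing columns: {missing}")
        if len(self.frame) and self.frame["weight"].sum() <= 0:
            raise ConfigError("total panel weight must be positive")

    @property
    def total_weight(self) -> float:
        return float(self.frame["weight"].sum())

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def binary_columns(self) -> list[str]:
        return [*self.exposure_names, self.outcome_name]

    def subset(self, index: np.ndarray) -> "BinaryPanel":
        """Row subset by boolean mask or positional integer indices."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return BinaryPanel(self.frame.iloc[index].reset_index(drop=True),
                           list(self.exposure_names), self.outcome_name)

    def to_csv(self, path) -> None:
        cols = ["unit_id", *self.exposure_names, self.outcome_name, "weight"]
        self.frame[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, outcome_name: str = "Y") -> "BinaryPanel":
        frame = pd.read_csv(path)
        exposures = [c for c in frame.columns if c not in ("unit_id", "weight", outcome_name)]
        return cls(frame, exposures, outcome_name)


def records_to_frame(records: Iterable[StudyAreaRecord]) -> pd.DataFrame:
    """Stack records into the canonical study-table DataFrame."""
    rows = [
        {c: getattr(r, c) for c in REQUIRED_COLUMNS}
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[StudyAreaRecord]:
    """Validate a study-table DataFrame row by row into records."""
    _check_columns(frame)
    out = []
    for i, row in frame.iterrows():
        out.append(
            StudyAreaRecord(
                area_id=str(row["area_id"]),
                jurisdiction=str(row["jurisdiction"]),
                recruitment=float(row["recruitment"]),
                weight=int(row["weight"]),
                agg_disturbance=float(row["agg_disturbance"]),
                linear_density=float(row["linear_density"]),
                cutblock_pct=float(row["cutblock_pct"]),
                burned_pct=float(row["burned_pct"]),
                mean_evi=float(row["mean_evi"]),
            )
        )
    return out


def _check_columns(frame: pd.DataFrame, columns: Sequence[str] = REQUIRED_COLUMNS) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"study table missing required column(s): {', '.join(missing)}")


def read_study_table(path, column_map: dict[str, str] | None = None) -> list[StudyAreaRecord]:
    """Read a study-area CSV into validated records.

    Parameters
    ----------
    path
        CSV file with a header; comma-separated, '.' decimal.
    column_map
        Optional mapping from the canonical column names to the names used
        in the file, e.g. ``{"recruitment": "calves_per_100_cows"}``.

    Rows with an empty required cell are dropped with a row-indexed
    warning (no imputation).  A wholly missing column raises
    :class:`SchemaError`; an uninterpretable cell raises :class:`ParseError`
    naming the row and column.  Fractional weights are rejected: the weight
    is a count of observation-years.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    _check_columns(raw)

    records: list[StudyAreaRecord] = []
    dropped: list[int] = []
    for i, row in raw.iterrows():
        if any(pd.isna(row[c]) for c in REQUIRED_COLUMNS):
            dropped.append(int(i))
            continue
        values: dict[str, object] = {
            "area_id": str(row["area_id"]),
            "jurisdiction": str(row["jurisdiction"]),
        }
        for col in _NUMERIC_COLUMNS:
            cell = row[col]
            try:
                num = float(cell)
            except (TypeError, ValueError):
                raise ParseError(f"row {i}, column {col!r}: cannot parse {cell!r} as a number")
            if col == "weight":
                if not float(num).is_integer():
                    raise ParseError(
                        f"row {i}, column 'weight': {cell!r} is not an integer number "
                        "of observation-years"
                    )
                values[col] = int(num)
            else:
                values[col] = num
        try:
            records.append(StudyAreaRecord(**values))  # type: ignore[arg-type]
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} row(s) with missing required values: rows {dropped}",
            stacklevel=2,
        )
    return records


def write_study_table(records: Iterable[StudyAreaRecord] | pd.DataFrame, path) -> None:
    """Write records (or a study-table frame) back to CSV, round-trip safe."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


class ThresholdBinarizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: continuous study table -> weighted binary panel.

    Parameters
    ----------
    outcome_spec
        Rule coding the outcome; defaults to declining = recruitment < 29.
    exposure_specs
        One rule per exposure.  Exposure names default to the column names;
        duplicates raise :class:`ConfigError`.
    exposure_names
        Optional override names, aligned with ``exposure_specs``.
    """

    def __init__(self, outcome_spec: ThresholdSpec = DEFAULT_OUTCOME_SPEC,
                 exposure_specs: Sequence[ThresholdSpec] = (),
                 exposure_names: Sequence[str] | None = None,
                 outcome_name: str = "Y"):
        self.outcome_spec = outcome_spec
        self.exposure_specs = list(exposure_specs)
        self.exposure_names = list(exposure_names) if exposure_names is not None else None
        self.outcome_name = outcome_name

    def fit(self, X=None, y=None):  # stateless; present for pipeline compatibility
        return self

    def transform(self, X) -> BinaryPanel:
        frame = X if isinstance(X, pd.DataFrame) else records_to_frame(X)
        names = self.exposure_names or [s.column for s in self.exposure_specs]
        if len(names) != len(self.exposure_specs):
            raise ConfigError("exposure_names must align with exposure_specs")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate exposure name(s): {dupes}")
        needed = {self.outcome_spec.column, *(s.column for s in self.exposure_specs)}
        missing = sorted(needed - set(frame.columns))
        if missing:
            raise SchemaError(f"threshold specs reference missing column(s): {missing}")
        out = pd.DataFrame({"unit_id": frame["area_id"].astype(str).to_numpy()
                            if "area_id" in frame.columns
                            else np.arange(len(frame)).astype(str)})
        for name, spec in zip(names, self.exposure_specs):
            out[name] = spec.apply(frame[spec.column].to_numpy())
        out[self.outcome_name] = self.outcome_spec.apply(frame[self.outcome_spec.column].to_numpy())
        out["weight"] = frame["weight"].to_numpy().astype(np.int64) if "weight" in frame.columns \
            else np.ones(len(frame), dtype=np.int64)
        return BinaryPanel(out, list(names), self.outcome_name)


def binarize(records, outcome_spec: ThresholdSpec = DEFAULT_OUTCOME_SPEC,
             exposure_specs: Sequence[ThresholdSpec] = (),
             exposure_names: Sequence[str] | None = None) -> BinaryPanel:
    """Dichotomize a study table into a weighted binary panel.

    Thin wrapper over :class:`ThresholdBinarizer`.  Total weight is
    conserved: the panel's weights are the records' weights unchanged.
    """
    return ThresholdBinarizer(outcome_spec, exposure_specs, exposure_names).transform(records)


def expand_weights(panel: BinaryPanel) -> BinaryPanel:
    """Replicate each unit ``weight`` times with weight 1.

    Total weight is preserved exactly; estimation on the expanded panel
    must match the weighted panel (used as an equivalence oracle).
    """
    w = panel.frame["weight"].to_numpy()
    idx = np.repeat(np.arange(len(panel.frame)), w)
    frame = panel.frame.iloc[idx].reset_index(drop=True).copy()
    frame["weight"] = 1
    return BinaryPanel(frame, list(panel.exposure_names), panel.outcome_name)
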