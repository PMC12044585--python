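"""End-to-end attribution pipeline: table -> binary panel -> network -> report.

The run order mirrors the analysis procedure: read (or simulate) the
study-area table, dichotomize, fit the hypothesized causal network as
weighted-frequency CPTs, refuse any query whose exposures are not
exogenous, prune unsupported parents of the outcome by lowest conditional
mutual information, answer the attribution queries, and optionally sweep
the aggregate-disturbance cutpoint.  Every artifact needed to audit a run
(CPTs, quadrant weights behind each p1/p0, pruning events, versions, seed)
is written alongside the attribution table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import CausalAttribError, ConfigError, PipelineError, UndefinedProbabilityError
from .estimators import CausalQueryResult, attribution_query
from .network import (
    check_exogeneity,
    cpts_to_frame,
    fit_cpts,
    make_dag,
    prune_parents,
    query_marginal,
)
from .panel import (
    DEFAULT_OUTCOME_SPEC,
    BinaryPanel,
    ThresholdSpec,
    binarize,
    read_study_table,
    records_to_frame,
)
from .report import write_attribution_table
from .simulate import default_config, simulate_panel
from .thresholds import sensitivity_sweep

log = logging.getLogger("causalattrib")

__all__ = ["QuerySpec", "PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class QuerySpec:
    exposures: tuple[str, ...]
    stratum: Mapping[str, int] | None = None
    label: str = ""


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run (loadable from YAML)."""

    input: str | None = None
    simulate: Mapping | None = None
    outcome: ThresholdSpec = DEFAULT_OUTCOME_SPEC
    exposures: Sequence[ThresholdSpec] = ()
    exposure_names: Sequence[str] | None = None
    dag_arcs: Sequence[tuple[str, str]] = ()
    queries: Sequence[QuerySpec] = ()
    sweep: Mapping | None = None
    outdir: str = "causalattrib_out"
    seed: int = 0
    decimals: int = 1
    column_map: Mapping[str, str] | None = None

    def __post_init__(self):
        if not self.queries and not self.sweep:
            raise ConfigError("config must define at least one query or a sweep")
        if self.input is None and self.simulate is None:
            raise ConfigError("config must give an input path or a simulate block")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        def spec(d: Mapping) -> ThresholdSpec:
            return ThresholdSpec(d["column"], float(d["cutpoint"]),
                                 d.get("direction", "greater"), d.get("strict", True))

        outcome = spec(raw["outcome"]) if "outcome" in raw else DEFAULT_OUTCOME_SPEC
        exposures = [spec(d) for d in raw.get("exposures", [])]
        names = [d.get("name", d["column"]) for d in raw.get("exposures", [])]
        queries = [
            QuerySpec(tuple(q["exposures"]),
                      {k: int(v) for k, v in q.get("stratum", {}).items()} or None,
                      q.get("label", ""))
            for q in raw.get("queries", [])
        ]
        arcs = [tuple(arc) for arc in raw.get("dag", {}).get("arcs", [])]
        return cls(
            input=raw.get("input"), simulate=raw.get("simulate"),
            outcome=outcome, exposures=exposures, exposure_names=names,
            dag_arcs=arcs, queries=queries, sweep=raw.get("sweep"),
            outdir=raw.get("outdir", "causalattrib_out"),
            seed=int(raw.get("seed", 0)), decimals=int(raw.get("decimals", 1)),
            column_map=raw.get("column_map"),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_records(config: PipelineConfig) -> pd.DataFrame:
    if config.input is not None:
        return records_to_frame(read_study_table(config.input, config.column_map))
    sim = dict(config.simulate or {})
    sim.setdefault("seed", config.seed)
    return simulate_panel(default_config(**sim))


def _quadrant_weights(panel: BinaryPanel, query: QuerySpec) -> dict:
    """Weighted counts of the four exposure/outcome quadrants behind a query."""
    out = {}
    frame = panel.frame
    mask = np.ones(len(frame), dtype=bool)
    for k, v in (query.stratum or {}).items():
        mask &= panel.column(k) == v
    for xval in (0, 1):
        xmask = mask.copy()
        for name in query.exposures:
            xmask &= panel.column(name) == xval
        for yval in (0, 1):
            w = frame.loc[xmask & (panel.column(panel.outcome_name) == yval), "weight"].sum()
            out[f"X={xval},Y={yval}"] = float(w)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured run; returns and writes the report bundle.

    Raises :class:`PipelineError` (naming the failing stage) on any error;
    in particular a query over a non-exogenous exposure aborts the run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"version": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__,
                     "networkx": nx.__version__,
                     "seed": config.seed, "events": []}

    try:
        frame = _load_records(config)
    except CausalAttribError as exc:
        raise PipelineError("load", str(exc)) from exc
    frame.to_csv(outdir / "panel_input.csv", index=False)

    try:
        panel = binarize(frame, config.outcome, config.exposures, config.exposure_names)
    except CausalAttribError as exc:
        raise PipelineError("binarize", str(exc)) from exc

    cpts = None
    dag = None
    if config.dag_arcs:
        try:
            nodes = dict.fromkeys([n for arc in config.dag_arcs for n in arc])
            dag = make_dag(nodes, config.dag_arcs)
            cpts = fit_cpts(dag, panel)
        except CausalAttribError as exc:
            raise PipelineError("fit_cpts", str(exc)) from exc

        for query in config.queries:
            if not check_exogeneity(dag, query.exposures):
                raise PipelineError(
                    "exogeneity",
                    f"exposure(s) {list(query.exposures)} have incoming arcs; "
                    "probabilities of causation are not identified",
                )

        outcome_node = panel.outcome_name
        if outcome_node in dag.nodes and dag.in_degree(outcome_node) >= 1:
            try:
                dag, removals = prune_parents(dag, panel, outcome_node)
            except CausalAttribError as exc:
                raise PipelineError("prune", str(exc)) from exc
            for parent, cmi in removals:
                run_log["events"].append(
                    {"stage": "prune", "removed": parent, "cmi_nats": cmi})
                log.info("pruned arc %s -> %s (CMI %.6f nats)", parent, outcome_node, cmi)
            cpts = fit_cpts(dag, panel)
        cpts_to_frame(cpts).to_csv(outdir / "cpts.csv", index=False)

    results: list[CausalQueryResult] = []
    for query in config.queries:
        res = attribution_query(panel, query.exposures, query.stratum, query.label)
        quadrants = _quadrant_weights(panel, query)
        event = {"stage": "query", "label": query.label or ",".join(query.exposures),
                 "quadrant_weights": quadrants}
        if dag is not None and cpts is not None:
            # network route: evidence on the exposures (and stratum), read the outcome
            try:
                evidence = {e: 1 for e in query.exposures}
                evidence.update(query.stratum or {})
                event["network_p1"] = query_marginal(dag, cpts, evidence, panel.outcome_name)
                evidence = {e: 0 for e in query.exposures}
                evidence.update(query.stratum or {})
                event["network_p0"] = query_marginal(dag, cpts, evidence, panel.outcome_name)
            except (UndefinedProbabilityError, ConfigError) as exc:
                event["network_query"] = f"undefined: {exc}"
        run_log["events"].append(event)
        results.append(res)

    write_attribution_table(results, outdir / "attribution.csv", config.decimals)

    sweep_result = None
    if config.sweep:
        s = dict(config.sweep)
        try:
            sweep_result = sensitivity_sweep(
                frame,
                base_cutpoint=float(s.get("base", 35.0)),
                half_range=float(s.get("half_range", 30.0)),
                step=float(s.get("step", 5.0)),
                outcome_spec=config.outcome,
                column=s.get("column", "agg_disturbance"),
            )
        except CausalAttribError as exc:
            raise PipelineError("sweep", str(exc)) from exc
        sweep_result.to_frame().to_csv(outdir / "sweep.csv", index=False)

    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    return {"panel": panel, "results": results, "sweep": sweep_result,
            "cpts": cpts, "dag": dag, "run_log": run_log, "outdir": outdir}
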