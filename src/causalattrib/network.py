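"""Discrete structural-causal-model machinery over binary panels.

The causal hypotheses handled here are tiny DAGs (at most a handful of
binary nodes) whose conditional probability tables (CPTs) are weighted
relative frequencies from the panel — point frequencies with no priors or
pseudo-counts, so quadrant proportions are reproduced exactly.  Queries
set evidence on exposures and read off the outcome probability by exact
summation; no approximate propagation is needed at this scale.

The pruning rule mirrors a common model-reduction step: a parent whose
joint configurations with the other parents are never observed leaves
empty CPT cells; the parent with the lowest conditional mutual information
with the child (given the remaining parents) is dropped first, repeatedly,
until the CPT is fully supported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigError, UndefinedProbabilityError
from .panel import BinaryPanel

__all__ = [
    "Cpt",
    "DiscreteBayesNetwork",
    "make_dag",
    "read_edgelist",
    "write_edgelist",
    "fit_cpts",
    "query_marginal",
    "conditional_mutual_information",
    "prune_parents",
    "check_exogeneity",
    "cpts_to_frame",
]


def make_dag(nodes: Iterable[str], arcs: Iterable[tuple[str, str]]) -> nx.DiGraph:
    """Build a validated DAG from node names and (parent, child) arcs."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for parent, child in arcs:
        if parent not in g or child not in g:
            raise ConfigError(f"arc ({parent!r}, {child!r}) references an unknown node")
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ConfigError("graph contains a directed cycle")
    return g


def read_edgelist(path) -> nx.DiGraph:
    """Read a DAG from 'parent<TAB>child' lines (isolated nodes: a bare name)."""
    nodes, arcs = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                nodes.append(parts[0])
            else:
                nodes.extend(parts[:2])
                arcs.append((parts[0], parts[1]))
    return make_dag(dict.fromkeys(nodes), arcs)


def write_edgelist(dag: nx.DiGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for parent, child in sorted(dag.edges):
            fh.write(f"{parent}\t{child}\n")
        for node in sorted(n for n in dag.nodes if dag.degree(n) == 0):
            fh.write(f"{node}\n")


@dataclass
class Cpt:
    """Conditional probability table of ``child`` = 1 per parent configuration.

    ``table`` maps each configuration in {0,1}^|parents| to P(child=1 |
    configuration), or ``None`` where the panel carries no weight for that
    configuration (an *empty cell*); ``support`` holds the observed weight.
    """

    child: str
    parents: tuple[str, ...]
    table: dict[tuple[int, ...], float | None]
    support: dict[tuple[int, ...], float]

    def empty_cells(self) -> list[tuple[int, ...]]:
        return [cfg for cfg, p in self.table.items() if p is None]


def _weighted_counts(panel: BinaryPanel, columns: Sequence[str]) -> dict[tuple[int, ...], float]:
    w = panel.column("weight").astype(float)
    if not columns:
        return {(): float(w.sum())}
    keys = np.stack([panel.column(c) for c in columns], axis=1)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    sums = np.bincount(inverse, weights=w)
    return {tuple(int(v) for v in cfg): float(s) for cfg, s in zip(uniq, sums)}


def fit_cpts(dag: nx.DiGraph, panel: BinaryPanel) -> dict[str, Cpt]:
    """Weighted-frequency CPT for every node (marginal frequency for roots).

    Each cell is the weighted relative frequency of child = 1 given the
    parent configuration; configurations never observed are flagged empty
    (probability ``None``, support 0).
    """
    missing = [n for n in dag.nodes if n not in panel.frame.columns]
    if missing:
        raise ConfigError(f"dag node(s) absent from the panel: {missing}")
    cpts: dict[str, Cpt] = {}
    for node in dag.nodes:
        parents = tuple(sorted(dag.predecessors(node)))
        joint = _weighted_counts(panel, [*parents, node])
        table: dict[tuple[int, ...], float | None] = {}
        support: dict[tuple[int, ...], float] = {}
        for cfg in itertools.product((0, 1), repeat=len(parents)):
            w1 = joint.get((*cfg, 1), 0.0)
            w_all = w1 + joint.get((*cfg, 0), 0.0)
            support[cfg] = w_all
            table[cfg] = (w1 / w_all) if w_all > 0 else None
        cpts[node] = Cpt(node, parents, table, support)
    return cpts


def query_marginal(dag: nx.DiGraph, cpts: Mapping[str, Cpt],
                   evidence: Mapping[str, int], target: str) -> float:
    """P(target = 1 | evidence) by exact summation over unassigned nodes.

    Raises :class:`UndefinedProbabilityError` if an empty CPT cell is
    reachable with positive probability given the evidence, and
    :class:`ConfigError` for unknown variables or evidence on the target.
    """
    for var in (*evidence, target):
        if var not in dag.nodes:
            raise ConfigError(f"unknown network variable {var!r}")
        if var not in cpts:
            raise ConfigError(f"no CPT fitted for {var!r}")
    if target in evidence:
        raise ConfigError(f"target {target!r} is already assigned as evidence")
    for var, val in evidence.items():
        if val not in (0, 1):
            raise ConfigError(f"evidence for {var!r} must be 0 or 1, got {val!r}")

    free = [n for n in dag.nodes if n not in evidence and n != target]
    weight = {1: 0.0, 0: 0.0}
    for assignment in itertools.product((0, 1), repeat=len(free)):
        state = dict(evidence)
        state.update(zip(free, assignment))
        for tval in (0, 1):
            state[target] = tval
            factors = []
            has_empty = False
            for node in dag.nodes:
                cpt = cpts[node]
                cfg = tuple(state[p] for p in cpt.parents)
                p1 = cpt.table[cfg]
                if p1 is None:
                    has_empty = True
                    continue
                factors.append(p1 if state[node] == 1 else 1.0 - p1)
            prod = math.prod(factors)
            if has_empty:
                if prod != 0.0:
                    raise UndefinedProbabilityError(
                        "query reaches an unsupported CPT configuration"
                    )
                continue
            weight[tval] += prod
    total = weight[0] + weight[1]
    if total <= 0:
        raise UndefinedProbabilityError("evidence has zero probability under the fitted network")
    return weight[1] / total


def conditional_mutual_information(panel: BinaryPanel, factor: str, target: str,
                                   given: Iterable[str] = ()) -> float:
    """I(factor; target | given) in nats from weighted empirical frequencies.

    Terms with zero probability contribute zero; the result is floored at
    zero to absorb floating-point round-off.
    """
    given = tuple(given)
    if factor == target:
        raise ConfigError("factor and target must be distinct variables")
    for var in (factor, target, *given):
        if var not in panel.frame.columns:
            raise ConfigError(f"unknown panel variable {var!r}")
    if len(panel.frame) == 0:
        raise ConfigError("empty panel")

    total = panel.total_weight
    joint = _weighted_counts(panel, [factor, target, *given])
    # marginalize once; configurations are tiny so dict passes are fine
    def marg(keep: tuple[int, ...]) -> dict[tuple[int, ...], float]:
        out: dict[tuple[int, ...], float] = {}
        for cfg, w in joint.items():
            key = tuple(cfg[i] for i in keep)
            out[key] = out.get(key, 0.0) + w
        return out

    idx_g = tuple(range(2, 2 + len(given)))
    p_fg = marg((0, *idx_g))
    p_tg = marg((1, *idx_g))
    p_g = marg(idx_g)

    info = 0.0
    for cfg, w in joint.items():
        if w <= 0:
            continue
        f, t, g = cfg[0], cfg[1], cfg[2:]
        p_ftg = w / total
        num = p_ftg * (p_g[g] / total)
        den = (p_fg[(f, *g)] / total) * (p_tg[(t, *g)] / total)
        info += p_ftg * math.log(num / den)
    return max(info, 0.0)


def prune_parents(dag: nx.DiGraph, panel: BinaryPanel, child: str
                  ) -> tuple[nx.DiGraph, list[tuple[str, float]]]:
    """Drop low-information parents of ``child`` until its CPT has no empty cells.

    While the child's CPT has at least one unsupported configuration and at
    least two parents remain, the parent with the lowest conditional mutual
    information with the child given the other remaining parents is removed
    (ties broken lexicographically by name).  Returns the pruned DAG and a
    removal log of ``(parent, cmi)`` pairs.  The last parent is never
    removed.
    """
    if child not in dag.nodes:
        raise ConfigError(f"unknown node {child!r}")
    parents = sorted(dag.predecessors(child))
    if not parents:
        raise ConfigError(f"{child!r} has no parents to prune")
    pruned = dag.copy()
    removals: list[tuple[str, float]] = []
    while True:
        parents = sorted(pruned.predecessors(child))
        sub = make_dag([child, *parents], [(p, child) for p in parents])
        cpt = fit_cpts(sub, panel)[child]
        if not cpt.empty_cells() or len(parents) < 2:
            break
        scored = [
            (conditional_mutual_information(panel, p, child,
                                            [q for q in parents if q != p]), p)
            for p in parents
        ]
        cmi, victim = min(scored, key=lambda t: (t[0], t[1]))
        pruned.remove_edge(victim, child)
        removals.append((victim, cmi))
    return pruned, removals


def check_exogeneity(dag: nx.DiGraph, exposures: Iterable[str]) -> bool:
    """True iff every exposure has no incoming arcs (in-degree zero)."""
    exposures = list(exposures)
    unknown = [x for x in exposures if x not in dag.nodes]
    if unknown:
        raise ConfigError(f"exposure(s) not in the dag: {unknown}")
    return all(dag.in_degree(x) == 0 for x in exposures)


def cpts_to_frame(cpts: Mapping[str, Cpt]) -> pd.DataFrame:
    """Flatten CPTs for CSV export: child, parents, configuration, probability, support."""
    rows = []
    for child in sorted(cpts):
        cpt = cpts[child]
        for cfg in sorted(cpt.table):
            rows.append({
                "child": child,
                "parents": ",".join(cpt.parents),
                "configuration": ",".join(map(str, cfg)),
                "probability": cpt.table[cfg],
                "support": cpt.support[cfg],
            })
    return pd.DataFrame(rows, columns=["child", "parents", "configuration", "probability", "support"])


class DiscreteBayesNetwork(BaseEstimator):
    """Sklearn-style wrapper: fit weighted-frequency CPTs on a DAG, then query.

    Parameters
    ----------
    arcs : iterable of (parent, child)
    nodes : optional iterable of node names (for isolated nodes)

    Attributes (after :meth:`fit`)
    ------------------------------
    dag_ : networkx.DiGraph
    cpts_ : dict mapping node -> Cpt
    pruning_log_ : list of (parent, cmi) removals performed by :meth:`prune`
    """

    def __init__(self, arcs: Sequence[tuple[str, str]] = (), nodes: Sequence[str] = ()):
        self.arcs = list(arcs)
        self.nodes = list(nodes)

    def fit(self, X: BinaryPanel, y=None):
        nodes = list(dict.fromkeys([*self.nodes, *(n for arc in self.arcs for n in arc)]))
        self.dag_ = make_dag(nodes, self.arcs)
        self.cpts_ = fit_cpts(self.dag_, X)
        self.panel_ = X
        self.pruning_log_ = []
        return self

    def query(self, evidence: Mapping[str, int], target: str) -> float:
        return query_marginal(self.dag_, self.cpts_, evidence, target)

    def prune(self, child: str) -> "DiscreteBayesNetwork":
        self.dag_, log = prune_parents(self.dag_, self.panel_, child)
        self.pruning_log_.extend(log)
        self.cpts_ = fit_cpts(self.dag_, self.panel_)
        return self

    def exogenous(self, exposures: Iterable[str]) -> bool:
        return check_exogeneity(self.dag_, exposures)
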