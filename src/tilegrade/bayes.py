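"""Boolean Bayesian causal network for Tile AO/OTA grading.

The expert-structured graph links patient age (dichotomised at 60 years,
reflecting bone fragility) to rotational (R) and translational (T)
instability, and each instability to the seven fracture-type nodes.  The
generative orientation R,T -> fracture keeps every conditional probability
table small enough to fit from a few hundred patients, and makes observed
fractures informative about one another through their common causes — the
property the retrieval algorithm relies on.

The Tile grade itself is a deterministic label of (R, T): A when both are
stable, B for isolated rotational instability, C whenever translational
instability is present.  Evaluation therefore operates on P(R=1|e) and
P(T=1|e) directly.

Exact inference is sum-product variable elimination over boolean factors;
tests check it against full joint enumeration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .records import FRACTURE_TYPES

AGE_NODE = "age60"
R_NODE = "R"
T_NODE = "T"
FRACTURE_NODES: tuple[str, ...] = tuple(t.value for t in FRACTURE_TYPES)


class ZeroProbabilityEvidence(ValueError):
    """Raised when the supplied evidence has probability zero under the model."""


class TileGrade(enum.Enum):
    A = "A"
    B = "B"
    C = "C"


def tile_from_instability(R: bool, T: bool) -> TileGrade:
    """Map the two component instabilities to the first-order Tile grade.

    (stable, stable) -> A; rotational only -> B; any translational
    instability -> C (translational instability is the hallmark of global
    instability, so the textually undefined R=0,T=1 combination grades C).
    """
    if T:
        return TileGrade.C
    return TileGrade.B if R else TileGrade.A


def age_flag(age_years: int) -> bool:
    """Dichotomise age: below 60 years -> 0, 60 or older -> 1."""
    if age_years < 0:
        raise ValueError(f"negative age {age_years}")
    return age_years >= 60


@dataclass(frozen=True)
class NetworkSpec:
    """A directed acyclic graph over named boolean nodes."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network structure contains a cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents in canonical (node-order) sequence."""
        ps = {u for u, v in self.edges if v == node}
        return tuple(n for n in self.nodes if n in ps)

    def topological_order(self) -> tuple[str, ...]:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        # stable: break ties by canonical node order
        order_idx = {n: i for i, n in enumerate(self.nodes)}
        return tuple(nx.lexicographical_topological_sort(g, key=lambda n: order_idx[n]))


def default_structure(include_age: bool = True) -> NetworkSpec:
    """The expert causal graph: age -> {R, T}; R -> fx and T -> fx for all 7.

    ``include_age=False`` yields the age-blind variant (age node and its
    edges removed) with no other change.
    """
    nodes: list[str] = []
    edges: set[tuple[str, str]] = set()
    if include_age:
        nodes.append(AGE_NODE)
        edges |= {(AGE_NODE, R_NODE), (AGE_NODE, T_NODE)}
    nodes += [R_NODE, T_NODE, *FRACTURE_NODES]
    for fx in FRACTURE_NODES:
        edges |= {(R_NODE, fx), (T_NODE, fx)}
    return NetworkSpec(tuple(nodes), frozenset(edges))


@dataclass(frozen=True)
class CPDTable:
    """P(node = 1 | parent configuration) for every configuration.

    ``p1`` has one axis of length 2 per parent, in ``parents`` order; a
    root node has a 0-d array.
    """

    node: str
    parents: tuple[str, ...]
    p1: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.p1, dtype=float)
        if arr.shape != (2,) * len(self.parents):
            raise ValueError(
                f"CPD for {self.node}: expected shape {(2,) * len(self.parents)}, got {arr.shape}"
            )
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"CPD for {self.node}: probabilities outside [0, 1]")
        object.__setattr__(self, "p1", arr)

    def prob(self, value: bool, parent_values: Mapping[str, bool]) -> float:
        idx = tuple(int(parent_values[p]) for p in self.parents)
        p = float(self.p1[idx]) if self.parents else float(self.p1)
        return p if value else 1.0 - p


CPDSet = dict[str, CPDTable]


def fit_cpds(
    spec: NetworkSpec, data: pd.DataFrame, pseudocount: float = 1.0
) -> CPDSet:
    """Bayesian (Laplace-smoothed) CPD estimation from a boolean table.

    P(node=1 | config) = (n1 + a) / (n1 + n0 + 2a); parent configurations
    never observed get 0.5.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    missing = [n for n in spec.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"data table lacks columns for nodes: {missing}")
    a = float(pseudocount)
    cpds: CPDSet = {}
    for node in spec.nodes:
        parents = spec.parents(node)
        shape = (2,) * len(parents)
        p1 = np.full(shape, 0.5)
        vals = data[node].astype(int).to_numpy()
        if parents:
            pvals = data[list(parents)].astype(int).to_numpy()
            for idx in np.ndindex(*shape):
                mask = np.all(pvals == np.array(idx), axis=1)
                n = int(mask.sum())
                n1 = int(vals[mask].sum())
                if n + 2 * a > 0:
                    p1[idx] = (n1 + a) / (n + 2 * a)
        else:
            n = len(vals)
            n1 = int(vals.sum())
            if n + 2 * a > 0:
                p1 = np.array((n1 + a) / (n + 2 * a))
            else:
                p1 = np.array(0.5)
        cpds[node] = CPDTable(node, parents, np.asarray(p1))
    return cpds


# ---------------------------------------------------------------------------
# Exact inference: sum-product variable elimination over boolean factors


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple[str, ...], table: np.ndarray) -> None:
        self.vars = vars
        self.table = table

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self.table.reshape(self.table.shape + (1,) * (len(out_vars) - len(self.vars)))
        # align other's axes to out_vars
        b_shape = tuple(2 if v in other.vars else 1 for v in out_vars)
        src_axes = [other.vars.index(v) for v in out_vars if v in other.vars]
        b = np.transpose(other.table, src_axes).reshape(b_shape)
        return _Factor(out_vars, a * b)

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        new_vars = self.vars[:axis] + self.vars[axis + 1 :]
        return _Factor(new_vars, self.table.sum(axis=axis))


def _cpd_factor(cpd: CPDTable, evidence: Mapping[str, bool]) -> _Factor:
    vars = (cpd.node,) + cpd.parents
    p1 = np.asarray(cpd.p1, dtype=float)
    table = np.stack([1.0 - p1, p1], axis=0)  # axis 0: node value
    # condition on evidence by slicing observed axes to length 1... simpler:
    keep_vars = []
    for i, v in enumerate(vars):
        if v in evidence:
            table = np.take(table, int(evidence[v]), axis=len(keep_vars))
        else:
            keep_vars.append(v)
    return _Factor(tuple(keep_vars), np.asarray(table, dtype=float))


class Inference:
    """Exact posterior queries on one (spec, cpds) pair, with memoisation.

    Memoisation matters in cohort evaluation, where many patients share a
    fracture pattern and the refinement loop repeats similar queries.
    """

    def __init__(self, spec: NetworkSpec, cpds: CPDSet) -> None:
        missing = [n for n in spec.nodes if n not in cpds]
        if missing:
            raise ValueError(f"missing CPDs for nodes: {missing}")
        self.spec = spec
        self.cpds = cpds
        self._cache: dict[tuple, float] = {}

    def marginal(self, evidence: Mapping[str, bool], query: str) -> float:
        """P(query = 1 | evidence), by variable elimination."""
        if query not in self.spec.nodes:
            raise ValueError(f"unknown query node {query!r}")
        if query in evidence:
            raise ValueError(f"query node {query!r} is in the evidence")
        for k in evidence:
            if k not in self.spec.nodes:
                raise ValueError(f"evidence names unknown node {k!r}")
        key = (query, tuple(sorted((k, bool(v)) for k, v in evidence.items())))
        if key in self._cache:
            return self._cache[key]

        factors = [_cpd_factor(self.cpds[n], evidence) for n in self.spec.nodes]
        hidden = [n for n in self.spec.nodes if n != query and n not in evidence]
        # greedy min-degree elimination ordering
        while hidden:
            var = min(
                hidden,
                key=lambda v: (
                    len({u for f in factors if v in f.vars for u in f.vars}) ,
                    self.spec.nodes.index(v),
                ),
            )
            hidden.remove(var)
            related = [f for f in factors if var in f.vars]
            factors = [f for f in factors if var not in f.vars]
            prod = related[0]
            for f in related[1:]:
                prod = prod.multiply(f)
            factors.append(prod.sum_out(var))

        result = _Factor((), np.array(1.0))
        for f in factors:
            result = result.multiply(f)
        if result.vars != (query,):
            # factors with no remaining vars already folded in; ensure query axis
            raise AssertionError("elimination left unexpected variables")
        unnorm = result.table
        total = float(unnorm.sum())
        if total <= 0.0:
            raise ZeroProbabilityEvidence(
                f"evidence {dict(evidence)} has probability zero under the model"
            )
        p = float(unnorm[1] / total)
        self._cache[key] = p
        return p


def marginal(
    spec: NetworkSpec, cpds: CPDSet, evidence: Mapping[str, bool], query: str
) -> float:
    """One-shot exact posterior P(query=1 | evidence)."""
    return Inference(spec, cpds).marginal(evidence, query)


def joint_probability(
    spec: NetworkSpec, cpds: CPDSet, assignment: Mapping[str, bool]
) -> float:
    """P(full assignment) under the factorisation; all nodes must be set."""
    p = 1.0
    for node in spec.nodes:
        cpd = cpds[node]
        p *= cpd.prob(assignment[node], {q: assignment[q] for q in cpd.parents})
    return p


# ---------------------------------------------------------------------------
# Human-auditable serialization


def model_to_dict(spec: NetworkSpec, cpds: CPDSet) -> dict:
    out = {
        "schema_version": 1,
        "nodes": list(spec.nodes),
        "edges": sorted([list(e) for e in spec.edges]),
        "cpds": {},
    }
    for node in spec.nodes:
        cpd = cpds[node]
        table = {}
        for idx in np.ndindex(*cpd.p1.shape) if cpd.parents else [()]:
            key = ",".join(f"{p}={v}" for p, v in zip(cpd.parents, idx)) or "(root)"
            val = float(cpd.p1[idx]) if cpd.parents else float(cpd.p1)
            table[key] = round(val, 10)
        out["cpds"][node] = {"parents": list(cpd.parents), "p_node_is_1": table}
    return out


def save_model(spec: NetworkSpec, cpds: CPDSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(spec, cpds), fh, sort_keys=False)


def load_model(path: str | Path) -> tuple[NetworkSpec, CPDSet]:
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    spec = NetworkSpec(tuple(obj["nodes"]), frozenset(tuple(e) for e in obj["edges"]))
    cpds: CPDSet = {}
    for node, entry in obj["cpds"].items():
        parents = tuple(entry["parents"])
        shape = (2,) * len(parents)
        p1 = np.zeros(shape) if parents else np.array(0.0)
        for key, val in entry["p_node_is_1"].items():
            if key == "(root)":
                p1 = np.array(float(val))
            else:
                idx = tuple(int(part.split("=")[1]) for part in key.split(","))
                p1[idx] = float(val)
        cpds[node] = CPDTable(node, parents, p1)
    return spec, cpds
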