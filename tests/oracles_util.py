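"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately avoids the code paths under test: marginals by
full joint enumeration, fusion components by all-pairs transitive closure,
MIP by per-slab python max, AUC by pair counting.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np

from tilegrade.bayes import CPDSet, NetworkSpec
from tilegrade.records import Detection2D


def enumeration_marginal(
    spec: NetworkSpec, cpds: CPDSet, evidence: Mapping[str, bool], query: str
) -> float:
    """P(query=1 | evidence) by summing the full joint over all assignments."""
    free = [n for n in spec.nodes if n not in evidence]
    num = 0.0
    den = 0.0
    for bits in itertools.product([False, True], repeat=len(free)):
        assignment = dict(evidence)
        assignment.update(zip(free, bits))
        p = 1.0
        for node in spec.nodes:
            cpd = cpds[node]
            p *= cpd.prob(assignment[node], {q: assignment[q] for q in cpd.parents})
        den += p
        if assignment[query]:
            num += p
    if den == 0.0:
        raise ZeroDivisionError("evidence has probability zero")
    return num / den


def transitive_closure_components(
    items: Sequence, linked
) -> set[frozenset[int]]:
    """Connected components by repeated all-pairs closure over ``linked``."""
    n = len(items)
    adj = [[i == j or linked(items[i], items[j]) for j in range(n)] for i in range(n)]
    # Floyd-Warshall-style closure
    for k in range(n):
        for i in range(n):
            if adj[i][k]:
                for j in range(n):
                    if adj[k][j]:
                        adj[i][j] = True
    comps: set[frozenset[int]] = set()
    for i in range(n):
        comps.add(frozenset(j for j in range(n) if adj[i][j]))
    return comps


def detections_linked(a: Detection2D, b: Detection2D) -> bool:
    """The 2D->3D fusion link predicate, restated independently."""
    if a.fracture_type != b.fracture_type:
        return False
    if abs(a.slice_index - b.slice_index) > 1:
        return False
    ax0, ay0, ax1, ay1 = a.box
    bx0, by0, bx1, by1 = b.box
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def mip_slabs(volume_zyx: np.ndarray, slab: int) -> list[np.ndarray]:
    """Per-slab max with a plain python loop; axis 0 is axial."""
    out = []
    for start in range(0, volume_zyx.shape[0], slab):
        block = volume_zyx[start : start + slab]
        acc = block[0].copy()
        for sl in block[1:]:
            acc = np.maximum(acc, sl)
        out.append(acc)
    return out


def pair_counting_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the fraction of concordant positive/negative pairs (+1/2 ties)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_boolean_dag(
    rng: np.random.Generator, max_nodes: int = 10
) -> tuple[NetworkSpec, CPDSet]:
    """A random DAG with CPD entries bounded away from 0/1."""
    from tilegrade.bayes import CPDTable

    n = int(rng.integers(2, max_nodes + 1))
    names = tuple(f"n{i}" for i in range(n))
    perm = rng.permutation(n)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                edges.add((names[perm[i]], names[perm[j]]))
    spec = NetworkSpec(names, frozenset(edges))
    cpds: CPDSet = {}
    for node in names:
        parents = spec.parents(node)
        shape = (2,) * len(parents)
        p1 = 0.05 + 0.9 * rng.random(shape)
        cpds[node] = CPDTable(node, parents, p1 if parents else np.array(float(p1)))
    return spec, cpds
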