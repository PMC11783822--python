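"""Bayesian refinement of the fracture list and final Tile grade.

The detector runs at a highly specific operating point, so true but subtle
findings may land only in the low-confidence set FXlow.  Refinement asks the
causal model which absent fracture types are likely given everything
currently observed (a leave-one-out conditional per candidate); a candidate
present in FXlow whose conditional probability clears z* is promoted into
the evidence, and the loop repeats until no candidate clears the bar.  The
final Tile grade is recomputed from the updated evidence.

The algorithm only ever adds findings — a high-confidence (possibly false
positive) finding is never rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import AbstractSet, Mapping, Optional

from .bayes import (
    AGE_NODE,
    CPDSet,
    Inference,
    NetworkSpec,
    TileGrade,
    tile_from_instability,
)
from .fusion import Thresholds
from .records import FRACTURE_TYPES, FractureType

_TYPE_ORDER = {t: i for i, t in enumerate(FRACTURE_TYPES)}


@dataclass(frozen=True)
class RefinementResult:
    """Full audit trail of one patient's grading and retrieval."""

    initial_evidence: Mapping[str, bool]
    added: tuple[tuple[FractureType, float], ...]
    final_evidence: Mapping[str, bool]
    p_R_initial: float
    p_T_initial: float
    p_R_final: float
    p_T_final: float
    tile_initial: TileGrade
    tile_final: TileGrade

    def to_dict(self) -> dict:
        return {
            "initial_evidence": {k: int(v) for k, v in self.initial_evidence.items()},
            "added": [{"fracture_type": t.value, "probability": q} for t, q in self.added],
            "final_evidence": {k: int(v) for k, v in self.final_evidence.items()},
            "p_R_initial": self.p_R_initial,
            "p_T_initial": self.p_T_initial,
            "p_R_final": self.p_R_final,
            "p_T_final": self.p_T_final,
            "tile_initial": self.tile_initial.value,
            "tile_final": self.tile_final.value,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _fracture_evidence(
    spec: NetworkSpec,
    positives: AbstractSet[FractureType],
    age60: Optional[bool],
) -> dict[str, bool]:
    """Boolean evidence map: observed types 1, the rest 0, plus the age flag."""
    evidence = {t.value: (t in positives) for t in FRACTURE_TYPES if t.value in spec.nodes}
    if AGE_NODE in spec.nodes and age60 is not None:
        evidence[AGE_NODE] = bool(age60)
    return evidence


def _instability(engine: Inference, evidence: Mapping[str, bool]) -> tuple[float, float, TileGrade]:
    p_R = engine.marginal(evidence, "R")
    p_T = engine.marginal(evidence, "T")
    return p_R, p_T, tile_from_instability(p_R >= 0.5, p_T >= 0.5)


def initial_grade(
    spec: NetworkSpec,
    cpds: CPDSet,
    fx_high: AbstractSet[FractureType],
    age60: Optional[bool],
    engine: Optional[Inference] = None,
) -> tuple[float, float, TileGrade]:
    """Grade from the high-confidence findings alone.

    Evidence sets every detected type to 1, every other type to 0, and the
    age flag; returns (P(R=1|e), P(T=1|e), grade at the 0.5 posterior cut).
    """
    engine = engine or Inference(spec, cpds)
    return _instability(engine, _fracture_evidence(spec, fx_high, age60))


def candidate_probabilities(
    spec: NetworkSpec,
    cpds: CPDSet,
    current_evidence: Mapping[str, bool],
    candidates: AbstractSet[FractureType],
    engine: Optional[Inference] = None,
) -> dict[FractureType, float]:
    """Leave-one-out conditionals: P(fx=1 | all other evidence).

    Each candidate is un-observed only during its own query; every other
    fracture state and the age flag stay fixed.
    """
    for t in candidates:
        if current_evidence.get(t.value, False):
            raise ValueError(f"candidate {t.value} is already positive evidence")
    engine = engine or Inference(spec, cpds)
    out: dict[FractureType, float] = {}
    for t in candidates:
        ev = {k: v for k, v in current_evidence.items() if k != t.value}
        out[t] = engine.marginal(ev, t.value)
    return out


def refine(
    spec: NetworkSpec,
    cpds: CPDSet,
    fx_high: AbstractSet[FractureType],
    fx_low: AbstractSet[FractureType],
    age60: Optional[bool],
    thresholds: Thresholds,
    engine: Optional[Inference] = None,
) -> RefinementResult:
    """Greedy sequential retrieval of likely-missed low-confidence findings.

    Each round scores the remaining FXlow \\ positives candidates with their
    leave-one-out conditional; the best candidate is accepted if its
    probability reaches z_star (ties broken by canonical type order).
    Terminates after at most one addition per fracture type.
    """
    if not set(fx_high) <= set(fx_low):
        raise ValueError("FXhigh must be a subset of FXlow")
    engine = engine or Inference(spec, cpds)

    initial_evidence = _fracture_evidence(spec, fx_high, age60)
    p_R0, p_T0, tile0 = _instability(engine, initial_evidence)

    positives: set[FractureType] = set(fx_high)
    evidence = dict(initial_evidence)
    added: list[tuple[FractureType, float]] = []
    while True:
        candidates = {t for t in fx_low if t not in positives}
        if not candidates:
            break
        probs = candidate_probabilities(spec, cpds, evidence, candidates, engine)
        best = min(probs, key=lambda t: (-probs[t], _TYPE_ORDER[t]))
        if probs[best] < thresholds.z_star:
            break
        positives.add(best)
        evidence[best.value] = True
        added.append((best, probs[best]))

    p_R1, p_T1, tile1 = _instability(engine, evidence)
    return RefinementResult(
        initial_evidence=initial_evidence,
        added=tuple(added),
        final_evidence=evidence,
        p_R_initial=p_R0,
        p_T_initial=p_T0,
        p_R_final=p_R1,
        p_T_final=p_T1,
        tile_initial=tile0,
        tile_final=tile1,
    )
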