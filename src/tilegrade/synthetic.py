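"""Synthetic cohort and detector simulator.

Stands in for a trauma CT cohort with expert instability labels and for a
trained 2D fracture detector.  Ground truth is drawn by ancestral sampling
from a known causal network (age -> instabilities -> fracture types), and
the detector is emulated stochastically: each true fracture is detected in
a given augmented scan with a per-type probability d_t, detected fractures
emit one 2D box per occupied slice (each independently dropped with a
per-slice miss probability, but never all of them), boxes get small
coordinate jitter, and each augmented scan also receives Poisson false
positives.  Per-slice dropout is what splits single fractures into several
3D pieces inside one scan — the failure mode cross-scan fusion repairs.

Box scores are drawn from a Beta distribution rescaled onto (keep_2d, 1],
i.e. conditional on the box surviving the detector's operating point, so
d_t alone controls per-scan detectability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .bayes import (
    AGE_NODE,
    CPDSet,
    CPDTable,
    NetworkSpec,
    R_NODE,
    T_NODE,
    default_structure,
)
from .records import FRACTURE_TYPES, Detection2D, FractureType, PatientRecord

#: Default conditional probabilities P(fx=1 | R, T) used by the generator.
#: Directions are clinically sensible (anterior widening and parallel SI
#: patterns track translational instability; anteriorly divergent SI tracks
#: isolated rotational instability) but they are configuration values, not
#: fitted estimates.  Index order: [R][T].
_DEFAULT_FX_CPDS: dict[str, list[list[float]]] = {
    "psd": [[0.05, 0.60], [0.50, 0.80]],
    "si_anterior_divergent": [[0.02, 0.10], [0.70, 0.50]],
    "si_parallel": [[0.02, 0.70], [0.10, 0.75]],
    "sacral_nondiastatic": [[0.15, 0.30], [0.45, 0.50]],
    "sacral_diastatic": [[0.02, 0.60], [0.10, 0.70]],
    "isp_avulsion": [[0.02, 0.15], [0.40, 0.45]],
    "ring_fx": [[0.30, 0.60], [0.60, 0.80]],
}


def default_generator_cpds(spec: Optional[NetworkSpec] = None) -> CPDSet:
    """Generator CPDs over the default structure (or an age-blind variant)."""
    spec = spec or default_structure()
    cpds: CPDSet = {}
    if AGE_NODE in spec.nodes:
        cpds[AGE_NODE] = CPDTable(AGE_NODE, (), np.array(0.35))
        cpds[R_NODE] = CPDTable(R_NODE, (AGE_NODE,), np.array([0.45, 0.60]))
        cpds[T_NODE] = CPDTable(T_NODE, (AGE_NODE,), np.array([0.25, 0.40]))
    else:
        cpds[R_NODE] = CPDTable(R_NODE, (), np.array(0.50))
        cpds[T_NODE] = CPDTable(T_NODE, (), np.array(0.30))
    for fx, table in _DEFAULT_FX_CPDS.items():
        parents = spec.parents(fx)
        arr = np.array(table)
        # default table is indexed [R][T]; reorder to the spec's parent order
        if parents == (T_NODE, R_NODE):
            arr = arr.T
        elif parents != (R_NODE, T_NODE):
            raise ValueError(f"unsupported parent set {parents} for generator node {fx}")
        cpds[fx] = CPDTable(fx, parents, arr)
    return cpds


@dataclass(frozen=True)
class CohortParams:
    """Cohort-level generator settings."""

    n_patients: int = 400
    p_age60: float = 0.35
    generator_cpds: Optional[CPDSet] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.p_age60 <= 1.0:
            raise ValueError("p_age60 must lie in [0, 1]")


@dataclass(frozen=True)
class DetectorParams:
    """Stochastic detector emulation settings.

    detect_prob: per-type probability the fracture is found in one augmented
    scan (scalar or per-type mapping); miss_prob: per-slice 2D dropout;
    fp_rate: Poisson mean of false-positive boxes per augmented scan;
    tp_beta / fp_beta: Beta shape parameters of box scores, rescaled onto
    (keep_2d, 1]; volume_shape: (nx, ny, nz) detector frame; K: number of
    augmented scans.
    """

    detect_prob: float | Mapping[FractureType, float] = 0.85
    miss_prob: float = 0.1
    fp_rate: float = 0.2
    tp_beta: tuple[float, float] = (4.0, 2.0)
    fp_beta: tuple[float, float] = (1.0, 3.0)
    keep_2d: float = 0.5
    volume_shape: tuple[int, int, int] = (96, 96, 48)
    K: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        for p in self._detect_probs().values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must lie in [0, 1]")

    def _detect_probs(self) -> dict[FractureType, float]:
        if isinstance(self.detect_prob, Mapping):
            return {t: float(self.detect_prob[t]) for t in FRACTURE_TYPES}
        return {t: float(self.detect_prob) for t in FRACTURE_TYPES}


def generate_cohort(
    params: CohortParams, spec: Optional[NetworkSpec] = None
) -> list[PatientRecord]:
    """Ancestral-sample a labeled cohort from the generator network."""
    spec = spec or default_structure()
    cpds = params.generator_cpds or default_generator_cpds(spec)
    rng = np.random.default_rng(params.seed)
    order = spec.topological_order()
    patients: list[PatientRecord] = []
    for i in range(params.n_patients):
        values: dict[str, bool] = {}
        if AGE_NODE in spec.nodes:
            values[AGE_NODE] = bool(rng.random() < params.p_age60)
        for node in order:
            if node in values:
                continue
            cpd = cpds[node]
            p = cpd.prob(True, {q: values[q] for q in cpd.parents})
            values[node] = bool(rng.random() < p)
        age60 = values.get(AGE_NODE, False)
        age = int(rng.integers(60, 96)) if age60 else int(rng.integers(18, 60))
        patients.append(
            PatientRecord(
                patient_id=f"syn{i:05d}",
                age_years=age,
                truth_fractures={t: values[t.value] for t in FRACTURE_TYPES},
                truth_R=values[R_NODE],
                truth_T=values[T_NODE],
            )
        )
    return patients


def _sample_cuboid(rng: np.random.Generator, shape: tuple[int, int, int]) -> tuple:
    nx_, ny, nz = shape
    dx = int(rng.integers(8, 21))
    dy = int(rng.integers(8, 21))
    dz = int(rng.integers(2, 9))
    if dx > nx_ or dy > ny or dz > nz:
        raise ValueError(f"fracture cuboid ({dx},{dy},{dz}) cannot fit in volume {shape}")
    x0 = int(rng.integers(0, nx_ - dx + 1))
    y0 = int(rng.integers(0, ny - dy + 1))
    z0 = int(rng.integers(0, nz - dz + 1))
    return (x0, y0, z0, x0 + dx, y0 + dy, z0 + dz)


def _score(rng: np.random.Generator, beta: tuple[float, float], keep: float) -> float:
    return float(keep + (1.0 - keep) * rng.beta(*beta))


def simulate_detections(
    patient: PatientRecord,
    det: DetectorParams,
    rng: Optional[np.random.Generator] = None,
) -> list[Detection2D]:
    """Emulate the detector on all K augmented scans of one patient."""
    if patient.truth_fractures is None:
        raise ValueError(f"patient {patient.patient_id} has no ground-truth fractures")
    if rng is None:
        rng = np.random.default_rng(det.seed)
    nx_, ny, nz = det.volume_shape
    dprobs = det._detect_probs()
    out: list[Detection2D] = []

    true_cuboids = {
        t: _sample_cuboid(rng, det.volume_shape)
        for t in FRACTURE_TYPES
        if patient.truth_fractures.get(t, False)
    }

    for k in range(det.K):
        for t, (x0, y0, z0, x1, y1, z1) in true_cuboids.items():
            if rng.random() >= dprobs[t]:
                continue
            slices = np.arange(z0, z1)
            keep_mask = rng.random(len(slices)) >= det.miss_prob
            if not keep_mask.any():
                keep_mask[rng.integers(0, len(slices))] = True  # never drop all
            for s in slices[keep_mask]:
                jx = int(rng.integers(-1, 2))
                jy = int(rng.integers(-1, 2))
                bx0 = max(0, x0 + jx)
                by0 = max(0, y0 + jy)
                bx1 = min(nx_, max(bx0 + 1, x1 + jx))
                by1 = min(ny, max(by0 + 1, y1 + jy))
                out.append(
                    Detection2D(
                        patient_id=patient.patient_id,
                        augmentation_id=k,
                        slice_index=int(s),
                        box=(float(bx0), float(by0), float(bx1), float(by1)),
                        fracture_type=t,
                        network_score=_score(rng, det.tp_beta, det.keep_2d),
                    )
                )
        for _ in range(rng.poisson(det.fp_rate)):
            t = FRACTURE_TYPES[int(rng.integers(0, len(FRACTURE_TYPES)))]
            fx0, fy0, fz0, fx1, fy1, fz1 = _sample_cuboid(rng, det.volume_shape)
            s = int(rng.integers(fz0, fz1))
            out.append(
                Detection2D(
                    patient_id=patient.patient_id,
                    augmentation_id=k,
                    slice_index=s,
                    box=(float(fx0), float(fy0), float(fx1), float(fy1)),
                    fracture_type=t,
                    network_score=_score(rng, det.fp_beta, det.keep_2d),
                )
            )
    return out


def simulate_cohort_detections(
    patients: Sequence[PatientRecord], det: DetectorParams
) -> dict[str, list[Detection2D]]:
    """Simulate every patient, each under an independent child seed."""
    seeds = np.random.SeedSequence(det.seed).spawn(len(patients))
    return {
        p.patient_id: simulate_detections(p, det, np.random.default_rng(s))
        for p, s in zip(patients, seeds)
    }
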