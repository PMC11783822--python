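"""Self-ensembling detection fusion.

Two fusion stages turn per-slice detector boxes into patient-level findings:

1. within one augmented scan, 2D boxes of the same fracture type that
   overlap in-plane on the same or adjacent slices are merged into a 3D
   fracture (connected components of the overlap graph);
2. across the K augmented scans, 3D fractures of the same type whose cuboids
   intersect are merged into one fused finding whose confidence is the
   *frequency* with which it was detected:

       Pc(fx) = (# augmented scans containing >= 1 constituent) / K.

Multiple constituents inside one scan count once, so a fracture split by a
missed 2D slice in one scan does not deflate its own score.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import (
    FRACTURE_TYPES,
    Detection2D,
    Fracture3D,
    FractureType,
    FusedFracture,
)

_TYPE_ORDER = {t: i for i, t in enumerate(FRACTURE_TYPES)}


@dataclass(frozen=True)
class Thresholds:
    """Confidence thresholds governing detection sets and refinement.

    keep_2d filters raw detector boxes (strict >); z_high/z_low cut the
    frequency scores into the high- and low-confidence finding sets; z_star
    is the acceptance threshold on the causal model's conditional
    probability when retrieving a low-confidence finding.
    """

    keep_2d: float = 0.5
    z_high: float = 0.8
    z_low: float = 0.5
    z_star: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.z_low <= self.z_high <= 1.0:
            raise ValueError("need 0 <= z_low <= z_high <= 1")
        if not 0.0 <= self.z_star <= 1.0 + 1e-12:
            raise ValueError("z_star must lie in [0, 1]")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _boxes_overlap_2d(a: tuple, b: tuple) -> bool:
    # half-open intervals: nonempty intersection on both in-plane axes
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def _cuboids_overlap(a: tuple, b: tuple) -> bool:
    return (
        a[0] < b[3] and b[0] < a[3]
        and a[1] < b[4] and b[1] < a[4]
        and a[2] < b[5] and b[2] < a[5]
    )


def fuse_2d_to_3d(
    detections: Sequence[Detection2D], keep_2d: float = 0.5
) -> list[Fracture3D]:
    """Merge one scan's 2D detections into 3D fractures.

    Detections with network_score <= keep_2d are discarded.  Two kept
    detections are linked iff they share a fracture type, their in-plane
    boxes intersect, and they lie on the same or adjacent slices; each
    connected component becomes one Fracture3D.
    """
    ids = {(d.patient_id, d.augmentation_id) for d in detections}
    if len(ids) > 1:
        raise ValueError(f"detections span multiple patient/augmentation ids: {sorted(ids)}")
    kept = [d for d in detections if d.network_score > keep_2d]
    if not kept:
        return []

    uf = _UnionFind(len(kept))
    # bucket by (type, slice) so only same/adjacent-slice pairs are compared
    buckets: dict[tuple[FractureType, int], list[int]] = defaultdict(list)
    for i, d in enumerate(kept):
        buckets[(d.fracture_type, d.slice_index)].append(i)
    for (ftype, s), idxs in buckets.items():
        neighbours = idxs + buckets.get((ftype, s + 1), [])
        for ai, i in enumerate(idxs):
            for j in neighbours:
                if j == i:
                    continue
                if _boxes_overlap_2d(kept[i].box, kept[j].box):
                    uf.union(i, j)

    groups: dict[int, list[Detection2D]] = defaultdict(list)
    for i, d in enumerate(kept):
        groups[uf.find(i)].append(d)
    fractures = [Fracture3D.from_detections(g) for g in groups.values()]
    fractures.sort(key=lambda f: (_TYPE_ORDER[f.fracture_type], f.cuboid[2], f.cuboid[1], f.cuboid[0]))
    return fractures


def fuse_across_scans(
    fractures_by_augmentation: Mapping[int, Sequence[Fracture3D]], K: int
) -> list[FusedFracture]:
    """Merge 3D fractures across the K augmented scans into fused findings.

    Fractures of the same type with intersecting cuboids are connected; a
    component's cuboid is the minimal cuboid containing all members and its
    frequency is the fraction of scans holding at least one member.
    """
    if K <= 0:
        raise ValueError("K must be a positive number of augmented scans")
    flat: list[tuple[int, Fracture3D]] = []
    for aug_id, frs in fractures_by_augmentation.items():
        if not 0 <= aug_id < K:
            raise ValueError(f"augmentation_id {aug_id} outside [0, {K})")
        flat.extend((aug_id, f) for f in frs)
    if not flat:
        return []

    uf = _UnionFind(len(flat))
    by_type: dict[FractureType, list[int]] = defaultdict(list)
    for i, (_, f) in enumerate(flat):
        by_type[f.fracture_type].append(i)
    for idxs in by_type.values():
        for a in range(len(idxs)):
            fa = flat[idxs[a]][1]
            for b in range(a + 1, len(idxs)):
                fb = flat[idxs[b]][1]
                if _cuboids_overlap(fa.cuboid, fb.cuboid):
                    uf.union(idxs[a], idxs[b])

    groups: dict[int, list[tuple[int, Fracture3D]]] = defaultdict(list)
    for i, item in enumerate(flat):
        groups[uf.find(i)].append(item)

    fused: list[FusedFracture] = []
    for members in groups.values():
        cuboids = [f.cuboid for _, f in members]
        cuboid = (
            min(c[0] for c in cuboids),
            min(c[1] for c in cuboids),
            min(c[2] for c in cuboids),
            max(c[3] for c in cuboids),
            max(c[4] for c in cuboids),
            max(c[5] for c in cuboids),
        )
        by_aug: dict[int, tuple[Fracture3D, ...]] = {}
        for aug_id in sorted({a for a, _ in members}):
            by_aug[aug_id] = tuple(f for a, f in members if a == aug_id)
        fused.append(
            FusedFracture(
                cuboid=cuboid,
                fracture_type=members[0][1].fracture_type,
                constituents_by_augmentation=by_aug,
                frequency=len(by_aug) / K,
            )
        )
    fused.sort(key=lambda f: (_TYPE_ORDER[f.fracture_type], f.cuboid[2], f.cuboid[1], f.cuboid[0]))
    return fused


def frequency_score(component: FusedFracture, K: int) -> float:
    """Self-ensembling vote: distinct scans holding a constituent, over K."""
    if not component.constituents_by_augmentation:
        raise ValueError("empty fused component")
    if K <= 0:
        raise ValueError("K must be positive")
    return len(component.constituents_by_augmentation) / K


def type_confidence(
    fused: Iterable[FusedFracture],
) -> dict[FractureType, float]:
    """Per fracture type, the maximum fused-finding frequency (0 if none)."""
    conf = {t: 0.0 for t in FRACTURE_TYPES}
    for f in fused:
        conf[f.fracture_type] = max(conf[f.fracture_type], f.frequency)
    return conf


def detect_sets(
    confidences: Mapping[FractureType, float], thresholds: Thresholds
) -> tuple[frozenset[FractureType], frozenset[FractureType]]:
    """High- and low-confidence fracture-type sets (FXhigh subset of FXlow)."""
    fx_high = frozenset(t for t in FRACTURE_TYPES if confidences.get(t, 0.0) >= thresholds.z_high)
    fx_low = frozenset(t for t in FRACTURE_TYPES if confidences.get(t, 0.0) >= thresholds.z_low)
    return fx_high, fx_low


def fuse_patient(
    detections: Sequence[Detection2D], K: int, keep_2d: float = 0.5
) -> list[FusedFracture]:
    """Full two-stage fusion for one patient's detections across all scans."""
    by_aug: dict[int, list[Detection2D]] = defaultdict(list)
    for d in detections:
        by_aug[d.augmentation_id].append(d)
    fractures = {aug: fuse_2d_to_3d(dets, keep_2d) for aug, dets in by_aug.items()}
    return fuse_across_scans(fractures, K)


def export_fused(fused: Sequence[FusedFracture]) -> list[dict]:
    """JSON-ready export of fused findings (cuboid, type, frequency, votes)."""
    return [
        {
            "cuboid": list(f.cuboid),
            "fracture_type": f.fracture_type.value,
            "frequency": f.frequency,
            "constituents_per_augmentation": {
                str(a): len(c) for a, c in f.constituents_by_augmentation.items()
            },
        }
        for f in fused
    ]
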