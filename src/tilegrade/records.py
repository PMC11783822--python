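"""Domain records: fracture taxonomy, detections, fused findings, patients.

Coordinate convention: all boxes are 0-based and half-open on every axis.
A 2D detection on slice ``s`` occupies ``z in [s, s+1)``, which makes
"adjacent slices" and 3D intersection tests uniform across the pipeline.

Detections are exchanged as JSON-lines (one record per line, streamable and
diff-able); patients as CSV.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

SCHEMA_VERSION = 1


class FractureType(enum.Enum):
    """The seven CT findings with first-order Tile grading saliency.

    The definition order is the canonical ordering used everywhere a
    deterministic tie-break over fracture types is needed.
    """

    PSD = "psd"
    SI_ANTERIOR_DIVERGENT = "si_anterior_divergent"
    SI_PARALLEL = "si_parallel"
    SACRAL_NONDIASTATIC = "sacral_nondiastatic"
    SACRAL_DIASTATIC = "sacral_diastatic"
    ISP_AVULSION = "isp_avulsion"
    RING_FX = "ring_fx"

    def __lt__(self, other: "FractureType") -> bool:
        order = list(FractureType)
        return order.index(self) < order.index(other)


#: Canonical fracture-type ordering (tie-breaks, CSV column order, ...).
FRACTURE_TYPES: tuple[FractureType, ...] = tuple(FractureType)


def fracture_type_from_string(code: str) -> FractureType:
    try:
        return FractureType(code)
    except ValueError:
        valid = ", ".join(t.value for t in FRACTURE_TYPES)
        raise ValueError(
            f"unknown fracture type {code!r}; expected one of: {valid}"
        ) from None


@dataclass(frozen=True)
class Detection2D:
    """One detector box on one MIP slice of one augmented scan."""

    patient_id: str
    augmentation_id: int
    slice_index: int
    box: tuple[float, float, float, float]  # (x_min, y_min, x_max, y_max)
    fracture_type: FractureType
    network_score: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}: need x_min<x_max, y_min<y_max")
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")
        if self.augmentation_id < 0:
            raise ValueError("augmentation_id must be non-negative")
        if not 0.0 <= self.network_score <= 1.0:
            raise ValueError("network_score must lie in [0, 1]")


@dataclass(frozen=True)
class Fracture3D:
    """A within-scan 3D finding fused from 2D detections.

    ``cuboid`` is the minimal axis-aligned half-open box containing every
    constituent; ``score`` is the maximum constituent network score.
    """

    cuboid: tuple[float, float, float, float, float, float]
    fracture_type: FractureType
    score: float
    constituents: tuple[Detection2D, ...]

    @property
    def augmentation_id(self) -> int:
        return self.constituents[0].augmentation_id

    @classmethod
    def from_detections(cls, detections: Sequence[Detection2D]) -> "Fracture3D":
        if not detections:
            raise ValueError("cannot build a Fracture3D from zero detections")
        types = {d.fracture_type for d in detections}
        if len(types) != 1:
            raise ValueError("constituent detections must share a fracture type")
        x0 = min(d.box[0] for d in detections)
        y0 = min(d.box[1] for d in detections)
        z0 = min(d.slice_index for d in detections)
        x1 = max(d.box[2] for d in detections)
        y1 = max(d.box[3] for d in detections)
        z1 = max(d.slice_index for d in detections) + 1
        ordered = tuple(
            sorted(detections, key=lambda d: (d.slice_index, d.box, d.network_score))
        )
        return cls(
            cuboid=(x0, y0, float(z0), x1, y1, float(z1)),
            fracture_type=detections[0].fracture_type,
            score=max(d.network_score for d in detections),
            constituents=ordered,
        )


@dataclass(frozen=True)
class FusedFracture:
    """A cross-augmentation finding with a frequency confidence score.

    ``frequency`` is the fraction of the K augmented scans in which at least
    one constituent 3D fracture appears (self-ensembling vote).
    """

    cuboid: tuple[float, float, float, float, float, float]
    fracture_type: FractureType
    constituents_by_augmentation: Mapping[int, tuple[Fracture3D, ...]]
    frequency: float


@dataclass(frozen=True)
class PatientRecord:
    """Patient metadata plus optional ground-truth labels.

    Truth fields are present for labeled (or synthetic) patients only: one
    boolean per fracture type, and the consensus rotational/translational
    instability labels.
    """

    patient_id: str
    age_years: int
    truth_fractures: Optional[Mapping[FractureType, bool]] = None
    truth_R: Optional[bool] = None
    truth_T: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"negative age {self.age_years} for patient {self.patient_id}")


# ---------------------------------------------------------------------------
# JSON-lines detections


def _detection_to_dict(d: Detection2D) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "patient_id": d.patient_id,
        "augmentation_id": d.augmentation_id,
        "slice_index": d.slice_index,
        "box": list(d.box),
        "fracture_type": d.fracture_type.value,
        "network_score": d.network_score,
    }


def _detection_from_dict(obj: dict) -> Detection2D:
    return Detection2D(
        patient_id=str(obj["patient_id"]),
        augmentation_id=int(obj["augmentation_id"]),
        slice_index=int(obj["slice_index"]),
        box=tuple(float(v) for v in obj["box"]),
        fracture_type=fracture_type_from_string(obj["fracture_type"]),
        network_score=float(obj["network_score"]),
    )


def write_detections(
    detections: Iterable[Detection2D],
    path: str | Path,
    meta: Optional[Mapping] = None,
) -> None:
    """Write detections as JSON-lines; ``meta`` becomes a header record."""
    with open(path, "w") as fh:
        if meta is not None:
            fh.write(json.dumps({"record_type": "meta", **dict(meta)}) + "\n")
        for d in detections:
            fh.write(json.dumps(_detection_to_dict(d)) + "\n")


def read_detections(path: str | Path) -> list[Detection2D]:
    """Read a JSON-lines detections file; malformed rows name their line."""
    out: list[Detection2D] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                if obj.get("record_type") == "meta":
                    continue
                out.append(_detection_from_dict(obj))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: malformed detection on line {lineno}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Patient CSV

_LABEL_COLUMNS = ["truth_R", "truth_T"] + [f"truth_{t.value}" for t in FRACTURE_TYPES]


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row: dict = {
            "schema_version": SCHEMA_VERSION,
            "patient_id": p.patient_id,
            "age_years": p.age_years,
        }
        if p.truth_R is not None:
            row["truth_R"] = int(p.truth_R)
        if p.truth_T is not None:
            row["truth_T"] = int(p.truth_T)
        if p.truth_fractures is not None:
            for t in FRACTURE_TYPES:
                row[f"truth_{t.value}"] = int(bool(p.truth_fractures.get(t, False)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_patients(patients: Sequence[PatientRecord], path: str | Path,
                   meta: Optional[Mapping] = None) -> None:
    with open(path, "w") as fh:
        if meta is not None:
            for key, val in meta.items():
                fh.write(f"# {key}={val}\n")
        patients_to_frame(patients).to_csv(fh, index=False)


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read a patient CSV; label columns are optional."""
    df = pd.read_csv(path, comment="#")
    out: list[PatientRecord] = []
    for _, row in df.iterrows():
        age = int(row["age_years"])
        if age < 0:
            raise ValueError(f"{path}: negative age {age} for patient {row['patient_id']}")
        truth_fx = None
        fx_cols = [f"truth_{t.value}" for t in FRACTURE_TYPES]
        if all(c in df.columns and pd.notna(row[c]) for c in fx_cols):
            truth_fx = {t: bool(int(row[f"truth_{t.value}"])) for t in FRACTURE_TYPES}

        def _opt(col: str) -> Optional[bool]:
            if col in df.columns and pd.notna(row[col]):
                return bool(int(row[col]))
            return None

        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age_years=age,
                truth_fractures=truth_fx,
                truth_R=_opt("truth_R"),
                truth_T=_opt("truth_T"),
            )
        )
    return out
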