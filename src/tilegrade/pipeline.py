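"""Orchestration: configuration, provenance, and the end-to-end stages.

Every artifact embeds the hash of the resolved configuration and the seed
that produced it (JSON-lines meta record or ``# key=value`` CSV comment
lines), so any output can be traced back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import fusion, records
from .bayes import age_flag, default_structure, load_model
from .evaluation import cross_validate, threshold_sweep
from .fusion import Thresholds, detect_sets
from .model import TileBayesModel
from .records import FRACTURE_TYPES, Detection2D, FractureType
from .synthetic import CohortParams, DetectorParams, generate_cohort, simulate_cohort_detections

log = logging.getLogger("tilegrade")


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    seed: int = 0
    output_dir: str = "out"
    detections_path: Optional[str] = None
    patients_path: Optional[str] = None
    model_path: Optional[str] = None
    confidences_path: Optional[str] = None
    include_age: bool = True
    K: int = 25
    keep_2d: float = 0.5
    z_high: float = 0.8
    z_low: float = 0.5
    z_star: float = 0.5
    n_patients: int = 100
    p_age60: float = 0.35
    detect_prob: float = 0.85
    miss_prob: float = 0.1
    fp_rate: float = 0.2
    sweep_axis: str = "z_star"
    sweep_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7)
    k_folds: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**{k: (tuple(v) if k == "sweep_grid" else v) for k, v in raw.items()})
        cfg.thresholds()  # validate threshold ordering eagerly
        return cfg

    def thresholds(self) -> Thresholds:
        return Thresholds(self.keep_2d, self.z_high, self.z_low, self.z_star)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def meta(self) -> dict:
        return {"config_hash": self.config_hash(), "seed": self.seed}


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_csv(df: pd.DataFrame, path: Path, meta: Mapping) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def run_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate a labeled synthetic cohort plus detector output files."""
    out = _outdir(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    s_cohort, s_det = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    patients = generate_cohort(
        CohortParams(cfg.n_patients, cfg.p_age60, seed=s_cohort),
        default_structure(cfg.include_age),
    )
    det = DetectorParams(
        detect_prob=cfg.detect_prob,
        miss_prob=cfg.miss_prob,
        fp_rate=cfg.fp_rate,
        keep_2d=cfg.keep_2d,
        K=cfg.K,
        seed=s_det,
    )
    detections = simulate_cohort_detections(patients, det)
    patients_path = out / "patients.csv"
    detections_path = out / "detections.jsonl"
    records.write_patients(patients, patients_path, meta=cfg.meta())
    flat = [d for pid in sorted(detections) for d in detections[pid]]
    records.write_detections(flat, detections_path, meta=cfg.meta())
    log.info("simulated %d patients, %d detections", len(patients), len(flat))
    return {"patients": patients_path, "detections": detections_path}


def _load_detections_by_patient(cfg: PipelineConfig) -> dict[str, list[Detection2D]]:
    if cfg.detections_path is None:
        raise ValueError("config field 'detections_path' is required for this command")
    dets = records.read_detections(cfg.detections_path)
    by_patient: dict[str, list[Detection2D]] = {}
    for d in dets:
        by_patient.setdefault(d.patient_id, []).append(d)
    return by_patient


def run_fuse(cfg: PipelineConfig) -> dict[str, Path]:
    """Fuse detections into findings; write fused JSONL + confidence CSV."""
    out = _outdir(cfg)
    by_patient = _load_detections_by_patient(cfg)
    fused_path = out / "fused.jsonl"
    conf_rows = []
    with open(fused_path, "w") as fh:
        fh.write(json.dumps({"record_type": "meta", **cfg.meta()}) + "\n")
        for pid in sorted(by_patient):
            fused = fusion.fuse_patient(by_patient[pid], cfg.K, cfg.keep_2d)
            for item in fusion.export_fused(fused):
                fh.write(json.dumps({"patient_id": pid, **item}) + "\n")
            conf = fusion.type_confidence(fused)
            conf_rows.append({"patient_id": pid, **{t.value: conf[t] for t in FRACTURE_TYPES}})
    conf_path = out / "confidences.csv"
    _write_csv(pd.DataFrame(conf_rows), conf_path, cfg.meta())
    log.info("fused findings for %d patients", len(conf_rows))
    return {"fused": fused_path, "confidences": conf_path}


def run_fit(cfg: PipelineConfig) -> dict[str, Path]:
    """Fit CPDs on labeled patients and serialize the audited model."""
    if cfg.patients_path is None:
        raise ValueError("config field 'patients_path' is required for this command")
    out = _outdir(cfg)
    patients = records.read_patients(cfg.patients_path)
    labeled = [p for p in patients if p.truth_fractures is not None and p.truth_R is not None]
    if not labeled:
        raise ValueError("no labeled patients to fit on")
    results = TileBayesModel.from_patients(labeled, default_structure(cfg.include_age)).fit()
    model_path = out / "model.yaml"
    results.save(model_path)
    with open(model_path, "a") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
    log.info("fit CPDs on %d labeled patients", len(labeled))
    return {"model": model_path}


def _read_confidences(path: str | Path) -> dict[str, dict[FractureType, float]]:
    df = pd.read_csv(path, comment="#")
    return {
        str(row["patient_id"]): {t: float(row[t.value]) for t in FRACTURE_TYPES}
        for _, row in df.iterrows()
    }


def run_grade(cfg: PipelineConfig) -> dict[str, Path]:
    """Grade every patient: initial + refined instabilities and Tile grade."""
    if cfg.model_path is None or cfg.confidences_path is None or cfg.patients_path is None:
        raise ValueError(
            "config fields 'model_path', 'confidences_path' and 'patients_path' "
            "are required for this command"
        )
    out = _outdir(cfg)
    spec, cpds = load_model(cfg.model_path)
    confs = _read_confidences(cfg.confidences_path)
    patients = {p.patient_id: p for p in records.read_patients(cfg.patients_path)}
    from .bayes import Inference
    from .refinement import refine

    engine = Inference(spec, cpds)
    th = cfg.thresholds()
    grade_path = out / "grades.jsonl"
    no_findings = {t: 0.0 for t in FRACTURE_TYPES}
    with open(grade_path, "w") as fh:
        fh.write(json.dumps({"record_type": "meta", **cfg.meta()}) + "\n")
        for pid in sorted(set(confs) | set(patients)):
            # a patient absent from the detector output has no findings
            fx_high, fx_low = detect_sets(confs.get(pid, no_findings), th)
            age60 = age_flag(patients[pid].age_years) if pid in patients else None
            res = refine(spec, cpds, fx_high, fx_low, age60, th, engine)
            fh.write(json.dumps({"patient_id": pid, **res.to_dict()}) + "\n")
            log.debug("patient %s: %s -> %s", pid, res.tile_initial.value, res.tile_final.value)
    return {"grades": grade_path}


def run_sweep(cfg: PipelineConfig) -> dict[str, Path]:
    """Threshold sweep over z_low or z_star for LOW/HIGH/REFINE variants."""
    if cfg.model_path is None or cfg.confidences_path is None or cfg.patients_path is None:
        raise ValueError(
            "config fields 'model_path', 'confidences_path' and 'patients_path' "
            "are required for this command"
        )
    out = _outdir(cfg)
    spec, cpds = load_model(cfg.model_path)
    confs = _read_confidences(cfg.confidences_path)
    patients = [p for p in records.read_patients(cfg.patients_path) if p.patient_id in confs]
    table = threshold_sweep(
        cfg.sweep_axis, list(cfg.sweep_grid), cfg.thresholds(), patients, confs, spec, cpds
    )
    sweep_path = out / f"sweep_{cfg.sweep_axis}.csv"
    _write_csv(table, sweep_path, cfg.meta())
    return {"sweep": sweep_path}


def run_evaluate(cfg: PipelineConfig) -> dict[str, Path]:
    """Cross-validated AUC/kappa report for the full pipeline."""
    if cfg.patients_path is None:
        raise ValueError("config field 'patients_path' is required for this command")
    out = _outdir(cfg)
    patients = records.read_patients(cfg.patients_path)
    by_patient = _load_detections_by_patient(cfg)
    report = cross_validate(
        patients, by_patient, default_structure(cfg.include_age),
        cfg.thresholds(), K=cfg.K, k_folds=cfg.k_folds, seed=cfg.seed,
    )
    metrics_path = out / "metrics.csv"
    _write_csv(report.to_frame(), metrics_path, cfg.meta())
    for key, (mean, std) in report.summary().items():
        log.info("%s: %.3f +/- %.3f", key, mean, std)
    return {"metrics": metrics_path}


def three_scan_example() -> tuple[list[fusion.FusedFracture], float]:
    """Worked self-ensembling example: a fracture split in one scan.

    Three augmented scans (K=3): the first holds two same-type boxes
    separated by a one-slice 2D miss, the second holds one bridging box
    spanning the gap, the third holds nothing.  Cross-scan fusion merges
    all three boxes into one finding seen in two of three scans, so its
    frequency confidence is 2/3 ~ 0.667 — the split pieces in the first
    scan count once.
    """
    t = FractureType.PSD
    box = (10.0, 10.0, 30.0, 30.0)

    def det(aug: int, s: int) -> Detection2D:
        return Detection2D("demo", aug, s, box, t, 0.9)

    scan0 = [det(0, 2), det(0, 3), det(0, 5), det(0, 6)]  # gap at slice 4
    scan1 = [det(1, s) for s in range(2, 7)]  # bridges the gap
    fused = fusion.fuse_across_scans(
        {0: fusion.fuse_2d_to_3d(scan0), 1: fusion.fuse_2d_to_3d(scan1)}, K=3
    )
    assert len(fused) == 1
    return fused, fused[0].frequency


def run_demo(cfg: PipelineConfig) -> dict[str, Path]:
    """Print and verify the three-scan fusion worked example."""
    fused, freq = three_scan_example()
    n_pieces_scan0 = len(fused[0].constituents_by_augmentation[0])
    print("Three-scan self-ensembling fusion example")
    print(f"  3D pieces in scan 0 (split by a 2D miss): {n_pieces_scan0}")
    print(f"  fused findings after cross-scan fusion:   {len(fused)}")
    print(f"  scans containing the finding:             "
          f"{sorted(fused[0].constituents_by_augmentation)} of K=3")
    print(f"  frequency confidence:                     {freq:.3f}")
    if round(freq, 3) != 0.667:
        raise AssertionError(f"expected frequency 0.667, got {freq:.3f}")
    return {}


COMMANDS = {
    "simulate": run_simulate,
    "fuse": run_fuse,
    "fit": run_fit,
    "grade": run_grade,
    "sweep": run_sweep,
    "evaluate": run_evaluate,
    "demo": run_demo,
}


def run_end_to_end(cfg: PipelineConfig, command: str) -> dict[str, Path]:
    """Dispatch one pipeline stage; logs the resolved config and seed."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; choose from {sorted(COMMANDS)}")
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    log.info("command=%s config_hash=%s seed=%d", command, cfg.config_hash(), cfg.seed)
    return COMMANDS[command](cfg)
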