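"""Metrics and experiment harness: AUC, Cohen's kappa, patient-level
cross-validation, and the z_low / z_star threshold sweeps.

Instability prediction is evaluated per component (rotational and
translational separately): AUC on the posterior probabilities and kappa on
hard calls at the 0.5 posterior cut, against the consensus truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm
from sklearn.model_selection import KFold, StratifiedKFold

from .bayes import CPDSet, Inference, NetworkSpec, age_flag, fit_cpds
from .fusion import Thresholds, detect_sets, fuse_patient, type_confidence
from .records import FRACTURE_TYPES, Detection2D, FractureType, PatientRecord
from .refinement import _fracture_evidence, refine

Variant = Literal["LOW", "HIGH", "REFINE"]


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """ROC-AUC (Mann-Whitney rank statistic with midrank tie handling)."""
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC-AUC requires both classes present")
    return float(_skm.roc_auc_score(y, np.asarray(scores, dtype=float)))


def cohen_kappa(pred: Sequence[bool], truth: Sequence[bool]) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e) with marginal-product p_e."""
    p = np.asarray(pred, dtype=int)
    t = np.asarray(truth, dtype=int)
    if len(p) != len(t):
        raise ValueError("pred and truth must have equal length")
    if len(p) == 0:
        raise ValueError("empty inputs")
    po = float((p == t).mean())
    pe = float(p.mean() * t.mean() + (1 - p.mean()) * (1 - t.mean()))
    if pe >= 1.0 - 1e-15:
        if po >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("expected agreement is 1 with imperfect observed agreement")
    return float(_skm.cohen_kappa_score(p, t))


def patient_confidences(
    detections_by_patient: Mapping[str, Sequence[Detection2D]],
    K: int,
    keep_2d: float = 0.5,
) -> dict[str, dict[FractureType, float]]:
    """Run the two-stage fusion per patient and return type confidences."""
    return {
        pid: type_confidence(fuse_patient(dets, K, keep_2d))
        for pid, dets in detections_by_patient.items()
    }


def predict_instability(
    spec: NetworkSpec,
    cpds: CPDSet,
    confidences: Mapping[FractureType, float],
    age60: Optional[bool],
    thresholds: Thresholds,
    variant: Variant = "REFINE",
    engine: Optional[Inference] = None,
) -> tuple[float, float]:
    """Posterior (P(R=1|e), P(T=1|e)) for one patient under one variant.

    LOW conditions on the low-threshold finding set, HIGH on the
    high-threshold set, REFINE on the high set after Bayesian retrieval.
    """
    engine = engine or Inference(spec, cpds)
    fx_high, fx_low = detect_sets(confidences, thresholds)
    if variant == "LOW":
        ev = _fracture_evidence(spec, fx_low, age60)
        return engine.marginal(ev, "R"), engine.marginal(ev, "T")
    if variant == "HIGH":
        ev = _fracture_evidence(spec, fx_high, age60)
        return engine.marginal(ev, "R"), engine.marginal(ev, "T")
    res = refine(spec, cpds, fx_high, fx_low, age60, thresholds, engine)
    return res.p_R_final, res.p_T_final


@dataclass
class MetricsReport:
    """Mean +/- std of AUC and kappa for R and T across folds.

    Per-fold values are retained; a fold where a metric is undefined (one
    class only) is stored as NaN and excluded from the aggregates.
    """

    fold_metrics: list[dict[str, float]] = field(default_factory=list)

    _KEYS = ("auc_R", "auc_T", "kappa_R", "kappa_T")

    def mean(self, key: str) -> float:
        vals = [m[key] for m in self.fold_metrics]
        return float(np.nanmean(vals)) if vals else float("nan")

    def std(self, key: str) -> float:
        vals = [m[key] for m in self.fold_metrics]
        return float(np.nanstd(vals)) if vals else float("nan")

    def summary(self) -> dict[str, tuple[float, float]]:
        return {k: (self.mean(k), self.std(k)) for k in self._KEYS}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, **m} for i, m in enumerate(self.fold_metrics)]
        return pd.DataFrame(rows)


def _fold_metrics(
    spec: NetworkSpec,
    cpds: CPDSet,
    test_patients: Sequence[PatientRecord],
    confidences: Mapping[str, Mapping[FractureType, float]],
    thresholds: Thresholds,
    variant: Variant = "REFINE",
) -> dict[str, float]:
    engine = Inference(spec, cpds)
    no_findings = {t: 0.0 for t in FRACTURE_TYPES}
    p_R, p_T, y_R, y_T = [], [], [], []
    for p in test_patients:
        # a patient without any detector output has all-zero confidences
        conf = confidences.get(p.patient_id, no_findings)
        pr, pt = predict_instability(
            spec, cpds, conf, age_flag(p.age_years), thresholds, variant, engine
        )
        p_R.append(pr)
        p_T.append(pt)
        y_R.append(bool(p.truth_R))
        y_T.append(bool(p.truth_T))

    def _safe(fn, *args):
        try:
            return fn(*args)
        except ValueError:
            return float("nan")

    return {
        "auc_R": _safe(roc_auc, p_R, y_R),
        "auc_T": _safe(roc_auc, p_T, y_T),
        "kappa_R": _safe(cohen_kappa, [v >= 0.5 for v in p_R], y_R),
        "kappa_T": _safe(cohen_kappa, [v >= 0.5 for v in p_T], y_T),
    }


def _truth_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {
            "age60": int(age_flag(p.age_years)),
            "R": int(bool(p.truth_R)),
            "T": int(bool(p.truth_T)),
        }
        for t in FRACTURE_TYPES:
            row[t.value] = int(bool(p.truth_fractures.get(t, False)))
        rows.append(row)
    return pd.DataFrame(rows)


def cross_validate(
    patients: Sequence[PatientRecord],
    detections_by_patient: Mapping[str, Sequence[Detection2D]],
    spec: NetworkSpec,
    thresholds: Thresholds,
    K: int = 25,
    k_folds: int = 5,
    seed: int = 0,
    variant: Variant = "REFINE",
    pseudocount: float = 1.0,
) -> MetricsReport:
    """Patient-level k-fold evaluation of the full pipeline.

    Folds are stratified by the translational-instability truth label (the
    rarer instability, keeping folds two-class) when labels exist; in each
    fold CPDs are fit on the training patients' truth table and the fused
    detections of the test patients are graded.
    """
    if len(patients) < k_folds:
        raise ValueError("need at least k_folds patients")
    confidences = patient_confidences(detections_by_patient, K, thresholds.keep_2d)
    y_strat = [int(bool(p.truth_T)) for p in patients]
    idx = np.arange(len(patients))
    if 0 < sum(y_strat) < len(y_strat) and min(sum(y_strat), len(y_strat) - sum(y_strat)) >= k_folds:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = splitter.split(idx, y_strat)
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
        splits = splitter.split(idx)

    report = MetricsReport()
    for train_idx, test_idx in splits:
        train = [patients[i] for i in train_idx]
        test = [patients[i] for i in test_idx]
        cpds = fit_cpds(spec, _truth_frame(train), pseudocount)
        report.fold_metrics.append(
            _fold_metrics(spec, cpds, test, confidences, thresholds, variant)
        )
    return report


def threshold_sweep(
    axis: Literal["z_low", "z_star"],
    grid: Sequence[float],
    fixed: Thresholds,
    patients: Sequence[PatientRecord],
    confidences: Mapping[str, Mapping[FractureType, float]],
    spec: NetworkSpec,
    cpds: CPDSet,
) -> pd.DataFrame:
    """AUC of the LOW / HIGH / REFINE variants along a threshold grid.

    One row per grid value with six AUC columns; CPDs are supplied by the
    caller (fit on held-out training data).
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    if axis not in ("z_low", "z_star"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    rows = []
    for value in grid:
        kwargs = {"keep_2d": fixed.keep_2d, "z_high": fixed.z_high,
                  "z_low": fixed.z_low, "z_star": fixed.z_star}
        kwargs[axis] = float(min(value, 1.0)) if axis == "z_star" else float(value)
        th = Thresholds(**kwargs)
        if axis == "z_star" and value > 1.0:
            # beyond-unity acceptance bar: no candidate can ever be added
            th = Thresholds(fixed.keep_2d, fixed.z_high, fixed.z_low, 1.0 + 1e-12)
        row: dict[str, float] = {"value": float(value)}
        for variant in ("LOW", "HIGH", "REFINE"):
            m = _fold_metrics(spec, cpds, patients, confidences, th, variant)
            row[f"auc_R_{variant.lower()}"] = m["auc_R"]
            row[f"auc_T_{variant.lower()}"] = m["auc_T"]
        rows.append(row)
    return pd.DataFrame(rows)
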