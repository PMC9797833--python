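"""Study- and cohort-level orchestration.

``run_study`` executes the full per-study pipeline (reslice every view,
measure all three perimeter methods over the cycle, compute LS / FAC /
EF); a view whose slice shows no left atrium is downgraded to
non-compliant (its contour stays closed) rather than aborting the
study, and unreadable inputs flag the study as failed with a reason —
mirroring a clinical workflow where a handful of automated analyses
fail and are simply excluded.

``run_cohort`` fits LS cutoffs on the training records only (per-view
and pooled single-threshold ROC) and reports classification metrics
separately per cohort, in both threshold modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ctio
from .stats import (
    classify_patient,
    classify_view,
    confusion_metrics,
    consensus_view_labels,
    roc_and_optimal_cutoff,
)
from .strain import METHODS, StrainResult, build_view_curve, ejection_fraction, \
    fractional_area_change, longitudinal_strain, select_ed_es

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Every tunable of the measurement pipeline, in one place."""

    pixel_spacing_mm: float | None = None  # default: smallest voxel dim
    extent_mm: float | None = None  # default: auto from label bounding box
    closing_radius_px: float = 10.0
    downsample: int = 5
    per_view_ed_es: bool = False
    classify_method: str = "spline"
    segment_view_map: dict | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(data))


@dataclass
class StudyRecord:
    """Bookkeeping for one study in a cohort run."""

    study_id: str
    volumes: object = None  # path(s) to NIfTI, or a CineSegmentation
    planes: object = None  # path to JSON, or a list of PlaneDefinition
    role: str = "train"  # "train" | "test"
    analyzable: bool = True
    failure_reason: str | None = None


def _load_record(record: StudyRecord):
    cine = record.volumes
    if not hasattr(cine, "frames"):
        cine = ctio.load_cine(cine)
    planes = record.planes
    if planes is None or isinstance(planes, (str, Path)):
        planes = ctio.load_planes(planes)
    return cine, planes


def run_study(record: StudyRecord, config: AnalysisConfig | None = None):
    """Full pipeline on one study.

    Returns ``(StrainResult, DataFrame)`` where the frame has one row
    per (view, method) with P_ED, P_ES, LS, FAC, ED, ES, EF and the
    compliance flag.  On unreadable input the record is flagged failed
    and ``(None, empty frame)`` is returned.
    """
    config = config or AnalysisConfig()
    try:
        cine, planes = _load_record(record)
    except Exception as e:  # unreadable volume/plane file
        record.analyzable = False
        record.failure_reason = str(e)
        log.error("study %s failed: %s", record.study_id, e)
        return None, pd.DataFrame()
    ed, es = select_ed_es(cine)
    rows = []
    ls, fac, compliant = {}, {}, {}
    ef = ejection_fraction(cine, (ed, es))
    for plane in planes:
        curve = build_view_curve(
            cine, plane,
            pixel_spacing=config.pixel_spacing_mm,
            extent_mm=config.extent_mm,
            closing_radius_px=config.closing_radius_px,
            downsample=config.downsample,
            ed_es=(ed, es),
            per_view_ed_es=config.per_view_ed_es,
        )
        if not curve.compliant:
            log.warning("study %s view %s non-compliant (no LA found)",
                        record.study_id, plane.view)
        ls[plane.view] = {}
        fac[plane.view] = fractional_area_change(curve)
        compliant[plane.view] = curve.compliant
        for m in METHODS:
            ls_vm = longitudinal_strain(curve, m)
            ls[plane.view][m] = ls_vm
            rows.append({
                "study": record.study_id, "view": plane.view, "method": m,
                "p_ed_mm": curve.perimeters_mm[m][curve.ed],
                "p_es_mm": curve.perimeters_mm[m][curve.es],
                "ls": ls_vm, "ls_pct": 100.0 * ls_vm,
                "fac": fac[plane.view], "ef": ef,
                "ed": curve.ed, "es": curve.es,
                "compliant": curve.compliant,
            })
    result = StrainResult(ls=ls, fac=fac, ef=ef, ed=ed, es=es,
                          compliant=compliant)
    return result, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort level


def fit_thresholds(results: pd.DataFrame, view_truth: dict,
                   method: str = "spline") -> dict:
    """Per-view and pooled single LS cutoffs from training results.

    ``view_truth`` is {study: {view: bool}}.  Returns
    {"individual": {view: tau}, "single": tau, "auc": {...}}.
    """
    df = results[results.method == method]
    taus, aucs = {}, {}
    pooled_scores, pooled_truth = [], []
    for view in sorted(df.view.unique()):
        sub = df[df.view == view]
        scores = sub.ls.to_numpy()
        truth = np.array([view_truth[s][view] for s in sub.study])
        roc = roc_and_optimal_cutoff(scores, truth)
        taus[view] = roc.optimal_threshold
        aucs[view] = roc.auc
        pooled_scores.append(scores)
        pooled_truth.append(truth)
    roc_all = roc_and_optimal_cutoff(
        np.concatenate(pooled_scores), np.concatenate(pooled_truth)
    )
    return {
        "individual": taus,
        "single": roc_all.optimal_threshold,
        "auc": {**aucs, "pooled": roc_all.auc},
    }


def evaluate_thresholds(results: pd.DataFrame, view_truth: dict,
                        thresholds, method: str = "spline") -> dict:
    """Classify every view and study against the truth.

    ``thresholds`` is either a {view: tau} mapping or a single float.
    Returns per-view-tag, pooled per-view and per-patient ClassMetrics.
    """
    df = results[results.method == method]
    view_pred, view_true = [], []
    per_tag = {}
    study_pred, study_true = {}, {}
    for view in sorted(df.view.unique()):
        sub = df[df.view == view]
        preds, trues = [], []
        for row in sub.itertuples():
            p = classify_view(row.ls, view, thresholds)
            t = bool(view_truth[row.study][view])
            preds.append(p)
            trues.append(t)
            study_pred.setdefault(row.study, []).append(p)
            study_true.setdefault(row.study, []).append(t)
        per_tag[view] = confusion_metrics(preds, trues)
        view_pred += preds
        view_true += trues
    studies = sorted(study_pred)
    patient = confusion_metrics(
        [classify_patient(study_pred[s]) for s in studies],
        [any(study_true[s]) for s in studies],
    )
    return {
        "per_view_tag": per_tag,
        "per_view": confusion_metrics(view_pred, view_true),
        "per_patient": patient,
    }


def truth_from_expert_labels(labels_by_study: dict,
                             segment_view_map: dict | None = None) -> dict:
    """{study: {reader: {segment: label}}} -> {study: {view: bool}}."""
    return {
        s: consensus_view_labels(readers, segment_view_map)[0]
        for s, readers in labels_by_study.items()
    }


def run_cohort(records, config: AnalysisConfig | None = None,
               view_truth: dict | None = None,
               thresholds: dict | None = None) -> dict:
    """Analyze a cohort and (when truth is given) fit and evaluate LS
    cutoffs.  Thresholds are fit on training records only; metrics are
    reported separately per cohort and per threshold mode."""
    config = config or AnalysisConfig()
    results = []
    for rec in records:
        _, rows = run_study(rec, config)
        if rec.analyzable:
            results.append(rows)
    if not results:
        raise ValueError("every study in the cohort failed; no report")
    df = pd.concat(results, ignore_index=True)
    report = {"results": df,
              "n_analyzable": sum(r.analyzable for r in records),
              "n_failed": sum(not r.analyzable for r in records)}
    if view_truth is None:
        return report
    roles = {r.study_id: r.role for r in records if r.analyzable}
    train_df = df[df.study.map(roles) == "train"]
    test_df = df[df.study.map(roles) == "test"]
    if thresholds is None:
        if train_df.empty:
            raise ValueError("threshold fitting requires training records")
        thresholds = fit_thresholds(train_df, view_truth,
                                    config.classify_method)
    report["thresholds"] = thresholds
    report["metrics"] = {}
    for name, sub in (("train", train_df), ("test", test_df)):
        if sub.empty:
            continue
        report["metrics"][name] = {
            "individual": evaluate_thresholds(
                sub, view_truth, thresholds["individual"],
                config.classify_method),
            "single": evaluate_thresholds(
                sub, view_truth, thresholds["single"],
                config.classify_method),
        }
    return report
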