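"""End-to-end orchestration: load -> grid -> features -> score -> ROC.

``run_pipeline`` executes the full chain on a directory tree laid out the
way :func:`hepatexture.phantom.generate_cohort` writes it (one DICOM
directory per patient, a contour sidecar, a labels CSV) and is equally
usable on real exported studies with manually drawn contours.  The run is
deterministic given (inputs, config): no stage draws random numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roc_stats
from .biomarker_models import BiomarkerModel, get_preset, score
from .estimators import (EstimatorContext, EstimatorVector, aggregate_patient,
                         compute_sample_estimators, REGISTRY_VERSION,
                         ESTIMATOR_IDS)
from .imaging_io import MRStudy, load_series
from .protocols import Protocol
from .roi_grid import (QCConfig, ROIContour, compute_sample_side,
                       extract_samples, qc_homogeneity, rasterize_contour,
                       robust_scale, DEFAULT_TARGET_VOLUME_MM3)

__all__ = ["RunConfig", "PatientFeatures", "extract_patient_features",
           "cohort_feature_table", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (always persisted)."""

    data_dir: str = ""
    contours: str = ""
    labels_csv: str = ""
    out_dir: str = ""
    model: str = "nashmri"          # preset name or path to a model JSON
    target_volume_mm3: tuple[float, float] = DEFAULT_TARGET_VOLUME_MM3
    qc_z_cut: float = 3.0
    qc_f_cut: float = 0.05
    n_levels: int = 16
    glcm_distance: int = 1
    normalize: bool = True          # feed window-normalised pixels
    seed: int = 0
    registry_version: str = REGISTRY_VERSION

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class PatientFeatures:
    patient_id: str
    aggregates: dict[Protocol, EstimatorVector]
    qc_counts: dict[str, int] = field(default_factory=dict)


def _normalise(slc, pixels: np.ndarray) -> np.ndarray:
    span = slc.window_max - slc.window_min
    return (pixels - slc.window_min) / span


def extract_patient_features(study: MRStudy,
                             contours: dict[tuple[str, str, int], ROIContour],
                             config: RunConfig | None = None) -> PatientFeatures:
    """Grid-sample every selected slice and aggregate the estimators.

    ``contours`` is keyed (patient, protocol, slice_index) as read by
    :func:`hepatexture.roi_grid.load_contours`.
    """
    cfg = config or RunConfig()
    qc_cfg = QCConfig(z_cut=cfg.qc_z_cut, f_cut=cfg.qc_f_cut)
    counts = {"samples": 0, "outside_30pct": 0, "inhomogeneous": 0,
              "passed": 0}
    aggregates: dict[Protocol, EstimatorVector] = {}
    for proto, slices in study.slices.items():
        if proto is Protocol.UNKNOWN:
            continue
        vectors = []
        for slc in study.protocol_slices(proto):
            key = (study.patient_id, str(proto), slc.slice_index)
            contour = contours.get(key)
            if contour is None:
                continue
            mask = rasterize_contour(contour, slc.rows, slc.cols)
            side = compute_sample_side(slc.fov_mm, slc.rows, slc.cols,
                                       slc.thickness_mm,
                                       cfg.target_volume_mm3)
            work = slc
            if cfg.normalize:
                work = dataclasses.replace(
                    slc, pixels=_normalise(slc, slc.pixels),
                    window_min=0.0, window_max=1.0)
            ctx = EstimatorContext.for_slice(
                work, normalized=cfg.normalize,
                n_levels=cfg.n_levels, distance=cfg.glcm_distance)
            slice_scale = robust_scale(work.pixels[mask]) if mask.any() else None
            for sample in extract_samples(work, mask, side):
                counts["samples"] += 1
                if not sample.qc_pass:
                    counts["outside_30pct"] += 1
                    continue
                sample = qc_homogeneity(sample, qc_cfg, scale=slice_scale)
                if not sample.qc_pass:
                    counts["inhomogeneous"] += 1
                    continue
                counts["passed"] += 1
                vectors.append(
                    compute_sample_estimators(sample, ctx, protocol=proto))
        if vectors:
            aggregates[proto] = aggregate_patient(vectors, proto)
    return PatientFeatures(patient_id=study.patient_id,
                           aggregates=aggregates, qc_counts=counts)


def cohort_feature_table(data_dir: str | os.PathLike,
                         contours: dict,
                         config: RunConfig | None = None
                         ) -> tuple[pd.DataFrame, list[PatientFeatures]]:
    """Aggregate feature table for every patient directory under data_dir.

    Columns are named ``"PROTOCOL:Eid"``; one row per patient.
    """
    cfg = config or RunConfig()
    data_dir = os.fspath(data_dir)
    rows = []
    feats: list[PatientFeatures] = []
    for name in sorted(os.listdir(data_dir)):
        pdir = os.path.join(data_dir, name)
        if not os.path.isdir(pdir):
            continue
        study = load_series(pdir)
        pf = extract_patient_features(study, contours, cfg)
        feats.append(pf)
        row: dict = {"patient_id": pf.patient_id}
        for proto, vec in pf.aggregates.items():
            for eid in ESTIMATOR_IDS:
                if eid in vec.values:
                    row[f"{proto}:{eid}"] = vec.values[eid]
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id"), feats


def _resolve_model(name_or_path: str) -> BiomarkerModel:
    if os.path.isfile(name_or_path):
        return BiomarkerModel.from_json(name_or_path)
    return get_preset(name_or_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write features/scores/ROC plus provenance.

    Outputs under ``config.out_dir``: ``features.csv``, ``scores.csv``,
    ``roc.json``, and ``run_config.json`` (resolved config, its hash,
    registry version and QC counts).  Returns the result bundle.
    """
    model = _resolve_model(config.model)  # fail before any computation
    from .roi_grid import load_contours
    contours = load_contours(config.contours)
    os.makedirs(config.out_dir, exist_ok=True)

    features, feats = cohort_feature_table(config.data_dir, contours, config)
    features.to_csv(os.path.join(config.out_dir, "features.csv"))

    score_rows = []
    for pf in feats:
        try:
            r = score(model, pf.aggregates, patient_id=pf.patient_id)
        except KeyError as exc:
            raise RuntimeError(
                f"scoring stage failed for {pf.patient_id}: {exc}") from exc
        score_rows.append({"patient_id": r.patient_id, "eta": r.eta,
                           "probability": r.probability,
                           "positive": r.positive})
    scores = pd.DataFrame(score_rows).set_index("patient_id")
    scores.to_csv(os.path.join(config.out_dir, "scores.csv"))

    bundle: dict = {"features": features, "scores": scores, "model": model}
    if config.labels_csv:
        labels = pd.read_csv(config.labels_csv).set_index("patient_id")
        joined = scores.join(labels, how="inner")
        roc = roc_stats.auroc_hanley(joined["probability"], joined["label"])
        metrics = roc_stats.threshold_metrics(
            joined["probability"], joined["label"], model.threshold)
        roc_doc = {
            "auroc": roc.auroc, "se": roc.se, "ci95": list(roc.ci95),
            "n_pos": roc.n_pos, "n_neg": roc.n_neg,
            "threshold": model.threshold,
            "sensitivity": metrics.sensitivity,
            "specificity": metrics.specificity,
            "ppv": metrics.ppv, "npv": metrics.npv,
        }
        with open(os.path.join(config.out_dir, "roc.json"), "w") as fh:
            json.dump(roc_doc, fh, indent=2)
        bundle["roc"] = roc
        bundle["threshold_metrics"] = metrics

    qc_total: dict[str, int] = {}
    for pf in feats:
        for k, v in pf.qc_counts.items():
            qc_total[k] = qc_total.get(k, 0) + v
    provenance = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash,
        "registry_version": config.registry_version,
        "qc_counts": qc_total,
        "n_patients": len(feats),
    }
    with open(os.path.join(config.out_dir, "run_config.json"), "w") as fh:
        json.dump(provenance, fh, indent=2)
    bundle["provenance"] = provenance
    return bundle
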