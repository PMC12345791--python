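"""End-to-end orchestration: simulate -> extract -> train -> predict -> evaluate.

Every stage reads/writes plain artifacts (HDF5 RF, CSV tables, JSON model
and report) so it can also be run independently via the CLI.  A single
global seed is fanned out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, making stages independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .evaluation import PerformanceReport, evaluate_predictions, group_ttests
from .qus_params import build_parametric_maps
from .response_model import (
    ResponseModel,
    predict_table,
    sequential_feature_selection,
    train_svm,
)
from .rf_synth import (
    ReferencePhantom,
    SyntheticCohortConfig,
    SyntheticPatient,
    iter_cohort,
    simulate_reference_phantom,
)
from .spectra import SpectralConfig
from .texture import (
    FEATURE_NAMES,
    GLCMConfig,
    QUSFeatureSet,
    assemble_features,
    delta_features,
)

logger = logging.getLogger(__name__)


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0]) for c in children]


def extract_patient_features(
    patient: SyntheticPatient,
    reference: ReferencePhantom,
    spectral: SpectralConfig,
    glcm: GLCMConfig,
) -> tuple[QUSFeatureSet, QUSFeatureSet, dict]:
    """Both timepoints of one patient through spectra -> maps -> features."""
    sets = []
    for week, scan in ((0, patient.rf_week0), (1, patient.rf_week1)):
        maps, _means, alpha = build_parametric_maps(
            scan, patient.roi_masks, spectral, reference
        )
        fs = assemble_features(patient.patient_id, week, maps, alpha.alpha, glcm)
        sets.append(fs)
    return sets[0], sets[1], {"true_label": patient.true_label}


def extract_cohort_features(
    patients: Iterable[SyntheticPatient],
    reference: ReferencePhantom,
    spectral: SpectralConfig,
    glcm: GLCMConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Feature tables (per week) and the delta table for a patient stream."""
    from .qus_params import prepare_reference

    if not hasattr(reference, "power_db"):
        reference = prepare_reference(reference, spectral)
    week_rows = []
    delta_rows = []
    labels = {}
    for p in patients:
        t0 = time.perf_counter()
        fs0, fs1, meta = extract_patient_features(p, reference, spectral, glcm)
        d = delta_features(fs0, fs1)
        for fs in (fs0, fs1):
            row = {"patient_id": fs.patient_id, "week": fs.week}
            row.update({k: fs.values[k] for k in FEATURE_NAMES})
            week_rows.append(row)
        drow = {"patient_id": d.patient_id}
        drow.update({k: d.values[k] for k in FEATURE_NAMES})
        delta_rows.append(drow)
        labels[p.patient_id] = meta["true_label"]
        logger.info(
            "extracted %s (%s) in %.2fs", p.patient_id, meta["true_label"], time.perf_counter() - t0
        )
    features = pd.DataFrame(week_rows)
    deltas = pd.DataFrame(delta_rows).set_index("patient_id")
    truth = pd.Series(labels, name="true_label")
    truth.index.name = "patient_id"
    return features, deltas, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PerformanceReport:
    """Run the full week-1 pipeline on synthetic cohorts; write all artifacts.

    Returns the validation-cohort performance report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    geometry = config.geometry.build()
    pulse = config.pulse.build()
    spectral = config.spectral.build()
    glcm = config.glcm.build()

    reference = simulate_reference_phantom(
        pulse,
        config.reference_attenuation,
        seeds[0],
        density_per_mm2=config.reference_density_per_mm2,
        depth_mm=geometry.depth_mm,
        n_lines=geometry.n_lines,
        line_pitch_mm=geometry.line_pitch_mm,
        n_frames=geometry.n_frames,
    )

    tables = {}
    for name, section, seed in (
        ("development", config.development, seeds[1]),
        ("validation", config.validation, seeds[2]),
    ):
        cohort_cfg = section.build(seed, geometry, pulse)
        logger.info("simulating + extracting %s cohort (n=%d)", name, cohort_cfg.n_patients)
        features, deltas, truth = extract_cohort_features(
            iter_cohort(cohort_cfg), reference, spectral, glcm
        )
        features.to_csv(out / f"{name}_features.csv", index=False)
        deltas.to_csv(out / f"{name}_deltas.csv")
        truth.to_csv(out / f"{name}_labels.csv")
        tables[name] = (deltas, truth)

    dev_deltas, dev_truth = tables["development"]
    selected = sequential_feature_selection(
        dev_deltas, config.model.n_features, dev_truth, seed=seeds[3],
        cv_folds=config.model.cv_folds, class_weight=config.model.class_weight,
    )
    logger.info("selected features: %s", selected)
    model = train_svm(
        dev_deltas,
        selected,
        dev_truth,
        seed=seeds[3],
        cv_folds=config.model.cv_folds,
        class_weight=config.model.class_weight,
        C_grid=config.model.C_grid,
        gamma_grid=config.model.gamma_grid,
        indeterminate_margin=config.model.indeterminate_margin,
    )
    model.save(out / "model.json")

    val_deltas, val_truth = tables["validation"]
    predictions = predict_table(model, val_deltas)
    predictions.to_csv(out / "predictions.csv")

    report = evaluate_predictions(predictions, val_truth, exclude=config.exclude)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out / "report.txt").write_text(report.to_text() + "\n")
    if report.roc_points is not None:
        pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / "roc_points.csv", index=False
        )
    ttests = group_ttests(val_deltas, val_truth)
    ttests.to_csv(out / "validation_ttests.csv")

    artifact_files = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "qusr_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_digest": config.digest(),
        "selected_features": selected,
        "files": {p.name: _sha256(p) for p in artifact_files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
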