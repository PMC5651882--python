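"""End-to-end orchestration, configuration and container I/O.

The pipeline runs: synthetic cohort (or on-disk manifest) -> per-frame
parametric maps -> per-plane texture features -> patient aggregation ->
group statistics, stepwise feature selection and LOPO k-NN classification.
All outputs are plain CSV/JSON; a run manifest records the config hash,
seed, package version and per-patient completion so identical config + seed
reproduce every numeric output bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (FEATURE_NAMES, build_feature_table, feature_stats,
                           knn_lopo, stepwise_lda)
from .maps import AnalysisConfig, build_parametric_maps, PARAMETER_IDS
from .synthetic_rf import (AcquisitionSpec, CohortSpec, Cohort, RFFrame,
                           default_cohort_spec, generate_cohort,
                           simulate_reference_set)
from .texture import map_features

__all__ = [
    "ClassifierConfig",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "cohort_features",
    "read_rf_container",
    "write_rf_container",
    "write_roi_mask",
    "read_roi_mask",
    "config_hash",
]


@dataclass(frozen=True)
class ClassifierConfig:
    k: int = 5
    select: str | None = "stepwise"
    select_per_fold: bool = False  # paper-style single global selection
    f_enter: float = 3.84
    f_remove: float = 2.71


@dataclass(frozen=True)
class PipelineConfig:
    """Full-pipeline configuration; analysis defaults match the published
    protocol (2 mm window, 94% overlap, 16 gray levels, distances 1-5 px,
    angles 0/45/90/135, 1 dB/MHz/cm intervening tissue)."""

    cohort: CohortSpec = field(default_factory=default_cohort_spec)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    texture_levels: int = 16
    texture_distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    texture_angles: tuple[int, ...] = (0, 45, 90, 135)
    seed: int = 0
    reference_seed_offset: int = 10_000

    def validate(self) -> None:
        if self.texture_levels < 2:
            raise ValueError("texture_levels must be >= 2")
        if self.classifier.k % 2 == 0:
            raise ValueError("classifier k must be odd")
        if not (0.0 <= self.analysis.overlap < 1.0):
            raise ValueError("window overlap must lie in [0, 1)")


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items() if not k.startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_to_jsonable(config), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    timings_s: dict[str, float]
    patient_status: dict[str, str]


# --------------------------------------------------------------------------
# feature extraction over a cohort
# --------------------------------------------------------------------------

def cohort_features(cohort: Cohort, refset, config: PipelineConfig
                    ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Long per-(patient, plane, parameter) feature table for a cohort.

    Failures are isolated per patient: a plane that cannot be analysed marks
    the patient 'failed' and the run continues.
    """
    rows = []
    status: dict[str, str] = {}
    for patient in cohort.patients:
        try:
            for plane_idx, (frame, roi) in enumerate(patient.planes):
                mapset = build_parametric_maps(frame, roi, refset, config.analysis)
                for pid in PARAMETER_IDS:
                    feats = map_features(
                        mapset.maps[pid], mapset.validity,
                        n_levels=config.texture_levels,
                        distances=config.texture_distances,
                        angles=config.texture_angles, parameter=pid)
                    rows.append({
                        "patient_id": patient.patient_id, "label": patient.label,
                        "plane": plane_idx, "parameter": pid,
                        "mean": feats.mean, "contrast": feats.contrast,
                        "correlation": feats.correlation, "energy": feats.energy,
                        "homogeneity": feats.homogeneity,
                        "n_glcms_averaged": feats.n_glcms_averaged,
                        "ace": mapset.ace.ACE,
                    })
            status[patient.patient_id] = "ok"
        except Exception as exc:  # noqa: BLE001 - per-patient isolation
            warnings.warn(f"patient {patient.patient_id} failed: {exc}", stacklevel=2)
            status[patient.patient_id] = f"failed: {exc}"
    return pd.DataFrame(rows), status


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Simulate, analyse and classify one cohort; optionally write outputs.

    Returns a dict with the feature tables, statistics, stepwise model and
    classification metrics, plus the run manifest.
    """
    config.validate()
    chash = config_hash(config)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    cohort_spec = config.cohort
    if cohort_spec.seed != config.seed:
        from dataclasses import replace

        cohort_spec = replace(cohort_spec, seed=config.seed)
    cohort = generate_cohort(cohort_spec)
    refset = simulate_reference_set(cohort_spec.acquisition,
                                    seed=config.seed + config.reference_seed_offset)
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    features_long, status = cohort_features(cohort, refset, config)
    timings["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = build_feature_table(features_long)
    stats = feature_stats(table)
    model = stepwise_lda(table, f_enter=config.classifier.f_enter,
                         f_remove=config.classifier.f_remove)
    result = knn_lopo(table, k=config.classifier.k,
                      select=config.classifier.select,
                      select_per_fold=config.classifier.select_per_fold,
                      f_enter=config.classifier.f_enter,
                      f_remove=config.classifier.f_remove)
    # sensitivity of the headline accuracy to the neighbourhood size
    k_sensitivity = {
        k: knn_lopo(table, k=k, select=config.classifier.select,
                    select_per_fold=config.classifier.select_per_fold,
                    f_enter=config.classifier.f_enter,
                    f_remove=config.classifier.f_remove).accuracy
        for k in (3, 5, 7) if k < len(table)
    }
    timings["classify"] = time.perf_counter() - t0

    manifest = RunManifest(chash, config.seed, __version__, timings, status)
    outputs = {
        "cohort": cohort,
        "features_long": features_long,
        "feature_table": table,
        "stats": stats,
        "stepwise": model,
        "classification": result,
        "k_sensitivity": k_sensitivity,
        "manifest": manifest,
    }
    if out_dir is not None:
        _write_outputs(outputs, Path(out_dir), chash)
    return outputs


def _write_outputs(outputs: dict, out_dir: Path, chash: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_cols = {"config_hash": chash}
    for name, df in (("features.csv", outputs["features_long"]),
                     ("feature_table.csv", outputs["feature_table"].reset_index()),
                     ("stats.csv", outputs["stats"].reset_index()),
                     ("predictions.csv", outputs["classification"].predictions.reset_index()),
                     ("roc.csv", outputs["classification"].roc)):
        df = df.copy()
        for k, v in meta_cols.items():
            df[k] = v
        df.to_csv(out_dir / name, index=False)
    res = outputs["classification"]
    metrics = {"sensitivity_pct": res.sensitivity, "specificity_pct": res.specificity,
               "accuracy_pct": res.accuracy, "auc": res.auc,
               "accuracy_by_k": {str(k): v for k, v in
                                 outputs.get("k_sensitivity", {}).items()},
               "config_hash": chash}
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    model = outputs["stepwise"]
    (out_dir / "model.json").write_text(json.dumps({
        "selected": model.selected,
        "standardized_coefficients": model.coefficients.to_dict(),
        "steps": model.steps, "config_hash": chash}, indent=2))
    mani = outputs["manifest"]
    (out_dir / "manifest.json").write_text(json.dumps(_to_jsonable(asdict(mani)), indent=2))
    outputs["cohort"].ground_truth.assign(config_hash=chash).to_csv(
        out_dir / "ground_truth.csv", index=False)


# --------------------------------------------------------------------------
# RF container I/O
# --------------------------------------------------------------------------

_REQUIRED_SIDECAR = ("sampling_rate_hz", "line_pitch_m", "c_mps",
                     "centre_frequency_hz", "shape", "dtype")


def write_rf_container(frame: RFFrame, path: str | Path) -> None:
    """Raw axial-major binary samples plus a JSON metadata sidecar."""
    path = Path(path)
    acq = frame.acquisition
    samples = np.ascontiguousarray(frame.samples)
    samples.tofile(path)
    sidecar = {
        "sampling_rate_hz": acq.sampling_rate * 1e6,
        "line_pitch_m": acq.line_pitch_mm * 1e-3,
        "c_mps": acq.speed_of_sound,
        "centre_frequency_hz": acq.centre_frequency * 1e6,
        "plane_offset_mm": frame.plane_offset_mm,
        "depth_cm": acq.depth,
        "lateral_fov_cm": acq.lateral_fov,
        "pulse_bandwidth_frac": acq.pulse_bandwidth_frac,
        "beam_width_mm": acq.beam_width,
        "shape": list(samples.shape),
        "dtype": str(samples.dtype),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_rf_container(path: str | Path) -> RFFrame:
    """Lossless inverse of :func:`write_rf_container`.

    Missing required sidecar fields refuse by name; truncated sample files
    raise an integrity error naming the failing byte offset.  Unknown extra
    sidecar keys are preserved (forward compatibility) with a warning.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text())
    for key in _REQUIRED_SIDECAR:
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} missing required field '{key}'")
    extra = set(meta) - set(_REQUIRED_SIDECAR) - {
        "plane_offset_mm", "depth_cm", "lateral_fov_cm",
        "pulse_bandwidth_frac", "beam_width_mm"}
    if extra:
        warnings.warn(f"sidecar has unknown keys (preserved): {sorted(extra)}",
                      stacklevel=2)
    shape = tuple(meta["shape"])
    dtype = np.dtype(meta["dtype"])
    expected = int(np.prod(shape)) * dtype.itemsize
    actual = path.stat().st_size
    if actual < expected:
        raise IOError(
            f"truncated RF container {path}: expected {expected} bytes, "
            f"file ends at byte offset {actual}")
    samples = np.fromfile(path, dtype=dtype, count=int(np.prod(shape))).reshape(shape)
    acq = AcquisitionSpec(
        centre_frequency=meta["centre_frequency_hz"] / 1e6,
        sampling_rate=meta["sampling_rate_hz"] / 1e6,
        num_lines=shape[1],
        lateral_fov=meta.get("lateral_fov_cm",
                             shape[1] * meta["line_pitch_m"] * 100.0),
        depth=meta.get("depth_cm",
                       shape[0] * meta["c_mps"] / (2 * meta["sampling_rate_hz"]) * 100.0),
        speed_of_sound=meta["c_mps"],
        pulse_bandwidth_frac=meta.get("pulse_bandwidth_frac", 0.6),
        beam_width=meta.get("beam_width_mm", 0.7),
    )
    return RFFrame(samples, acq, meta.get("plane_offset_mm", 0.0))


def write_roi_mask(mask: np.ndarray, path: str | Path) -> None:
    """Run-length JSON encoding of a binary ROI mask."""
    mask = np.asarray(mask, dtype=bool)
    runs = []
    for r in range(mask.shape[0]):
        row = mask[r]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            runs.append([int(r), int(start), int(stop - start)])
    Path(path).write_text(json.dumps({"shape": list(mask.shape), "runs": runs}))


def read_roi_mask(path: str | Path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    mask = np.zeros(tuple(data["shape"]), dtype=bool)
    for r, start, length in data["runs"]:
        mask[r, start:start + length] = True
    return mask


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file of overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    from dataclasses import replace

    cfg = PipelineConfig()
    cohort = cfg.cohort
    if "cohort" in raw:
        c = raw["cohort"]
        cohort = default_cohort_spec(
            n_patients_per_class=c.get("n_patients_per_class", cohort.n_patients_per_class),
            planes_per_patient=c.get("planes_per_patient", cohort.planes_per_patient),
            seed=c.get("seed", cohort.seed))
    analysis = replace(cfg.analysis, **{
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in raw.get("analysis", {}).items()})
    classifier = replace(cfg.classifier, **raw.get("classifier", {}))
    return replace(cfg, cohort=cohort, analysis=analysis, classifier=classifier,
                   seed=raw.get("seed", cfg.seed))
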