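"""End-to-end pipeline: volume -> MSP -> ROI -> 4 segmentations -> report.

Reads a NIfTI volume, detects the midsagittal plane, crops the brainstem
ROI, runs the four task networks (midbrain/pons x area/ellipse), measures
areas and diameters, and writes all artifacts (MSP image, ROI, masks,
JSON report, resolved configuration) atomically to an output directory.
Empty predicted masks are recorded as flagged failures, never raised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import PlaneParams
from .msp_detect import MspConfig, MspDetectionError, detect
from .phantom import PhantomVolume
from .planimetry import PlanimetricReport, measure
from .segnet import TASKS, UNet, load_model, predict

__all__ = [
    "PipelineConfig", "RunRecord", "PipelineInputError", "ModelMissingError",
    "load_config", "run_pipeline", "batch",
    "save_volume_nifti", "load_volume_nifti",
]

log = logging.getLogger("planistem")


class PipelineInputError(RuntimeError):
    """The input volume is unreadable or invalid."""


class ModelMissingError(RuntimeError):
    """A required model weight file cannot be loaded."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    msp: MspConfig = field(default_factory=MspConfig)
    model_paths: dict = field(default_factory=dict)  # task -> weights path
    threshold: float = 0.5
    output_dir: str = "planistem_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        missing = [t for t in TASKS if t not in self.model_paths]
        if missing:
            raise ModelMissingError(f"no model path for tasks: {missing}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides
                ) -> PipelineConfig:
    """Build a configuration from a YAML file with full defaulting."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    msp_kwargs = raw.pop("msp", {}) or {}
    if "slice_fractions" in msp_kwargs:
        msp_kwargs["slice_fractions"] = tuple(msp_kwargs["slice_fractions"])
    if "roi_origin" in msp_kwargs:
        msp_kwargs["roi_origin"] = tuple(msp_kwargs["roi_origin"])
    cfg = PipelineConfig(msp=MspConfig(**msp_kwargs), **raw)
    return cfg


@dataclass
class RunRecord:
    """Everything produced by one pipeline run, for audit and batching."""

    input_id: str
    plane: PlaneParams | None
    report: PlanimetricReport | None
    timings: dict
    failures: dict
    config_digest: str
    seed: int

    def as_dict(self) -> dict:
        flat = {
            "input_id": self.input_id,
            "config_digest": self.config_digest,
            "seed": self.seed,
            "failures": "; ".join(f"{k}: {v}"
                                  for k, v in self.failures.items()),
        }
        if self.plane is not None:
            flat.update({"yaw_deg": self.plane.yaw,
                         "roll_deg": self.plane.roll,
                         "distance_px": self.plane.distance})
        if self.report is not None:
            flat.update({
                "midbrain_area_mm2": self.report.midbrain_area,
                "pons_area_mm2": self.report.pons_area,
                "midbrain_diameter_mm": self.report.midbrain_diameter,
                "pons_diameter_mm": self.report.pons_diameter,
            })
        flat.update({f"t_{k}_s": round(v, 4)
                     for k, v in self.timings.items()})
        return flat


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume_nifti(path: str | Path, phantom: PhantomVolume) -> None:
    """Write a phantom volume as NIfTI with spacing in the header."""
    affine = np.diag(list(phantom.voxel_spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(phantom.intensities, dtype=np.float32),
                          affine)
    img.header.set_zooms(phantom.voxel_spacing)
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path
                      ) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise PipelineInputError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # nibabel raises many concrete types
        raise PipelineInputError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 3 or min(data.shape) < 10 or not np.isfinite(data).all():
        raise PipelineInputError(f"{path} is not a valid 3D volume")
    return data, zooms


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _save_image_npy(path: Path, arr: np.ndarray) -> None:
    _atomic_write(path, lambda p: np.save(p, arr, allow_pickle=False))


def _load_models(config: PipelineConfig) -> dict[str, UNet]:
    models = {}
    for task in TASKS:
        p = Path(config.model_paths[task])
        try:
            models[task] = load_model(p)
        except (OSError, KeyError, json.JSONDecodeError) as exc:
            raise ModelMissingError(
                f"cannot load weights for task {task!r} from {p}: {exc}"
            ) from exc
    return models


# ---------------------------------------------------------------------------
# run / batch
# ---------------------------------------------------------------------------

def run_pipeline(volume_path: str | Path, config: PipelineConfig,
                 models: dict[str, UNet] | None = None) -> RunRecord:
    """Execute the full measurement chain on one volume.

    Writes, under ``config.output_dir/<stem>/``: the MSP image and ROI
    (as .npy), the four predicted masks, the planimetric report and the
    resolved configuration.  All files appear atomically.  Empty
    predicted masks propagate as flagged failures in the report.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    volume_path = Path(volume_path)
    input_id = volume_path.name.removesuffix(".gz").removesuffix(".nii")
    out = Path(config.output_dir) / input_id
    timings: dict[str, float] = {}
    failures: dict[str, str] = {}

    t0 = time.perf_counter()
    volume, spacing = load_volume_nifti(volume_path)
    timings["load"] = time.perf_counter() - t0
    log.info("loaded %s shape=%s spacing=%s", input_id, volume.shape,
             spacing)

    t0 = time.perf_counter()
    plane, msp, roi = detect(volume, config.msp, voxel_spacing=spacing)
    timings["msp_detect"] = time.perf_counter() - t0
    log.info("MSP yaw=%.2f roll=%.2f distance=%.2f", plane.yaw, plane.roll,
             plane.distance)

    if models is None:
        models = _load_models(config)
    t0 = time.perf_counter()
    masks = {}
    for task in TASKS:
        _, masks[task] = predict(models[task], roi.intensities,
                                 threshold=config.threshold)
        if not masks[task].any():
            failures[task] = "empty predicted mask"
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    report = measure(masks, roi.pixel_spacing,
                     provenance={"models": {t: str(config.model_paths[t])
                                            for t in TASKS},
                                 "plane": plane.as_dict()})
    timings["measure"] = time.perf_counter() - t0

    record = RunRecord(input_id=input_id, plane=plane, report=report,
                       timings=timings, failures=failures,
                       config_digest=config.digest(), seed=config.seed)

    _save_image_npy(out / "msp.npy", msp.intensities.astype(np.float32))
    _save_image_npy(out / "roi.npy", roi.intensities.astype(np.float32))
    for task in TASKS:
        _save_image_npy(out / f"mask_{task}.npy",
                        masks[task].astype(np.uint8))
    _atomic_write(out / "report.json", lambda p: p.write_text(
        json.dumps({"record": record.as_dict(),
                    "report": report.as_dict()}, indent=2)))
    _atomic_write(out / "config.yaml", lambda p: p.write_text(
        yaml.safe_dump(config.as_dict(), default_flow_style=False)))
    return record


def batch(inputs, config: PipelineConfig) -> pd.DataFrame:
    """Run the pipeline over many volumes; failures never stop the batch.

    Returns one row per input; rows for failed inputs carry the error
    message in the ``failures`` column.
    """
    if not inputs:
        raise ValueError("batch needs at least one input")
    config.validate()
    models = _load_models(config)
    rows = []
    for path in inputs:
        try:
            rec = run_pipeline(path, config, models=models)
            rows.append(rec.as_dict())
        except (PipelineInputError, MspDetectionError,
                ModelMissingError) as exc:
            log.error("failed on %s: %s", path, exc)
            rows.append({"input_id": Path(path).name,
                         "config_digest": config.digest(),
                         "seed": config.seed,
                         "failures": f"{type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)
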