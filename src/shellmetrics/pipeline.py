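"""End-to-end measurement run: image in, morphometric record out.

Chains the stages -- color-model segmentation, morphological cleanup,
contour analysis (keeping the largest component), moment-based pose,
standardization, bounding-box morphometry, optional mass prediction -- and
writes every intermediate artifact (mask, contours, pose, standardized
image/mask, record) before the next stage runs, so a failed run can be
inspected stage by stage.  Runs are deterministic: no hidden state, no
unseeded randomness.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .contours import extract_contours, fill_contours, select_primary_contour
from .errors import InputError, MissingFieldError, ShellmetricsError
from .mass_model import MassModel, predict_mass
from .morphometry import (
    MorphometricRecord,
    calibrate_scale,
    convert_length,
    measure_extents,
    write_records_csv,
)
from .pose import Pose, estimate_pose, standardize
from .segmentation import FOREGROUND, ColorModelParams, segment_animal

log = logging.getLogger("shellmetrics.pipeline")


class NoAnimalFoundError(ShellmetricsError):
    """Segmentation produced no foreground."""


class StageError(ShellmetricsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration of one measurement run.

    ``view`` names which shell face the photograph shows: ``"carapace"``
    (dorsal; fills LC/WC) or ``"plastron"`` (ventral; fills LP/WP, and LF
    from the full silhouette since the plastron view includes the tail
    base).  Separating the plastron proper from the full ventral silhouette
    requires external part detections, supplied via
    :func:`shellmetrics.morphometry.measure_record` instead.
    """

    cr: float = -1.0
    cg: float = -1.0
    cb: float = 2.0
    thresh: float = 70.0
    close_kernel: int = 5
    scale_mm: float = 60.0  # reference object real length
    scale_px: float = 120.0  # reference object pixel length
    view: str = "carapace"
    model_path: str | None = None
    out_dir: str = "."
    log_level: str = "INFO"

    def color_params(self) -> ColorModelParams:
        return ColorModelParams(cr=self.cr, cg=self.cg, cb=self.cb, thresh=self.thresh)

    _FLOAT_KEYS = ("cr", "cg", "cb", "thresh", "scale_mm", "scale_px")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Read a plain ``key = value`` text file; overrides win."""
        cfg = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"malformed config line: {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            cfg[k] = v
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        known = set(cls.__dataclass_fields__)
        unknown = set(cfg) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for k in list(cfg):
            if k in cls._FLOAT_KEYS:
                cfg[k] = float(cfg[k])
            elif k == "close_kernel":
                cfg[k] = int(cfg[k])
        return cls(**cfg)


def _timed(stage, fn):
    t0 = time.perf_counter()
    try:
        result = fn()
    except ShellmetricsError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, exc) from exc
    log.info("STAGE %s done in %.3fs", stage, time.perf_counter() - t0)
    return result


def run_measure(image_path, config: PipelineConfig) -> tuple[Pose, MorphometricRecord, dict]:
    """Measure one image; returns (pose, record, artifact paths)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = Path(image_path).stem
    artifacts: dict[str, str] = {}

    image = iio.imread(image_path)
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[..., :3]

    mask = _timed("segment", lambda: segment_animal(image, config.color_params(), config.close_kernel))
    if not (mask == FOREGROUND).any():
        raise NoAnimalFoundError(f"no animal found in {image_path}")
    p = out / f"{stem}_mask.png"
    iio.imwrite(p, mask)
    artifacts["mask"] = str(p)
    log.info("STAGE segment area=%d", int((mask == FOREGROUND).sum()))

    contours = _timed("contours", lambda: extract_contours(mask))
    p = out / f"{stem}_contours.json"
    p.write_text(json.dumps([c.to_dict() for c in contours]))
    artifacts["contours"] = str(p)

    def _clean():
        primary = select_primary_contour(contours)
        keep = [primary] + [c for c in contours if c.kind == "hole" and c.parent_nbd == primary.nbd]
        return fill_contours(keep, mask.shape)

    clean_mask = _timed("primary-component", _clean)

    pose = _timed("pose", lambda: estimate_pose(clean_mask))
    p = out / f"{stem}_pose.json"
    p.write_text(pose.to_json())
    artifacts["pose"] = str(p)
    log.info("STAGE pose theta=%.2f heading=%.2f", pose.theta, pose.heading)

    def _std():
        return standardize(image, clean_mask, pose)

    std_image, std_mask, record_affine = _timed("standardize", _std)
    p_img = out / f"{stem}_std.png"
    p_msk = out / f"{stem}_std_mask.png"
    iio.imwrite(p_img, std_image)
    iio.imwrite(p_msk, std_mask)
    artifacts["std_image"], artifacts["std_mask"] = str(p_img), str(p_msk)

    def _measure():
        cal = calibrate_scale(config.scale_mm, config.scale_px)
        length_px, width_px = measure_extents(std_mask)
        L = convert_length(length_px, cal)
        W = convert_length(width_px, cal)
        if config.view == "carapace":
            return MorphometricRecord(id=stem, LC=L, WC=W)
        if config.view == "plastron":
            return MorphometricRecord(id=stem, LP=L, WP=W, LF=L)
        raise InputError(f"unknown view {config.view!r}")

    record = _timed("morphometry", _measure)
    p = out / f"{stem}_record.csv"
    write_records_csv([record], p)
    artifacts["record"] = str(p)
    log.info(
        "STAGE morphometry lengths=%s",
        {k: getattr(record, k) for k in ("LC", "WC", "LF", "LP", "WP") if getattr(record, k)},
    )
    return pose, record, artifacts


def run_predict(image_path, config: PipelineConfig, model: MassModel) -> float:
    """Measure an image and predict mass with a fitted model (grams)."""
    _, record, _ = run_measure(image_path, config)
    missing = [p for p in model.predictors if getattr(record, p) is None]
    if missing:
        raise MissingFieldError(missing)
    mass = predict_mass(model, record)
    log.info("STAGE predict mass=%.1f g", mass)
    return mass
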