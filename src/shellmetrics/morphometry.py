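"""Pixel-to-millimetre conversion and morphometric parameter extraction.

A reference object of known physical length ``Lb`` (mm) spanning ``Lbp``
pixels in the image gives the scale factor ``s = Lb / Lbp`` (mm/pixel);
any pixel length then converts as ``L = s * Lp``.  A single isotropic
factor assumes the camera plane is parallel to the measurement board.

Five standard shell parameters are measured for the Chinese softshell
turtle: carapace length/width (LC, WC) from the dorsal view, plastron
length/width (LP, WP) and plastron full length LF (plastron front edge to
tail base) from the ventral view.  Lengths run along the standardized body
axis (columns), widths across it (rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError, ParameterError
from .segmentation import FOREGROUND, _check_mask

LENGTH_FIELDS = ("LC", "WC", "LF", "LP", "WP")

CSV_HEADER = ["id", "LC_mm", "WC_mm", "LF_mm", "LP_mm", "WP_mm", "mass_g"]


@dataclass(frozen=True)
class ScaleCalibration:
    """mm-per-pixel scale from a reference object of known length."""

    lb_mm: float
    lbp_px: float

    def __post_init__(self):
        if self.lb_mm <= 0 or self.lbp_px <= 0:
            raise ParameterError("calibration lengths must be positive")

    @property
    def s(self) -> float:
        """Scale factor in mm/pixel."""
        return self.lb_mm / self.lbp_px


def calibrate_scale(lb_mm: float, lbp_px: float) -> ScaleCalibration:
    """Build a calibration; ``s = lb_mm / lbp_px``."""
    return ScaleCalibration(lb_mm=float(lb_mm), lbp_px=float(lbp_px))


def convert_length(lp_px: float, cal: ScaleCalibration) -> float:
    """Convert a pixel length to millimetres: ``L = s * Lp``."""
    if lp_px < 0:
        raise InputError(f"pixel length must be >= 0, got {lp_px}")
    return cal.s * lp_px


@dataclass
class MorphometricRecord:
    """One animal's shell measurements in mm and (optionally) mass in g."""

    LC: Optional[float] = None
    WC: Optional[float] = None
    LF: Optional[float] = None
    LP: Optional[float] = None
    WP: Optional[float] = None
    mass: Optional[float] = None
    id: Optional[str] = None

    def __post_init__(self):
        for f in LENGTH_FIELDS:
            v = getattr(self, f)
            if v is not None and v <= 0:
                raise InputError(f"{f} must be positive, got {v}")
        if self.WC is not None and self.LC is not None and self.WC > self.LC:
            warnings.warn("WC exceeds LC: unusual for this species", stacklevel=2)
        if self.WP is not None and self.LP is not None and self.WP > self.LP:
            warnings.warn("WP exceeds LP: unusual for this species", stacklevel=2)

    def missing_fields(self) -> tuple[str, ...]:
        return tuple(f for f in LENGTH_FIELDS if getattr(self, f) is None)


def measure_extents(standardized_mask) -> tuple[int, int]:
    """Bounding-box extents (length_px, width_px) of a standardized mask.

    Length is the column extent (along the body axis after standardization),
    width the row extent.  Warns if the mask does not look standardized
    (residual orientation above 2 degrees).
    """
    arr = _check_mask(standardized_mask)
    rows, cols = np.nonzero(arr == FOREGROUND)
    if rows.size == 0:
        raise DegenerateInputError("mask has no foreground pixels")
    from .pose import compute_moments, orientation_from_moments

    if rows.size > 1:
        theta = orientation_from_moments(compute_moments(arr))
        if min(theta, 180.0 - theta) > 2.0:
            warnings.warn(
                f"mask orientation {theta:.1f} deg: not standardized?", stacklevel=2
            )
    length = int(cols.max() - cols.min() + 1)
    width = int(rows.max() - rows.min() + 1)
    return length, width


def _region_extents(region) -> tuple[float, float]:
    """Extents of a region given as a mask or an (x1, y1, x2, y2) box."""
    if isinstance(region, (tuple, list)) and len(region) == 4:
        x1, y1, x2, y2 = map(float, region)
        if x2 < x1 or y2 < y1:
            raise InputError(f"invalid box {region}")
        return x2 - x1, y2 - y1
    length, width = measure_extents(region)
    if length <= 1 and width <= 1:
        raise DegenerateInputError("region is a single pixel")
    return float(length), float(width)


def measure_record(regions: dict, cal: ScaleCalibration, record_id: str | None = None) -> MorphometricRecord:
    """Build a morphometric record from labelled part regions.

    ``regions`` maps part names to either a standardized binary mask or an
    axis-aligned box ``(x1, y1, x2, y2)`` in pixels:

    - ``"carapace"``  -> LC (length extent), WC (width extent)
    - ``"plastron"``  -> LP, WP
    - ``"ventral_full"`` -> LF (length extent from plastron front to tail
      base); without it LF is left missing.

    Parts that are absent leave their fields missing (reported by
    :meth:`MorphometricRecord.missing_fields`); mass is never filled here.
    """
    values: dict[str, float] = {}
    if "carapace" in regions:
        lp, wp = _region_extents(regions["carapace"])
        values["LC"] = convert_length(lp, cal)
        values["WC"] = convert_length(wp, cal)
    if "plastron" in regions:
        lp, wp = _region_extents(regions["plastron"])
        values["LP"] = convert_length(lp, cal)
        values["WP"] = convert_length(wp, cal)
    if "ventral_full" in regions:
        lp, _ = _region_extents(regions["ventral_full"])
        values["LF"] = convert_length(lp, cal)
    return MorphometricRecord(id=record_id, **values)


def records_to_frame(records: list[MorphometricRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the canonical CSV columns."""
    rows = []
    for k, r in enumerate(records):
        rows.append(
            {
                "id": r.id if r.id is not None else str(k),
                "LC_mm": r.LC,
                "WC_mm": r.WC,
                "LF_mm": r.LF,
                "LP_mm": r.LP,
                "WP_mm": r.WP,
                "mass_g": r.mass,
            }
        )
    return pd.DataFrame(rows, columns=CSV_HEADER)


def frame_to_records(df: pd.DataFrame) -> list[MorphometricRecord]:
    records = []
    for _, row in df.iterrows():
        def val(col):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        records.append(
            MorphometricRecord(
                id=None if pd.isna(row.get("id")) else str(row.get("id")),
                LC=val("LC_mm"),
                WC=val("WC_mm"),
                LF=val("LF_mm"),
                LP=val("LP_mm"),
                WP=val("WP_mm"),
                mass=val("mass_g"),
            )
        )
    return records


def write_records_csv(records: list[MorphometricRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[MorphometricRecord]:
    return frame_to_records(pd.read_csv(path))
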