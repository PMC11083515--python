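"""Pose estimation from image moments, and rotation to the standard state.

The segmented animal's position and orientation are recovered from the raw
moments of its binary mask,

    M00 = sum V,   M10 = sum x*V,  M01 = sum y*V,
    M20 = sum x^2*V,  M02 = sum y^2*V,  M11 = sum x*y*V,

with V = 1 on the foreground.  The centroid is (xc, yc) = (M10/M00,
M01/M00), and the body-axis angle follows from the normalized central
second moments a = M20/M00 - xc^2, b = M11/M00 - xc*yc, c = M02/M00 - yc^2
as theta = atan2(2b, a - c) / 2.

Coordinate convention, used everywhere in this package: x = column,
y = row; angles are measured counterclockwise from the +x axis in a y-UP
sense (so they read like standard math angles when the image is displayed),
which in (row, col) index space means b is negated before the atan2.

``theta`` in [0, 180) is the undirected axis angle.  The directed
``heading`` in [0, 360) is defined so that heading 0 is the standard state
-- body axis horizontal, head pointing LEFT -- and a phantom generated at
heading h needs a rotation by -h to return to standard.  The 180-degree
ambiguity is resolved by the sign of the third central moment of the
foreground projected on the body axis: the head end (a compact protrusion
beyond the shell rim) skews the projection distribution toward itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, InputError
from .segmentation import BACKGROUND, FOREGROUND, _check_mask

#: relative tolerance below which a shape is treated as isotropic (theta = 0)
ISOTROPY_RTOL = 1e-9


@dataclass(frozen=True)
class MomentSet:
    """Raw moments up to order 2 and normalized central second moments."""

    m00: float
    m10: float
    m01: float
    m20: float
    m02: float
    m11: float
    a: float
    b: float
    c: float

    @property
    def xc(self) -> float:
        return self.m10 / self.m00

    @property
    def yc(self) -> float:
        return self.m01 / self.m00


@dataclass(frozen=True)
class Pose:
    """Centroid and orientation of the segmented animal.

    ``xc``/``yc`` are the centroid column/row in pixels; ``theta`` is the
    undirected axis angle in [0, 180) degrees; ``heading`` in [0, 360)
    degrees is 0 when the animal is in the standard state (head left).
    ``low_confidence`` flags headings derived from a near-symmetric mask.
    """

    xc: float
    yc: float
    theta: float
    heading: float
    low_confidence: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "xc": self.xc,
                "yc": self.yc,
                "theta_deg": self.theta,
                "heading_deg": self.heading,
                "low_confidence": self.low_confidence,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "Pose":
        d = json.loads(s)
        return cls(
            xc=d["xc"],
            yc=d["yc"],
            theta=d["theta_deg"],
            heading=d["heading_deg"],
            low_confidence=bool(d.get("low_confidence", False)),
        )


def _foreground_xy(mask) -> tuple[np.ndarray, np.ndarray]:
    arr = _check_mask(mask)
    rows, cols = np.nonzero(arr == FOREGROUND)
    if rows.size == 0:
        raise DegenerateInputError("mask has no foreground pixels")
    return cols.astype(np.float64), rows.astype(np.float64)


def compute_moments(mask) -> MomentSet:
    """Raw and normalized central moments of a binary mask (255 -> weight 1)."""
    x, y = _foreground_xy(mask)
    m00 = float(x.size)
    m10 = float(x.sum())
    m01 = float(y.sum())
    m20 = float((x * x).sum())
    m02 = float((y * y).sum())
    m11 = float((x * y).sum())
    xc, yc = m10 / m00, m01 / m00
    return MomentSet(
        m00=m00,
        m10=m10,
        m01=m01,
        m20=m20,
        m02=m02,
        m11=m11,
        a=m20 / m00 - xc * xc,
        b=m11 / m00 - xc * yc,
        c=m02 / m00 - yc * yc,
    )


def moments_from_points(points) -> MomentSet:
    """Moments of a list of (row, col) points, e.g. traced contour pixels."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        raise DegenerateInputError("empty point set")
    y, x = pts[:, 0], pts[:, 1]
    m00 = float(len(pts))
    xc, yc = float(x.mean()), float(y.mean())
    return MomentSet(
        m00=m00,
        m10=float(x.sum()),
        m01=float(y.sum()),
        m20=float((x * x).sum()),
        m02=float((y * y).sum()),
        m11=float((x * y).sum()),
        a=float((x * x).mean()) - xc * xc,
        b=float((x * y).mean()) - xc * yc,
        c=float((y * y).mean()) - yc * yc,
    )


def orientation_from_moments(m: MomentSet) -> float:
    """Body-axis angle in degrees, in [0, 180), y-up counterclockwise."""
    if m.m00 <= 0:
        raise DegenerateInputError("moments from an empty mask")
    # y-up sense: row increases downward, so the cross moment flips sign
    b_up = -m.b
    if abs(m.a - m.c) < ISOTROPY_RTOL * (m.a + m.c + 1e-30) and abs(
        2 * b_up
    ) < ISOTROPY_RTOL * (m.a + m.c + 1e-30):
        return 0.0
    theta = 0.5 * math.degrees(math.atan2(2 * b_up, m.a - m.c))
    return theta % 180.0


def resolve_heading(mask, m: MomentSet | None = None, theta: float | None = None):
    """Directed heading in [0, 360) from the axis angle and mask asymmetry.

    Projects the foreground onto the body axis (y-up unit vector at angle
    ``theta``) and uses the sign of the third central moment of the
    projections: the head-side protrusion skews mass toward the head, so a
    positive skew places the head along +theta.  Heading 0 means head left.

    Returns ``(heading_deg, low_confidence)``; ``low_confidence`` is set
    when the skew is numerically negligible (symmetric shape), in which
    case ``theta`` itself is returned as the heading.
    """
    if m is None:
        m = compute_moments(mask)
    if theta is None:
        theta = orientation_from_moments(m)
    x, y = _foreground_xy(mask)
    y_up = -y
    ux, uy = math.cos(math.radians(theta)), math.sin(math.radians(theta))
    proj = (x - m.xc) * ux + (y_up - (-m.yc)) * uy
    mu2 = float((proj**2).mean())
    mu3 = float((proj**3).mean())
    scale = mu2**1.5 + 1e-30
    skew = mu3 / scale
    if abs(skew) < 1e-6:
        return theta % 360.0, True
    if skew > 0:
        # head lies along +theta; standard state has the head at 180 degrees
        heading = (theta - 180.0) % 360.0
    else:
        heading = theta % 360.0
    return heading, False


def estimate_pose(mask, source: str = "mask") -> Pose:
    """Centroid + orientation + heading of a segmented mask.

    ``source="mask"`` computes moments over the filled foreground (default);
    ``source="contour"`` uses only the traced boundary pixels.
    """
    if source == "mask":
        m = compute_moments(mask)
    elif source == "contour":
        from .contours import extract_contours, select_primary_contour

        c = select_primary_contour(extract_contours(mask))
        m = moments_from_points(c.points)
    else:
        raise InputError(f"unknown moment source {source!r}")
    theta = orientation_from_moments(m)
    heading, low_conf = resolve_heading(mask, compute_moments(mask), theta)
    return Pose(xc=m.xc, yc=m.yc, theta=theta, heading=heading, low_confidence=low_conf)


@dataclass(frozen=True)
class AffineRecord:
    """Forward map ``(row', col') = A @ (row, col) + t`` applied by standardize."""

    matrix: tuple
    offset: tuple

    def apply(self, point_rc) -> tuple[float, float]:
        A = np.asarray(self.matrix)
        t = np.asarray(self.offset)
        p = A @ np.asarray(point_rc, dtype=float) + t
        return float(p[0]), float(p[1])

    def to_dict(self) -> dict:
        return asdict(self)


def standardize(image, mask, pose: Pose, background_rgb=(0, 0, 0)):
    """Rotate image and mask about the centroid into the standard state.

    Rotates by ``-pose.heading`` (counterclockwise, y-up) so the body axis
    becomes horizontal with the head at lower column indices.  The output
    canvas is sized to contain the whole rotated frame.  The image is
    resampled bilinearly, the mask with nearest-neighbor; uncovered canvas
    is filled with ``background_rgb`` (image) / background (mask).

    Returns ``(std_image, std_mask, record)`` where ``record`` is the
    forward affine map in (row, col) coordinates.
    """
    arr = np.asarray(image)
    msk = _check_mask(mask)
    if not (msk == FOREGROUND).any():
        raise DegenerateInputError("cannot standardize an empty mask")
    if arr.shape[:2] != msk.shape:
        raise InputError("image and mask shapes differ")

    h = math.radians(pose.heading)
    # content rotation by -heading (y-up CCW) expressed in (row, col) space
    A = np.array([[math.cos(h), math.sin(h)], [-math.sin(h), math.cos(h)]])
    c = np.array([pose.yc, pose.xc])

    H, W = msk.shape
    corners = np.array([[0.0, 0.0], [0.0, W - 1.0], [H - 1.0, 0.0], [H - 1.0, W - 1.0]])
    rotated = (corners - c) @ A.T + c
    lo = np.floor(rotated.min(axis=0))
    hi = np.ceil(rotated.max(axis=0))
    out_shape = (int(hi[0] - lo[0]) + 1, int(hi[1] - lo[1]) + 1)
    t = c - A @ c - lo  # forward offset: p' = A p + t

    # scipy's affine_transform maps output -> input: p = A^T (p' - t)
    inv_matrix = A.T
    inv_offset = -A.T @ t

    std_mask = ndimage.affine_transform(
        msk,
        inv_matrix,
        offset=inv_offset,
        output_shape=out_shape,
        order=0,
        mode="constant",
        cval=BACKGROUND,
    )
    if arr.ndim == 2:
        channels = [arr]
        bg = [0]
    else:
        channels = [arr[..., k] for k in range(arr.shape[2])]
        bg = list(background_rgb)[: len(channels)]
    std_channels = [
        ndimage.affine_transform(
            ch.astype(np.float64),
            inv_matrix,
            offset=inv_offset,
            output_shape=out_shape,
            order=1,
            mode="constant",
            cval=float(cv),
        )
        for ch, cv in zip(channels, bg)
    ]
    if arr.ndim == 2:
        std_image = np.clip(np.rint(std_channels[0]), 0, 255).astype(np.uint8)
    else:
        std_image = np.clip(np.rint(np.stack(std_channels, axis=-1)), 0, 255).astype(np.uint8)

    record = AffineRecord(
        matrix=tuple(map(tuple, A.tolist())), offset=(float(t[0]), float(t[1]))
    )
    return std_image, std_mask.astype(np.uint8), record
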