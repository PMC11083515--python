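"""Background/foreground separation with a constrained linear color model.

A single animal photographed on a uniformly colored board is separated from
the background by thresholding a linear combination of the R, G and B
channels,

    I(i, j) = Cr * R(i, j) + Cg * G(i, j) + Cb * B(i, j),

where the coefficients are constrained to sum to zero (which makes the
response invariant to adding the same offset to all three channels, i.e. to
uniform brightness changes) and to have absolute sum greater than one (so
the response actually amplifies chromatic contrast).  Pixels whose response
is at most ``thresh`` are labelled foreground (255), the rest background (0).
The default coefficients (-1, -1, 2) with ``thresh = 70`` target a blue
board: a blue pixel has a large positive response and is rejected, while the
olive/gray animal scores low and is kept.

A morphological closing (dilation then erosion) afterwards fills speckle
holes left by sensor noise inside the animal region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InputError, ParameterError

FOREGROUND = 255
BACKGROUND = 0


@dataclass(frozen=True)
class ColorModelParams:
    """Coefficients and threshold of the linear color model.

    Parameters
    ----------
    cr, cg, cb
        Channel coefficients.  Must satisfy ``cr + cg + cb == 0`` and
        ``|cr| + |cg| + |cb| > 1``.
    thresh
        Response threshold in pixel-value units.  Pixels with response
        ``I <= thresh`` become foreground.
    """

    cr: float = -1.0
    cg: float = -1.0
    cb: float = 2.0
    thresh: float = 70.0

    def __post_init__(self) -> None:
        s = self.cr + self.cg + self.cb
        if s != 0:
            raise ParameterError(f"color coefficients must sum to 0, got {s}")
        if abs(self.cr) + abs(self.cg) + abs(self.cb) <= 1:
            raise ParameterError("sum of |coefficients| must exceed 1")
        if not np.isfinite(self.thresh):
            raise ParameterError("thresh must be finite")


def _as_rgb(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InputError(f"expected an HxWx3 RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.size == 0:
        raise InputError("image is empty")
    return arr


def color_response(image, params: ColorModelParams = ColorModelParams()) -> np.ndarray:
    """Per-pixel linear response ``Cr*R + Cg*G + Cb*B`` as float64."""
    arr = _as_rgb(image)
    # signed wide arithmetic: uint8 inputs would wrap under negative coefficients
    r = arr[..., 0].astype(np.float64)
    g = arr[..., 1].astype(np.float64)
    b = arr[..., 2].astype(np.float64)
    return params.cr * r + params.cg * g + params.cb * b


def apply_color_model(image, params: ColorModelParams = ColorModelParams()) -> np.ndarray:
    """Threshold the color-model response into a {0, 255} uint8 mask.

    Foreground (255) where the response is ``<= params.thresh``, background
    (0) elsewhere.  Output has the same height and width as the input.
    """
    resp = color_response(image, params)
    return np.where(resp <= params.thresh, FOREGROUND, BACKGROUND).astype(np.uint8)


def _check_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InputError(f"expected a 2-D mask, got shape {arr.shape}")
    values = np.unique(arr)
    if not np.isin(values, (BACKGROUND, FOREGROUND)).all():
        raise InputError("mask values must be in {0, 255}")
    return arr


def morphological_close(mask, kernel_size: int = 5) -> np.ndarray:
    """Binary closing with a square structuring element.

    The mask is padded with background before the dilation so the operation
    stays extensive (output foreground contains input foreground) at the
    image border; animals are assumed interior to the frame.
    """
    arr = _check_mask(mask)
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ParameterError(f"kernel_size must be a positive odd integer, got {kernel_size}")
    if kernel_size == 1:
        return arr.astype(np.uint8).copy()
    fg = arr == FOREGROUND
    pad = kernel_size
    padded = np.pad(fg, pad, mode="constant", constant_values=False)
    structure = np.ones((kernel_size, kernel_size), dtype=bool)
    closed = ndimage.binary_closing(padded, structure=structure)
    closed = closed[pad:-pad, pad:-pad]
    return np.where(closed, FOREGROUND, BACKGROUND).astype(np.uint8)


def segment_animal(
    image,
    params: ColorModelParams = ColorModelParams(),
    kernel_size: int = 5,
) -> np.ndarray:
    """Color-model thresholding followed by morphological closing."""
    return morphological_close(apply_color_model(image, params), kernel_size)
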