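"""Framework-light attention and detection-loss primitives.

Pure-numpy reference implementations of four building blocks used in
attention-augmented single-stage detectors:

- **SimAM**: parameter-free spatial attention.  Each neuron ``t`` in a
  channel of M = H*W activations gets an energy measuring how linearly
  separable it is from the other M-1 neurons; the closed-form minimum is

      e*_t = 4 (sigma_t^2 + lam) / ((t - mu_t)^2 + 2 sigma_t^2 + 2 lam),

  where ``mu_t`` and ``sigma_t^2`` are the mean and variance of the OTHER
  M-1 activations in the channel (leave-one-out statistics, divisor M-1).
  Salient neurons have low energy; the feature map is reweighted by
  ``sigmoid(1/e*)``.

- **SE (squeeze-and-excitation)**: channel attention.  Global average
  pooling squeezes each channel to a scalar; a bottleneck pair of linear
  maps (reduction ratio r, rectifier in between) and a sigmoid produce one
  gate in (0, 1) per channel.

- **Focal loss**: binary cross-entropy with an ``alpha`` class balance and
  a ``(1 - p)^gamma`` modulation that down-weights easy examples.

- **GIoU**: intersection-over-union penalized by the fraction of the
  minimum enclosing box not covered by the union; in (-1, 1], equal to IoU
  when the enclosing box is exactly the union.

These are plain array functions with no autodiff: assembling or training a
detector around them is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError

_EPS = 1e-7


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def _as_chw(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InputError(f"expected a (C, H, W) feature map, got shape {arr.shape}")
    if arr.size == 0:
        raise InputError("empty feature map")
    if not np.isfinite(arr).all():
        raise InputError("feature map contains non-finite values")
    return arr


def simam_energy(x, lam: float = 1e-4) -> np.ndarray:
    """Per-neuron minimum energy e* of the SimAM separability problem.

    Uses exact leave-one-out channel statistics: for neuron value t,
    mu_t = (S - t)/(M - 1) and sigma_t^2 = (Q - t^2)/(M - 1) - mu_t^2 with
    S, Q the channel sum and sum of squares.
    """
    if lam <= 0:
        raise ParameterError(f"lambda must be > 0, got {lam}")
    arr = _as_chw(x)
    C, H, W = arr.shape
    M = H * W
    if M < 2:
        raise InputError("SimAM needs at least 2 spatial positions per channel")
    S = arr.sum(axis=(1, 2), keepdims=True)
    Q = (arr**2).sum(axis=(1, 2), keepdims=True)
    mu = (S - arr) / (M - 1)
    var = (Q - arr**2) / (M - 1) - mu**2
    var = np.maximum(var, 0.0)  # guard tiny negatives from cancellation
    return 4.0 * (var + lam) / ((arr - mu) ** 2 + 2.0 * var + 2.0 * lam)


def simam_enhance(x, lam: float = 1e-4) -> np.ndarray:
    """Reweight a (C, H, W) feature map by ``sigmoid(1 / e*)``."""
    arr = _as_chw(x)
    e_star = simam_energy(arr, lam)
    out = _sigmoid(1.0 / e_star) * arr
    return out if np.asarray(x).ndim == 3 else out[0]


@dataclass(frozen=True)
class SEWeights:
    """Bottleneck weights of an SE block: C -> C/r -> C."""

    reduce: np.ndarray  # (C, C/r)
    expand: np.ndarray  # (C/r, C)

    def __post_init__(self):
        red = np.asarray(self.reduce, dtype=np.float64)
        exp = np.asarray(self.expand, dtype=np.float64)
        if red.ndim != 2 or exp.ndim != 2 or red.shape[1] != exp.shape[0] or red.shape[0] != exp.shape[1]:
            raise ParameterError(
                f"inconsistent SE shapes: reduce {red.shape}, expand {exp.shape}"
            )
        object.__setattr__(self, "reduce", red)
        object.__setattr__(self, "expand", exp)

    @classmethod
    def random(cls, channels: int, r: int = 2, seed: int = 0) -> "SEWeights":
        if channels % r != 0:
            raise ParameterError(f"reduction ratio {r} must divide C={channels}")
        rng = np.random.default_rng(seed)
        hidden = channels // r
        return cls(
            reduce=rng.normal(0, 1 / np.sqrt(channels), (channels, hidden)),
            expand=rng.normal(0, 1 / np.sqrt(hidden), (hidden, channels)),
        )


def se_enhance(x, weights: SEWeights) -> np.ndarray:
    """Squeeze-and-excitation channel gating of a (C, H, W) feature map."""
    arr = _as_chw(x)
    C = arr.shape[0]
    if weights.reduce.shape[0] != C:
        raise InputError(
            f"weights built for C={weights.reduce.shape[0]}, feature map has C={C}"
        )
    z = arr.mean(axis=(1, 2))  # squeeze: global average pool
    hidden = np.maximum(z @ weights.reduce, 0.0)  # rectifier between the maps
    s = _sigmoid(hidden @ weights.expand)  # excitation gates in (0, 1)
    out = s[:, None, None] * arr
    return out if np.asarray(x).ndim == 3 else out[0]


def focal_loss(y_pred, y_true, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """Mean focal loss over a batch of binary labels.

    For y=1: ``-alpha (1-p)^gamma log p``; for y=0:
    ``-(1-alpha) p^gamma log(1-p)``.  Predictions are clipped to
    ``[1e-7, 1 - 1e-7]``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must be in [0, 1], got {alpha}")
    if gamma < 0:
        raise ParameterError(f"gamma must be >= 0, got {gamma}")
    p = np.clip(np.asarray(y_pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(y_true)
    if p.shape != t.shape:
        raise InputError("y_pred and y_true shapes differ")
    if not np.isin(t, (0, 1)).all():
        raise InputError("y_true must be binary")
    loss = np.where(
        t == 1,
        -alpha * (1.0 - p) ** gamma * np.log(p),
        -(1.0 - alpha) * p**gamma * np.log(1.0 - p),
    )
    return float(loss.mean())


@dataclass(frozen=True)
class Box:
    """Axis-aligned box with continuous corners; area = (x2-x1)(y2-y1)."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ParameterError(f"degenerate box corners: {self}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


def _to_box(b) -> Box:
    if isinstance(b, Box):
        return b
    return Box(*map(float, b))


def iou(a, b) -> float:
    """Intersection over union of two boxes (0 when the union is empty)."""
    a, b = _to_box(a), _to_box(b)
    iw = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    ih = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def giou(a, b) -> float:
    """Generalized IoU: ``IoU - (|C| - |A u B|) / |C|`` with C the minimum
    enclosing box.  In (-1, 1]; always <= IoU."""
    a, b = _to_box(a), _to_box(b)
    iw = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    ih = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = iw * ih
    union = a.area + b.area - inter
    enclosing = (max(a.x2, b.x2) - min(a.x1, b.x1)) * (max(a.y2, b.y2) - min(a.y1, b.y1))
    i = inter / union if union > 0 else 0.0
    if enclosing <= 0:
        return i
    return i - (enclosing - union) / enclosing
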