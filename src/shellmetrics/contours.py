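"""Topological contour extraction by border following.

Implements the classic raster-scan border-following scheme for binary
images: every connected foreground component yields one outer boundary,
every hole inside it yields one hole boundary, and each boundary receives a
unique integer identifier (NBD) in raster-scan discovery order, starting at
2 (1 is reserved for the image frame).  During tracing, boundary pixels are
marked +NBD or -NBD in a working copy so that later scan rows can recover
the hierarchy; the caller's mask is never modified.

Conventions: foreground is 8-connected, background (and holes) 4-connected;
coordinates are 0-based ``(row, col)``; the mask is conceptually surrounded
by a background frame so components touching the border still produce
closed outer boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import InputError, ShellmetricsError
from .segmentation import BACKGROUND, FOREGROUND, _check_mask

# 8-neighborhood in clockwise screen order starting from west
_CLOCKWISE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_COUNTERCLOCKWISE = [_CLOCKWISE[0]] + _CLOCKWISE[:0:-1]
_CW_INDEX = {d: k for k, d in enumerate(_CLOCKWISE)}
_CCW_INDEX = {d: k for k, d in enumerate(_COUNTERCLOCKWISE)}


@dataclass
class Contour:
    """One traced boundary.

    ``points`` is the ordered list of boundary pixels ``(row, col)``;
    consecutive points are 8-neighbors and the sequence is closed.  ``kind``
    is ``"outer"`` or ``"hole"``; ``parent_nbd`` is the NBD of the directly
    enclosing boundary, or ``None`` when the parent is the image frame.
    """

    nbd: int
    kind: str
    parent_nbd: Optional[int]
    points: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nbd": self.nbd,
            "kind": self.kind,
            "parent_nbd": self.parent_nbd,
            "points": [[int(r), int(c)] for r, c in self.points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Contour":
        return cls(
            nbd=int(d["nbd"]),
            kind=str(d["kind"]),
            parent_nbd=None if d["parent_nbd"] is None else int(d["parent_nbd"]),
            points=[(int(r), int(c)) for r, c in d["points"]],
        )


class NoContourError(ShellmetricsError, LookupError):
    """No outer contour is available to select."""


def extract_contours(mask) -> list[Contour]:
    """Trace all outer and hole boundaries of a {0, 255} mask.

    Returns the contours in discovery order.  The frame pseudo-boundary
    (NBD 1) is not returned; boundaries whose parent is the frame have
    ``parent_nbd`` set to ``None``.
    """
    arr = _check_mask(mask)
    h, w = arr.shape
    # working copy in the {0,1} convention, padded with a background frame
    f = np.zeros((h + 2, w + 2), dtype=np.int64)
    f[1:-1, 1:-1] = (arr == FOREGROUND).astype(np.int64)

    nbd = 1  # the frame
    kind = {1: "hole"}
    parent = {1: None}
    contours: dict[int, Contour] = {}

    H, W = f.shape
    for i in range(1, H - 1):
        lnbd = 1
        j = 1
        while j < W - 1:
            fij = f[i, j]
            if fij == 0:
                j += 1
                continue
            is_outer = fij == 1 and f[i, j - 1] == 0
            is_hole = fij >= 1 and f[i, j + 1] == 0
            if is_outer or is_hole:
                nbd += 1
                if is_outer:
                    start_dir = (0, -1)
                    this_kind = "outer"
                else:
                    if fij > 1:
                        lnbd = fij
                    start_dir = (0, 1)
                    this_kind = "hole"
                kind[nbd] = this_kind
                # hierarchy: same kind as the last border met -> share its
                # parent; different kind -> it is the parent
                if kind[lnbd] == this_kind:
                    parent[nbd] = parent[lnbd]
                else:
                    parent[nbd] = int(lnbd)
                points = _trace_border(f, (i, j), start_dir, nbd)
                contours[nbd] = Contour(
                    nbd=nbd,
                    kind=this_kind,
                    parent_nbd=None if parent[nbd] == 1 else parent[nbd],
                    points=[(r - 1, c - 1) for r, c in points],
                )
            if f[i, j] != 1:
                lnbd = abs(f[i, j])
            j += 1

    return [contours[k] for k in sorted(contours)]


def _trace_border(f: np.ndarray, start: tuple, start_dir: tuple, nbd: int) -> list:
    """Follow one boundary from ``start``, marking pixels in ``f``.

    ``start_dir`` points at the background neighbor that triggered the scan
    stop (west for outer, east for hole boundaries).
    """
    i, j = start
    # (3.1) clockwise search around start for a nonzero pixel
    k0 = _CW_INDEX[start_dir]
    found = None
    for k in range(8):
        dr, dc = _CLOCKWISE[(k0 + k) % 8]
        if f[i + dr, j + dc] != 0:
            found = (i + dr, j + dc)
            break
    if found is None:
        f[i, j] = -nbd
        return [(i, j)]
    i1, j1 = found
    # (3.2)
    i2, j2 = i1, j1
    i3, j3 = i, j
    points = []
    while True:
        # (3.3) counterclockwise search around (i3,j3) from the next
        # position after (i2,j2); note whether east was examined and zero
        d = (i2 - i3, j2 - j3)
        k0 = _CCW_INDEX[d]
        east_zero = False
        i4 = j4 = None
        for k in range(1, 9):
            dr, dc = _COUNTERCLOCKWISE[(k0 + k) % 8]
            if f[i3 + dr, j3 + dc] != 0:
                i4, j4 = i3 + dr, j3 + dc
                break
            if (dr, dc) == (0, 1):
                east_zero = True
        # (3.4) marking policy
        if east_zero:
            f[i3, j3] = -nbd
        elif f[i3, j3] == 1:
            f[i3, j3] = nbd
        points.append((i3, j3))
        # (3.5) termination: back at the start, about to repeat the first move
        if (i4, j4) == (i, j) and (i3, j3) == (i1, j1):
            break
        i2, j2 = i3, j3
        i3, j3 = i4, j4
    return points


def fill_contours(contours: list[Contour], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a contour set back into a {0, 255} mask.

    Outer boundaries contribute their enclosed region (boundary included);
    hole boundaries remove their strict interior (the boundary pixels
    themselves belong to the foreground).  Nested structures are handled by
    compositing in order of increasing hierarchy depth, so
    ``fill_contours(extract_contours(m), m.shape) == m``.
    """
    h, w = shape
    out = np.zeros((h, w), dtype=bool)
    by_nbd = {c.nbd: c for c in contours}

    def depth(c: Contour) -> int:
        d, p = 0, c.parent_nbd
        while p is not None:
            d += 1
            p = by_nbd[p].parent_nbd if p in by_nbd else None
        return d

    for c in sorted(contours, key=lambda c: (depth(c), c.nbd)):
        for r, cc in c.points:
            if not (0 <= r < h and 0 <= cc < w):
                raise InputError(f"contour point ({r}, {cc}) outside shape {shape}")
        if c.kind == "outer":
            region, _ = _enclosed(c.points, shape)
            out |= region
        else:
            out &= ~_hole_region(c.points, shape)
    return np.where(out, FOREGROUND, BACKGROUND).astype(np.uint8)


def _enclosed(points: list, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Region enclosed by a closed 8-connected pixel boundary.

    Returns ``(region, interior)`` boolean arrays: ``region`` includes the
    boundary pixels, ``interior`` excludes them.  Computed by flood-filling
    the 4-connected exterior of the boundary within a padded bounding box.
    """
    h, w = shape
    rows = [p[0] for p in points]
    cols = [p[1] for p in points]
    r0, r1 = min(rows) - 1, max(rows) + 1
    c0, c1 = min(cols) - 1, max(cols) + 1
    bh, bw = r1 - r0 + 1, c1 - c0 + 1
    boundary = np.zeros((bh, bw), dtype=bool)
    for r, c in points:
        boundary[r - r0, c - c0] = True
    free = ~boundary
    # label the 4-connected free space; anything sharing a label with the
    # padded border is exterior
    labels, _ = ndimage.label(free, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    exterior = np.isin(labels, border_labels[border_labels > 0])
    interior_local = free & ~exterior
    region = np.zeros((h, w), dtype=bool)
    interior = np.zeros((h, w), dtype=bool)
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, h - 1), min(c1, w - 1)
    sl_g = (slice(rr0, rr1 + 1), slice(cc0, cc1 + 1))
    sl_l = (slice(rr0 - r0, rr1 - r0 + 1), slice(cc0 - c0, cc1 - c0 + 1))
    region[sl_g] = (boundary | interior_local)[sl_l]
    interior[sl_g] = interior_local[sl_l]
    return region, interior


def _hole_region(points: list, shape: tuple[int, int]) -> np.ndarray:
    """The 4-connected background component enclosed by a hole boundary.

    A hole boundary starts at a foreground pixel whose east neighbor is the
    hole, so flood-filling 4-connected free space from that seed, with the
    boundary pixels as walls, recovers exactly the hole pixels.  (The
    stricter "everything the exterior flood cannot reach" would also swallow
    foreground pixels trapped inside a zigzagging boundary, which belong to
    the component, not the hole.)
    """
    h, w = shape
    rows = [p[0] for p in points]
    cols = [p[1] for p in points]
    r0, r1 = min(rows) - 1, max(rows) + 2
    c0, c1 = min(cols) - 1, max(cols) + 2
    bh, bw = r1 - r0 + 1, c1 - c0 + 1
    walls = np.zeros((bh, bw), dtype=bool)
    for r, c in points:
        walls[r - r0, c - c0] = True
    seed = (points[0][0] - r0, points[0][1] + 1 - c0)
    if walls[seed]:
        return np.zeros((h, w), dtype=bool)
    labels, _ = ndimage.label(~walls, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    hole_local = labels == labels[seed]
    region = np.zeros((h, w), dtype=bool)
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, h - 1), min(c1, w - 1)
    region[rr0 : rr1 + 1, cc0 : cc1 + 1] = hole_local[
        rr0 - r0 : rr1 - r0 + 1, cc0 - c0 : cc1 - c0 + 1
    ]
    return region


def contour_area(c: Contour, shape: tuple[int, int] | None = None) -> int:
    """Number of pixels enclosed by a contour (boundary included)."""
    rows = [p[0] for p in c.points]
    cols = [p[1] for p in c.points]
    shape = shape or (max(rows) + 2, max(cols) + 2)
    region, _ = _enclosed(c.points, shape)
    return int(region.sum())


def select_primary_contour(contours: list[Contour]) -> Contour:
    """The outer contour with the largest enclosed area (ties: smallest NBD)."""
    outers = [c for c in contours if c.kind == "outer"]
    if not outers:
        raise NoContourError("no outer contour found")
    return max(outers, key=lambda c: (contour_area(c), -c.nbd))
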