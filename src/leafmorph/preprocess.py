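"""Silhouette extraction: binarisation, boundary tracing, incircle centroid.

The pipeline works on a binary silhouette of a single leaf.  Coordinates are
(x, y) = (column, row), 0-based, with y increasing downward; "clockwise"
means clockwise on screen, which with this convention corresponds to a
positive shoelace sum.

The reference point for the shape signature is *not* the area centroid but
the centre of the incircle — the largest circle fully inside the silhouette.
For crescent-like or deeply lobed leaves the area centroid can fall outside
the lamina and produce a meaningless signature; the incircle centre cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters
from skimage.transform import resize

from .config import DEFAULT_CONFIG, RunConfig
from .errors import (
    AmbiguousBoundaryError,
    EmptySegmentationError,
    SegmentationFailureError,
)

__all__ = [
    "BinaryLeafImage",
    "Contour",
    "Centroid",
    "binarize",
    "standardize",
    "trace_boundary",
    "incircle_centroid",
    "remove_petiole",
    "signed_area",
    "preprocess_image",
]


@dataclass
class BinaryLeafImage:
    """A single-leaf silhouette: ``mask[row, col]`` is True on the lamina."""

    mask: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class Contour:
    """Closed clockwise 8-connected pixel boundary.

    ``points`` has shape (n, 2) with columns (x, y).  The first point is
    adjacent to the last; no two consecutive points coincide.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class Centroid:
    """Incircle centre (cx, cy) and its radius, in pixels."""

    cx: float
    cy: float
    incircle_radius: float


def signed_area(points: np.ndarray) -> float:
    """Shoelace sum of a closed polygon; positive = clockwise on screen."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# binarisation


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryLeafImage:
    """Threshold a raster leaf image into a single-component silhouette.

    The darker side of the threshold is assumed to be the leaf unless it
    occupies most of the image border, in which case polarity is flipped.
    The largest connected component is kept and interior holes (e.g. vein
    pixels of background colour) are filled.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        gray = skcolor.rgb2gray(arr[..., :3])
    else:
        gray = arr.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0

    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = threshold / 255.0 if threshold > 1.0 else threshold
    elif method == "otsu":
        if np.ptp(gray) == 0:
            raise EmptySegmentationError("empty segmentation")
        t = filters.threshold_otsu(gray)
        # threshold_otsu returns a bin centre; with few distinct grey levels
        # that centre can sit inside a class.  A few intermeans iterations
        # settle the cut midway between the class means.
        for _ in range(4):
            lo, hi = gray[gray <= t], gray[gray > t]
            if lo.size == 0 or hi.size == 0:
                break
            t_new = 0.5 * (lo.mean() + hi.mean())
            if abs(t_new - t) < 1e-6:
                break
            t = t_new
    else:
        raise ValueError(f"unknown binarisation method: {method}")

    fg = gray < t
    border = np.concatenate([fg[0], fg[-1], fg[:, 0], fg[:, -1]])
    if border.mean() > 0.5:
        fg = ~fg
    if not fg.any():
        raise EmptySegmentationError("empty segmentation")

    labels, nlab = ndimage.label(fg)
    if nlab > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, nlab + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)

    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    touches = (
        rows[0] == 0
        and rows[-1] == fg.shape[0] - 1
        and cols[0] == 0
        and cols[-1] == fg.shape[1] - 1
    )
    if touches:
        raise SegmentationFailureError("segmentation failure")
    return BinaryLeafImage(mask=fg)


def standardize(
    leaf: BinaryLeafImage,
    image: np.ndarray | None = None,
    size: int = DEFAULT_CONFIG.standard_size,
    pad: int = DEFAULT_CONFIG.border_pad,
):
    """Rescale so the silhouette's longest side is ``size - 2*pad`` px.

    Magnitude thresholds are absolute pixel distances, so every leaf is
    brought to the same working scale before the signature is taken.  The
    companion raster ``image`` (if given) is cropped/rescaled identically so
    that mid-vein measurements line up with the mask.
    """
    mask = leaf.mask
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if len(rows) == 0:
        raise EmptySegmentationError("empty segmentation")
    sub = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    target = size - 2 * pad
    scale = target / max(sub.shape)
    out_shape = (
        max(1, round(sub.shape[0] * scale)),
        max(1, round(sub.shape[1] * scale)),
    )
    big = resize(sub.astype(float), out_shape, order=1, anti_aliasing=False) >= 0.5
    out = np.zeros((out_shape[0] + 2 * pad, out_shape[1] + 2 * pad), dtype=bool)
    out[pad : pad + out_shape[0], pad : pad + out_shape[1]] = big
    out = ndimage.binary_fill_holes(out)

    img_out = None
    if image is not None:
        arr = np.asarray(image)
        sub_img = arr[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        resized = resize(
            sub_img.astype(float),
            out_shape + sub_img.shape[2:],
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        fill = float(np.median([arr[0, 0], arr[-1, -1], arr[0, -1], arr[-1, 0]]))
        img_out = np.full(out.shape + sub_img.shape[2:], fill, dtype=arr.dtype)
        img_out[pad : pad + out_shape[0], pad : pad + out_shape[1]] = resized.astype(
            arr.dtype
        )
    return BinaryLeafImage(mask=out, source_path=leaf.source_path), img_out


# ---------------------------------------------------------------------------
# boundary tracing

# 8-neighbourhood in (dx, dy), clockwise on screen starting from West
_NEIGH = np.array(
    [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)],
    dtype=np.int64,
)


def trace_boundary(leaf: BinaryLeafImage, start: tuple[int, int] | None = None) -> Contour:
    """Moore-neighbour boundary trace of the single foreground component.

    Returns the closed clockwise contour; the starting point is arbitrary
    (any boundary pixel may be supplied via ``start`` as (x, y)).
    """
    mask = leaf.mask
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        raise AmbiguousBoundaryError("ambiguous boundary: no foreground")
    if nlab > 1:
        raise AmbiguousBoundaryError("ambiguous boundary: multiple components")

    padded = np.pad(mask, 1)

    if start is None:
        rows, cols = np.nonzero(padded)
        i = int(np.lexsort((cols, rows))[0])
        sx, sy = int(cols[i]), int(rows[i])
        back = 0  # neighbour index of the backtrack pixel (West, background)
    else:
        sx, sy = int(start[0]) + 1, int(start[1]) + 1
        if not padded[sy, sx]:
            raise ValueError("start is not a foreground pixel")
        back = None
        for k, (dx, dy) in enumerate(_NEIGH):
            if not padded[sy + dy, sx + dx]:
                back = k
                break
        if back is None:
            raise ValueError("start is not a boundary pixel")

    pts = [(sx, sy)]
    cx, cy, b = sx, sy, back
    first_move = None
    limit = 4 * int(padded.sum()) + 8
    for _ in range(limit):
        nxt = None
        for j in range(1, 9):
            k = (b + j) % 8
            dx, dy = _NEIGH[k]
            if padded[cy + dy, cx + dx]:
                nxt = (cx + dx, cy + dy)
                # backtrack for the next step: the (background) pixel examined
                # just before this one, re-expressed about the new current pixel
                px = cx + _NEIGH[(k - 1) % 8][0]
                py = cy + _NEIGH[(k - 1) % 8][1]
                b = _neigh_index(px - nxt[0], py - nxt[1])
                break
        if nxt is None:  # isolated single pixel
            break
        if first_move is None:
            first_move = nxt
        elif (cx, cy) == (sx, sy) and nxt == first_move:
            break  # closed the loop: back at start heading the same way
        pts.append(nxt)
        cx, cy = nxt
    if len(pts) > 1 and pts[-1] == (sx, sy):
        pts.pop()

    points = np.array(pts, dtype=np.int64) - 1  # undo padding offset
    # drop duplicate consecutive points ("UniqueCur")
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = (np.diff(points, axis=0) != 0).any(axis=1)
    points = points[keep]
    if len(points) > 1 and (points[0] == points[-1]).all():
        points = points[:-1]
    if len(points) >= 3 and signed_area(points) < 0:
        points = np.concatenate([points[:1], points[1:][::-1]])
    return Contour(points=points)


def _neigh_index(dx: int, dy: int) -> int:
    for k, (nx, ny) in enumerate(_NEIGH):
        if nx == dx and ny == dy:
            return k
    raise ValueError("not an 8-neighbour offset")


# ---------------------------------------------------------------------------
# incircle centroid


def incircle_centroid(leaf: BinaryLeafImage) -> Centroid:
    """Centre of the largest inscribed circle (arg-max of distance-to-boundary).

    Ties are broken by smallest row, then smallest column, so the result is
    deterministic.
    """
    mask = leaf.mask
    if not mask.any():
        raise EmptySegmentationError("empty segmentation")
    dt = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    best = dt.max()
    cand = np.argwhere(dt >= best - 1e-9)
    row, col = cand[np.lexsort((cand[:, 1], cand[:, 0]))[0]]
    return Centroid(cx=float(col), cy=float(row), incircle_radius=float(best))


# ---------------------------------------------------------------------------
# petiole removal


def remove_petiole(
    leaf: BinaryLeafImage,
    width_fraction: float = 0.10,
    min_length_fraction: float = 0.12,
) -> BinaryLeafImage:
    """Cut a narrow basal protrusion (petiole) off the silhouette.

    A morphological opening with a disk of radius ~ ``width_fraction`` times
    the incircle diameter erases protrusions narrower than that; residual
    components that are long and thin are removed.  Leaves without such a
    protrusion are returned unchanged.
    """
    mask = leaf.mask
    c = incircle_centroid(leaf)
    radius = max(2.0, width_fraction * c.incircle_radius)
    opened = _disk_open(mask, radius)
    resid, nlab = ndimage.label(mask & ~opened, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return leaf
    long_side = max(mask.shape)
    min_len = min_length_fraction * long_side
    out = mask.copy()
    changed = False
    for lab in range(1, nlab + 1):
        comp = resid == lab
        ys, xs = np.nonzero(comp)
        extent = float(np.hypot(ys.max() - ys.min(), xs.max() - xs.min()))
        if extent < min_len:
            continue
        width = comp.sum() / max(extent, 1.0)
        if width <= 2 * radius:
            out[comp] = False
            changed = True
    if not changed:
        return leaf
    labels, nlab = ndimage.label(out, structure=np.ones((3, 3), dtype=int))
    if nlab > 1:
        sizes = ndimage.sum_labels(out, labels, index=np.arange(1, nlab + 1))
        out = labels == (1 + int(np.argmax(sizes)))
    out = ndimage.binary_fill_holes(out)
    return BinaryLeafImage(mask=out, source_path=leaf.source_path)


def _disk_erode(mask: np.ndarray, r: float) -> np.ndarray:
    """Euclidean-disk erosion via the exact distance transform."""
    return ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1] > r


def _disk_dilate(mask: np.ndarray, r: float) -> np.ndarray:
    return ndimage.distance_transform_edt(~mask) <= r


def _disk_open(mask: np.ndarray, r: float) -> np.ndarray:
    return _disk_dilate(_disk_erode(mask, r), r)


def _disk_close(mask: np.ndarray, r: float) -> np.ndarray:
    # erosion treats outside the frame as background, which is correct here
    # as long as the dilated mask stays clear of the frame edge (callers pad)
    return _disk_erode(_disk_dilate(mask, r), r)


# ---------------------------------------------------------------------------
# one-call convenience


def preprocess_image(
    image: np.ndarray,
    config: RunConfig = DEFAULT_CONFIG,
    source_path: str | None = None,
):
    """binarise -> (optional petiole cut) -> standardise.

    Returns ``(BinaryLeafImage, standardised raster or None)``.
    """
    leaf = binarize(image)
    leaf.source_path = source_path
    if config.remove_petiole:
        leaf = remove_petiole(leaf)
    return standardize(leaf, image=image, size=config.standard_size, pad=config.border_pad)
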