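"""Centroid-contour-distance shape signature and its extrema.

The signature ("CCD-EBP") records the Euclidean distance from the incircle
centre to *every* boundary pixel, in clockwise contour order.  Lobes appear
as peaks and sinuses as valleys of this 1-D cyclic signal.  An excursion
counts as a peak/valley only if it rises/falls by at least a magnitude
threshold ``delta``; because the right delta depends on lobe depth, the scan
is repeated for several thresholds and the per-threshold counts are
consolidated by their mode.

Conventional CCD samples the boundary at a fixed angular interval (36 points
at 10 degrees) and can miss extrema entirely; it is kept here only as a
reference mode (:func:`ccd_angle_sampled`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG
from .errors import InvalidCentroidError
from .preprocess import BinaryLeafImage, Centroid, Contour

__all__ = [
    "Signature",
    "ExtremaSet",
    "ConsolidatedExtrema",
    "ccd_ebp",
    "ccd_angle_sampled",
    "find_extrema",
    "consolidate_extrema",
    "count_lobes_sinuses",
    "first_mode",
]


@dataclass
class Signature:
    """Per-boundary-point centroid distance ``dist[i]`` (pixels)."""

    dist: np.ndarray
    centroid: Centroid
    contour: Contour

    def __post_init__(self) -> None:
        self.dist = np.asarray(self.dist, dtype=float)

    @property
    def n(self) -> int:
        return len(self.dist)

    def normalised(self) -> "Signature":
        """Signature rescaled to [0, 100] (alternative thresholding scale)."""
        d = self.dist
        span = np.ptp(d)
        nd = np.zeros_like(d) if span == 0 else (d - d.min()) * (100.0 / span)
        return Signature(dist=nd, centroid=self.centroid, contour=self.contour)


@dataclass
class ExtremaSet:
    """Peaks and valleys of the cyclic signature at one magnitude threshold.

    ``peaks`` / ``valleys`` are lists of (contour index, distance value);
    indices strictly alternate around the cycle.
    """

    delta: float
    peaks: list[tuple[int, float]] = field(default_factory=list)
    valleys: list[tuple[int, float]] = field(default_factory=list)

    @property
    def peak_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.peaks], dtype=np.int64)

    @property
    def valley_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.valleys], dtype=np.int64)


@dataclass
class ConsolidatedExtrema:
    """Mode-consolidated extrema across several magnitude thresholds."""

    thresholds: tuple[float, ...]
    per_threshold: list[ExtremaSet]
    mod_peak: int
    mod_valley: int
    chosen_threshold: float
    peak_positions: np.ndarray
    valley_positions: np.ndarray


def ccd_ebp(contour: Contour, centroid: Centroid, mask: BinaryLeafImage | None = None) -> Signature:
    """Distance from the incircle centre to every boundary point.

    If ``mask`` is provided, the centroid is checked to lie on the
    foreground; a centroid outside the leaf would invalidate the signature.
    """
    if mask is not None:
        r, c = int(round(centroid.cy)), int(round(centroid.cx))
        inside = (
            0 <= r < mask.mask.shape[0]
            and 0 <= c < mask.mask.shape[1]
            and bool(mask.mask[r, c])
        )
        if not inside:
            raise InvalidCentroidError("invalid centroid")
    d = np.hypot(contour.x - centroid.cx, contour.y - centroid.cy)
    return Signature(dist=d, centroid=centroid, contour=contour)


def ccd_angle_sampled(
    contour: Contour, centroid: Centroid, interval_deg: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Conventional angle-sampled CCD (reference mode).

    Selects one boundary point per interval angle — 36 points at a
    10-degree interval — and returns (indices, distances).
    """
    ang = np.degrees(
        np.arctan2(-(contour.y - centroid.cy), contour.x - centroid.cx)
    ) % 360.0
    targets = np.arange(0.0, 360.0, interval_deg)
    diff = np.abs(ang[None, :] - targets[:, None])
    diff = np.minimum(diff, 360.0 - diff)
    idx = np.unique(diff.argmin(axis=1))
    d = np.hypot(contour.x[idx] - centroid.cx, contour.y[idx] - centroid.cy)
    return idx, d


# ---------------------------------------------------------------------------
# delta-threshold extrema search


def find_extrema(signature: Signature | np.ndarray, delta: float) -> ExtremaSet:
    """Alternating peak/valley scan of the cyclic signature.

    While searching for a maximum, a peak is recorded at the running
    maximum once the signal drops below it by ``delta``; the scan then
    switches to searching for a minimum, and symmetrically for valleys.
    The cyclic signal is handled by rotating the array to start at its
    global minimum before the linear scan and mapping indices back, which
    removes the start/end artefacts a linear scan would otherwise have on a
    closed contour.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    d = signature.dist if isinstance(signature, Signature) else np.asarray(signature, float)
    n = len(d)
    out = ExtremaSet(delta=float(delta))
    if n == 0 or np.ptp(d) < delta:
        return out

    m = int(np.argmin(d))
    r = np.roll(d, -m)

    peaks: list[tuple[int, float]] = []
    valleys: list[tuple[int, float]] = []
    mx, mxpos = -np.inf, 0
    mn, mnpos = np.inf, 0
    lookformax = True
    for i in range(n):
        v = r[i]
        if v > mx:
            mx, mxpos = v, i
        if v < mn:
            mn, mnpos = v, i
        if lookformax:
            if v < mx - delta:
                peaks.append((mxpos, mx))
                mn, mnpos = v, i
                lookformax = False
        else:
            if v > mn + delta:
                valleys.append((mnpos, mn))
                mx, mxpos = v, i
                lookformax = True

    # close the cycle: the scan ends just before the global minimum (index 0)
    if lookformax and mx - r[0] >= delta and mxpos != 0:
        peaks.append((mxpos, mx))
    if len(peaks) == len(valleys) + 1:
        valleys.insert(0, (0, float(r[0])))

    out.peaks = [((i + m) % n, float(v)) for i, v in peaks]
    out.valleys = [((i + m) % n, float(v)) for i, v in valleys]
    return out


def first_mode(counts: list[int]) -> int:
    """Mode of ``counts``; ties broken by first occurrence ("first mode")."""
    if not counts:
        raise ValueError("empty counts")
    order: list[int] = []
    freq: dict[int, int] = {}
    for c in counts:
        if c not in freq:
            order.append(c)
        freq[c] = freq.get(c, 0) + 1
    best = max(freq.values())
    for c in order:
        if freq[c] == best:
            return c
    raise AssertionError("unreachable")


def consolidate_extrema(
    signature: Signature,
    thresholds: tuple[float, ...] = DEFAULT_CONFIG.magnitude_thresholds,
) -> ConsolidatedExtrema:
    """Run the extrema scan at each threshold and consolidate by mode.

    ``mod_peak`` / ``mod_valley`` are the first modes of the per-threshold
    counts.  Positions are taken from the first threshold whose peak *and*
    valley counts both equal the modes; if no threshold matches both, from
    the first matching the peak mode (valleys from the same run).
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    sets = [find_extrema(signature, t) for t in thresholds]
    pc = [len(s.peaks) for s in sets]
    vc = [len(s.valleys) for s in sets]
    mod_peak = first_mode(pc)
    mod_valley = first_mode(vc)

    chosen = None
    for i, s in enumerate(sets):
        if pc[i] == mod_peak and vc[i] == mod_valley:
            chosen = i
            break
    if chosen is None:
        for i, s in enumerate(sets):
            if pc[i] == mod_peak:
                chosen = i
                break
    if chosen is None:  # mod_peak always occurs, but keep a hard fallback
        chosen = 0
    s = sets[chosen]
    return ConsolidatedExtrema(
        thresholds=tuple(thresholds),
        per_threshold=sets,
        mod_peak=mod_peak,
        mod_valley=mod_valley,
        chosen_threshold=float(thresholds[chosen]),
        peak_positions=s.peak_indices,
        valley_positions=s.valley_indices,
    )


def count_lobes_sinuses(consolidated: ConsolidatedExtrema):
    """Lobes = consolidated peak count; sinuses = valley count.

    A smooth (unlobed) outline legitimately yields zero of each.
    Returns ``(lobes, sinuses, (peak_positions, valley_positions))``.
    """
    return (
        consolidated.mod_peak,
        consolidated.mod_valley,
        (consolidated.peak_positions, consolidated.valley_positions),
    )
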