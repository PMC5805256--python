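"""Leaf margin analysis: ripples ratio, tooth geometry, margin taxonomy.

Margin teeth are small oscillations of the shape signature: re-running the
extrema scan at a small magnitude threshold (2 px) finds them together with
the lobes and the apex, so the large-threshold extrema are subtracted
(set difference by contour index, with a proximity tolerance) to leave only
the teeth.

Whether a margin has teeth at all is decided by the ripples ratio: the
silhouette is smoothed with a Euclidean disk filter and the area changed by
the smoothing (XOR), divided by the leaf area, approaches zero for an
entire margin.

Each tooth is measured on its (left valley, peak, right valley) triple:
flank chords A and B, the enclosed area against the valley-valley chord,
the peak/valley triangle, the tooth height, and the distance of the tooth
to the midrib axis.  The taxonomy follows three binary cuts: unequal flanks
(saw-like, type 1 -> serrate/serrulate/doubly serrate); equal flanks with
triangularity <= 1 (shark-tooth, type 2 -> dentate/denticulate); equal
flanks with triangularity > 1 (rounded, type 3 -> crenate/crenulate).
Teeth whose height-to-midrib ratio is below 1/16 are diminutive and select
the -ulate form; above 1/8 the excursion is lobe-scale and is not a tooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .errors import DegenerateToothError, EmptySegmentationError
from .preprocess import BinaryLeafImage, Contour, _disk_close, _disk_open
from .signature import ConsolidatedExtrema, Signature, find_extrema

__all__ = [
    "ToothMeasurement",
    "MarginFeatures",
    "detect_teeth",
    "smooth_silhouette",
    "ripples_ratio",
    "pair_teeth",
    "measure_tooth",
    "diminutive_test",
    "tooth_type",
    "classify_margin",
    "analyse_margin",
]

MARGIN_CLASSES = (
    "entire",
    "serrate",
    "serrulate",
    "doubly_serrate",
    "dentate",
    "denticulate",
    "crenate",
    "crenulate",
)


@dataclass
class ToothMeasurement:
    peak_index: int
    left_valley_index: int
    right_valley_index: int
    A: float  # chord peak <-> left valley, px
    B: float  # chord peak <-> right valley, px
    tooth_area: float  # between the tooth outline and the valley-valley chord
    triangle_area: float  # peak/valleys triangle
    L_teeth: float  # tooth height: peak distance from the valley-valley chord
    L_teeth2midrib: float  # chord midpoint distance to the midrib axis

    @property
    def ratio_dt(self) -> float:
        return self.L_teeth / self.L_teeth2midrib if self.L_teeth2midrib > 0 else np.inf

    @property
    def triangularity(self) -> float:
        return self.tooth_area / self.triangle_area


@dataclass
class MarginFeatures:
    ripples_ratio: float
    teeth_peaks: np.ndarray
    teeth_valleys: np.ndarray
    teeth: list[ToothMeasurement] = field(default_factory=list)
    ratio_dt: float = 0.0  # median over reported teeth
    diminutive: bool = False
    tooth_type: str = "none"  # type1 | type2 | type3 | none
    margin_class: str = "entire"


# ---------------------------------------------------------------------------
# teeth detection


def detect_teeth(
    signature: Signature,
    consolidated: ConsolidatedExtrema,
    small_threshold: float = DEFAULT_CONFIG.small_threshold,
    match_tol: float = DEFAULT_CONFIG.teeth_match_tol,
) -> tuple[np.ndarray, np.ndarray]:
    """Small-threshold extrema minus the large-threshold extrema.

    A small extremum within ``match_tol`` (fraction of contour length) of a
    large one is the lobe/apex itself and is excluded; what remains are the
    teeth peaks and valleys.
    """
    small = find_extrema(signature, small_threshold)
    n = signature.n
    tol = max(1, int(round(match_tol * n)))

    def subtract(small_idx: np.ndarray, large_idx: np.ndarray) -> np.ndarray:
        if len(small_idx) == 0:
            return np.array([], dtype=np.int64)
        if len(large_idx) == 0:
            return np.asarray(small_idx, dtype=np.int64)
        d = np.abs(small_idx[:, None] - large_idx[None, :])
        d = np.minimum(d, n - d)  # cyclic index distance
        return np.asarray(small_idx, dtype=np.int64)[d.min(axis=1) > tol]

    peaks = subtract(small.peak_indices, consolidated.peak_positions)
    valleys = subtract(small.valley_indices, consolidated.valley_positions)
    return np.sort(peaks), np.sort(valleys)


# ---------------------------------------------------------------------------
# ripples ratio


def smooth_silhouette(mask: np.ndarray, radius: float) -> np.ndarray:
    """Disk-filter smoothing: opening (shaves protrusions) then closing
    (fills indentations), both with an exact Euclidean disk.

    The mask is padded by the radius first so the closing cannot interact
    with the image border.
    """
    pad = int(np.ceil(radius)) + 2
    m = np.pad(mask, pad)
    out = _disk_close(_disk_open(m, radius), radius)
    return out[pad:-pad, pad:-pad]


def ripples_ratio(
    mask: BinaryLeafImage | np.ndarray,
    smoothing_radius: float,
    return_masks: bool = False,
):
    """Changed-pixel fraction under disk smoothing: ``|XOR| / |leaf|``.

    Approaches zero for an entire (smooth) margin; teeth and ripples leave
    a band of changed pixels along the boundary.
    """
    m = mask.mask if isinstance(mask, BinaryLeafImage) else np.asarray(mask, bool)
    area = int(m.sum())
    if area == 0:
        raise EmptySegmentationError("empty mask")
    smoothed = smooth_silhouette(m, smoothing_radius)
    ripples = m ^ smoothed
    ratio = float(ripples.sum()) / float(area)
    if return_masks:
        return ratio, ripples, smoothed
    return ratio


# ---------------------------------------------------------------------------
# tooth measurement


def pair_teeth(
    teeth_peaks: np.ndarray, teeth_valleys: np.ndarray, n: int
) -> list[tuple[int, int, int]]:
    """(left valley, peak, right valley) triples by cyclic adjacency.

    Peaks without a valley on each side within 2.5x the median tooth
    spacing are skipped (margin ends, teeth absorbed by lobes).
    """
    peaks = np.sort(np.asarray(teeth_peaks, dtype=np.int64))
    valleys = np.sort(np.asarray(teeth_valleys, dtype=np.int64))
    if len(peaks) == 0 or len(valleys) < 2:
        return []
    spacing = np.median(np.diff(np.concatenate([peaks, [peaks[0] + n]])))
    max_gap = 2.5 * spacing
    triples = []
    for p in peaks:
        before = valleys[valleys < p]
        left = int(before[-1]) if len(before) else int(valleys[-1])
        after = valleys[valleys > p]
        right = int(after[0]) if len(after) else int(valleys[0])
        if (p - left) % n > max_gap or (right - p) % n > max_gap:
            continue
        triples.append((left, int(p), right))
    return triples


def _refine_valley(contour: Contour, p1: int, p2: int, centroid_xy: np.ndarray) -> int:
    """Innermost point between two adjacent tooth peaks.

    The signature's running-minimum valley drifts along the sloped distance
    baseline; the extreme perpendicular point against the peak-peak chord
    is baseline-free.
    """
    n = contour.n
    if p2 > p1:
        idx = np.arange(p1, p2 + 1)
    else:
        idx = np.concatenate([np.arange(p1, n), np.arange(0, p2 + 1)])
    seg = contour.points[idx % n].astype(float)
    P1 = contour.points[p1 % n].astype(float)
    P2 = contour.points[p2 % n].astype(float)
    chord = P2 - P1
    clen = np.linalg.norm(chord)
    if clen < 1e-9:
        return int(p1)
    u = chord / clen
    signed = (seg - P1) @ np.array([-u[1], u[0]])
    inward = np.sign(float((centroid_xy - P1) @ np.array([-u[1], u[0]])) or 1.0)
    return int(idx[int(np.argmax(inward * signed))] % n)


def measure_tooth(
    contour: Contour,
    peak: int,
    left_valley: int,
    right_valley: int,
    midrib_axis: tuple[np.ndarray, np.ndarray],
) -> ToothMeasurement:
    """Geometry of one tooth.

    ``midrib_axis`` is ``(point_on_axis, unit_direction)`` — the line
    through the north and south poles.  The tooth outline is the contour
    segment from the left to the right valley, closed by the valley-valley
    chord.
    """
    n = contour.n
    L = contour.points[left_valley % n].astype(float)
    R = contour.points[right_valley % n].astype(float)
    chord = R - L
    clen = float(np.linalg.norm(chord))
    if clen < 1e-9:
        raise DegenerateToothError("degenerate tooth: coincident valleys")

    if right_valley >= left_valley:
        seg = contour.points[left_valley : right_valley + 1].astype(float)
    else:
        seg = np.concatenate(
            [contour.points[left_valley:], contour.points[: right_valley + 1]]
        ).astype(float)

    # refine the peak to the outward point: maximum perpendicular distance
    # from the valley-valley chord.  The raw signature peak drifts along the
    # sloped distance baseline on flat-topped teeth; this measure does not.
    u = chord / clen
    perp = np.abs((seg - L) @ np.array([-u[1], u[0]]))
    # flat-topped teeth tie over many pixels; take the middle of the plateau
    near = np.flatnonzero(perp >= perp.max() - 0.75)
    k = int(near[len(near) // 2])
    if 0 < k < len(seg) - 1:
        peak = (left_valley + k) % n
    P = contour.points[peak % n].astype(float)
    A = float(np.linalg.norm(P - L))
    B = float(np.linalg.norm(P - R))
    tri2 = abs(float(np.cross(P - L, R - L)))  # twice the triangle area
    if tri2 < 1e-9:
        raise DegenerateToothError("degenerate tooth: collinear peak and valleys")
    x, y = seg[:, 0], seg[:, 1]
    tooth_area = abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))

    height = tri2 / clen  # perpendicular distance of the peak from the chord
    mid = 0.5 * (L + R)
    axis_pt, axis_dir = midrib_axis
    axis_dir = np.asarray(axis_dir, float)
    axis_dir = axis_dir / max(np.linalg.norm(axis_dir), 1e-9)
    to_mid = mid - np.asarray(axis_pt, float)
    dist_midrib = abs(float(np.cross(axis_dir, to_mid)))

    return ToothMeasurement(
        peak_index=int(peak),
        left_valley_index=int(left_valley),
        right_valley_index=int(right_valley),
        A=A,
        B=B,
        tooth_area=tooth_area,
        triangle_area=0.5 * tri2,
        L_teeth=float(height),
        L_teeth2midrib=float(dist_midrib),
    )


def diminutive_test(
    tooth: ToothMeasurement, config: RunConfig = DEFAULT_CONFIG
) -> tuple[float, bool]:
    """(ratio_dt, diminutive): height over midrib distance against 1/16.

    Ratios above 1/8 are lobe-scale excursions, not teeth (callers exclude
    them from the tooth vote).
    """
    r = tooth.ratio_dt
    return float(r), bool(r < config.diminutive_bound)


def tooth_type(tooth: ToothMeasurement, equal_tol: float = DEFAULT_CONFIG.equal_tol) -> str:
    """type1 (unequal flanks) / type2 (triangular) / type3 (rounded)."""
    if tooth.B <= 0:
        raise DegenerateToothError("degenerate tooth: zero flank")
    if abs(tooth.A / tooth.B - 1.0) > equal_tol:
        return "type1"
    return "type2" if tooth.triangularity <= 1.0 else "type3"


# ---------------------------------------------------------------------------
# margin classification


def _bimodal_sizes(ratios: np.ndarray, min_ratio: float, min_frac: float = 0.3) -> bool:
    """Two well-separated tooth-size modes (doubly serrate)?

    Splits the sorted size ratios at their largest gap; bimodal when both
    clusters are populated and their means differ by at least ``min_ratio``.
    """
    r = np.sort(np.asarray(ratios, float))
    if len(r) < 6:
        return False
    gaps = np.diff(r)
    cut = int(np.argmax(gaps)) + 1
    lo, hi = r[:cut], r[cut:]
    if min(len(lo), len(hi)) < min_frac * len(r):
        return False
    if lo.mean() <= 0:
        return False
    return bool(hi.mean() / lo.mean() >= min_ratio)


def valid_teeth(
    teeth: list[ToothMeasurement], config: RunConfig = DEFAULT_CONFIG
) -> list[ToothMeasurement]:
    """Teeth that enter the margin vote.

    Excursions past the 1/8 height-to-midrib bound are lobe-scale, not
    teeth; excursions shallower than the small magnitude threshold are
    rasterisation-level wiggles, not teeth.
    """
    return [
        t
        for t in teeth
        if 0.0 < t.ratio_dt <= config.lobe_ratio_bound
        and t.L_teeth >= config.small_threshold
    ]


def classify_margin(
    features: MarginFeatures,
    per_tooth: list[ToothMeasurement] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Final margin label from the ripples ratio and the tooth vote.

    Entire when the ripples ratio is near zero or no valid teeth exist;
    otherwise the majority tooth type and majority diminutive flag select
    the class, with bimodal type-1 tooth sizes promoted to doubly serrate.
    """
    teeth = per_tooth if per_tooth is not None else features.teeth
    valid = valid_teeth(teeth, config)
    if len(valid) < config.min_teeth:
        # a smooth margin yields no teeth (and a near-zero ripples ratio);
        # a handful of boundary quirks is not a toothed margin either.
        # Teeth decide: low-amplitude teeth can leave the ripples ratio at
        # rasterisation level, so the ratio alone cannot veto them.
        features.margin_class = "entire"
        return "entire"

    types = [tooth_type(t, config.equal_tol) for t in valid]
    counts = {k: types.count(k) for k in ("type1", "type2", "type3")}
    major = max(counts, key=lambda k: counts[k])
    features.tooth_type = major
    features.ratio_dt = float(np.median([t.ratio_dt for t in valid]))
    features.diminutive = bool(
        np.mean([t.ratio_dt < config.diminutive_bound for t in valid]) > 0.5
    )

    if major == "type1":
        # size bimodality decided on well-measured teeth (away from the poles)
        span = max(t.L_teeth2midrib for t in valid)
        sizes = np.array(
            [t.ratio_dt for t in valid if t.L_teeth2midrib >= 0.4 * span]
        )
        if _bimodal_sizes(sizes, config.doubly_ratio):
            features.margin_class = "doubly_serrate"
        else:
            features.margin_class = "serrulate" if features.diminutive else "serrate"
    elif major == "type2":
        features.margin_class = "denticulate" if features.diminutive else "dentate"
    else:
        features.margin_class = "crenulate" if features.diminutive else "crenate"
    return features.margin_class


def midrib_axis_from_mask(mask: BinaryLeafImage | np.ndarray):
    """Midrib axis as the silhouette's major principal axis.

    The mid-vein runs base to apex along the blade's long axis; the major
    axis of the second moments recovers it for any silhouette, including
    near-round blades whose radial signature has no clear polar structure.
    """
    m = mask.mask if isinstance(mask, BinaryLeafImage) else np.asarray(mask, bool)
    ys, xs = np.nonzero(m)
    pts = np.column_stack([xs, ys]).astype(float)
    mean = pts.mean(axis=0)
    cov = np.cov((pts - mean).T)
    w, v = np.linalg.eigh(cov)
    return mean, v[:, int(np.argmax(w))]


def analyse_margin(
    mask: BinaryLeafImage,
    contour: Contour,
    signature: Signature,
    consolidated: ConsolidatedExtrema,
    midrib_axis: tuple[np.ndarray, np.ndarray] | None,
    incircle_radius: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> MarginFeatures:
    """Full margin pipeline: ripples ratio, teeth, measurements, label.

    ``midrib_axis`` is ``(point, direction)``; pass ``None`` to use the
    silhouette's major principal axis.
    """
    if midrib_axis is None:
        midrib_axis = midrib_axis_from_mask(mask)
    radius = (
        config.smoothing_radius
        if config.smoothing_radius is not None
        else incircle_radius / 8.0
    )
    ratio = ripples_ratio(mask, radius)
    peaks, valleys = detect_teeth(
        signature, consolidated, config.small_threshold, config.teeth_match_tol
    )
    if len(peaks) >= config.min_teeth:
        # the margin is established as toothed; a second pass at half the
        # threshold recovers teeth whose radial prominence is attenuated on
        # steep flanks (the height filter keeps zig-zag noise out)
        peaks2, valleys2 = detect_teeth(
            signature, consolidated, config.small_threshold / 2.0, config.teeth_match_tol
        )
        if len(peaks2) > len(peaks):
            peaks, valleys = peaks2, valleys2
    feats = MarginFeatures(ripples_ratio=ratio, teeth_peaks=peaks, teeth_valleys=valleys)

    n = contour.n
    if len(peaks) >= 2:
        # triples from adjacent peaks, valleys refined geometrically
        cxy = np.array(
            [signature.centroid.cx, signature.centroid.cy]
        )
        gaps = np.diff(np.concatenate([peaks, [peaks[0] + n]]))
        spacing = float(np.median(gaps))
        m = len(peaks)
        for i in range(m):
            p = int(peaks[i])
            prev, nxt = int(peaks[(i - 1) % m]), int(peaks[(i + 1) % m])
            if (p - prev) % n > 2.5 * spacing or (nxt - p) % n > 2.5 * spacing:
                continue
            left = _refine_valley(contour, prev, p, cxy)
            right = _refine_valley(contour, p, nxt, cxy)
            try:
                feats.teeth.append(measure_tooth(contour, p, left, right, midrib_axis))
            except DegenerateToothError:
                continue
    classify_margin(feats, config=config)
    return feats
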