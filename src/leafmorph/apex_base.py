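"""Apex and base localisation and curvature description.

Rays from the incircle centre to the detected local maxima divide the full
turn into vertex angles (law of cosines on the two ray lengths and the
chord).  Normalised vertex angles split the maxima into a "north" and a
"south" region: the lone tip of a leaf subtends large angles to its
neighbours, while the remaining lobes crowd together.  The median maximum
of each region is its pole (two medians when the count is even).  Which
pole is the apex and which the base is decided by the mid-vein: the vein is
wider where it meets the petiole (base) than at the apical end.

Tip curvature is described by the Centroid Contour Gradient (CCG): one
boundary point of the tip region is sampled per interval angle
{0, theta, ..., 90} about the region centroid, and the absolute chord slope
between consecutive samples forms the descriptor.  Categorical tip labels
(acuminate/acute/rounded/... and cuneate/attenuate/cordate/...) come from
the flank geometry: the intersection angle of the two fitted flanks, their
straightness, and their bulge direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .config import DEFAULT_CONFIG, RunConfig
from .errors import (
    DegenerateFanError,
    IncompleteCCGError,
    InsufficientMaximaError,
    PoleSelectionError,
    VeinUndetectableError,
)
from .preprocess import BinaryLeafImage, Centroid, Contour
from .signature import ConsolidatedExtrema, Signature

__all__ = [
    "VertexFan",
    "PoleRegions",
    "CCGVector",
    "ApexBaseLabels",
    "build_vertex_fan",
    "split_north_south",
    "select_poles",
    "locate_poles",
    "extract_pole_regions",
    "measure_midvein_width",
    "disambiguate_apex_base",
    "ccg",
    "classify_apex_type",
    "classify_base_type",
]

APEX_LABELS = ("acuminate", "acute", "cuspidate", "obtuse", "rounded", "truncate")
BASE_LABELS = ("attenuate", "cuneate", "obtuse", "rounded", "cordate", "oblique")


@dataclass
class VertexFan:
    """Vertex angles at the centroid between consecutive local maxima."""

    maxima_indices: np.ndarray  # contour indices of the local maxima k_i
    points: np.ndarray  # (m, 2) maxima coordinates
    centroid: Centroid
    angles: np.ndarray  # V_i, degrees; angle i joins k_i and k_{i+1}
    norm_angles: np.ndarray | None = None
    region_labels: list[str] | None = None  # per angle: north | south
    north_members: np.ndarray | None = None  # indices into maxima list
    south_members: np.ndarray | None = None

    @property
    def m(self) -> int:
        return len(self.maxima_indices)


@dataclass
class PoleRegions:
    """North/south poles, their contour segments, and the apex/base call."""

    np_indices: np.ndarray  # contour indices of the north point(s)
    sp_indices: np.ndarray
    part_np: np.ndarray  # contour indices of the north segment
    part_sp: np.ndarray
    apex_is_north: bool | None = None
    rotation_deg: float | None = None  # rotation that puts the apex up
    method: str = "fan"  # fan | two_maxima | extreme_distance

    @property
    def apex_part(self) -> np.ndarray:
        if self.apex_is_north is None:
            raise PoleSelectionError("apex/base not yet disambiguated")
        return self.part_np if self.apex_is_north else self.part_sp

    @property
    def base_part(self) -> np.ndarray:
        if self.apex_is_north is None:
            raise PoleSelectionError("apex/base not yet disambiguated")
        return self.part_sp if self.apex_is_north else self.part_np

    @property
    def apex_pole(self) -> np.ndarray:
        return self.np_indices if self.apex_is_north else self.sp_indices

    @property
    def base_pole(self) -> np.ndarray:
        return self.sp_indices if self.apex_is_north else self.np_indices


@dataclass
class CCGVector:
    """Boundary samples at the interval angles and their chord gradients."""

    interval_angle: float
    angles: np.ndarray  # sampled interval angles, degrees
    sample_points: np.ndarray  # (n, 2) image coordinates
    gradients: np.ndarray  # n-1 non-negative chord slopes


@dataclass
class ApexBaseLabels:
    apex_type: str
    base_type: str
    apex_angle: float
    base_angle: float
    apex_confidence: float = 1.0
    base_confidence: float = 1.0


# ---------------------------------------------------------------------------
# vertex fan


def build_vertex_fan(
    maxima_indices: np.ndarray, contour: Contour, centroid: Centroid
) -> VertexFan:
    """Vertex angles V_i = angle(k_i, C, k_{i+1}) by the law of cosines.

    The wrap-around vertex (last maximum back to the first) is included, so
    for well-spread maxima the angles sum to a full turn.
    """
    idx = np.asarray(maxima_indices, dtype=np.int64)
    if len(idx) < 2:
        raise InsufficientMaximaError("insufficient maxima")
    pts = contour.points[idx].astype(float)
    c = np.array([centroid.cx, centroid.cy])
    nxt = np.roll(pts, -1, axis=0)
    d1 = np.linalg.norm(pts - c, axis=1)
    d2 = np.linalg.norm(nxt - c, axis=1)
    d12 = np.linalg.norm(pts - nxt, axis=1)
    cosv = (d1**2 + d2**2 - d12**2) / np.maximum(2.0 * d1 * d2, 1e-12)
    angles = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    return VertexFan(maxima_indices=idx, points=pts, centroid=centroid, angles=angles)


def split_north_south(
    fan: VertexFan, thres_norm: float = DEFAULT_CONFIG.thres_norm
) -> VertexFan:
    """Label each vertex angle north/south and derive maxima memberships.

    ``V_norm = (V - min V) / (max V - min V)``; a vertex is "north" when its
    normalised angle exceeds ``thres_norm``.  Both maxima flanking a vertex
    inherit its region; maxima claimed by both regions are removed from the
    larger region (they stay with the smaller one).
    """
    v = fan.angles
    span = v.max() - v.min()
    if span < 1e-9:
        raise DegenerateFanError("degenerate fan: all vertex angles equal")
    fan.norm_angles = (v - v.min()) / span
    fan.region_labels = ["north" if x > thres_norm else "south" for x in fan.norm_angles]

    m = fan.m
    north = np.zeros(m, dtype=bool)
    south = np.zeros(m, dtype=bool)
    for i, lab in enumerate(fan.region_labels):
        j = (i + 1) % m
        if lab == "north":
            north[i] = north[j] = True
        else:
            south[i] = south[j] = True
    both = north & south
    if south.sum() > north.sum():
        south &= ~both
    else:
        north &= ~both
    fan.north_members = np.flatnonzero(north)
    fan.south_members = np.flatnonzero(south)
    return fan


def _contiguous_cyclic(members: np.ndarray, m: int) -> np.ndarray:
    """Order region members along the cyclic maxima sequence."""
    s = set(members.tolist())
    if len(s) == m:
        return np.sort(members)
    # rotate so the run does not straddle the wrap point
    start = 0
    while start < m and (start in s or (start - 1) % m in s):
        start += 1
    ordered = [k for k in ((start + i) % m for i in range(m)) if k in s]
    return np.array(ordered, dtype=np.int64)


def select_poles(fan: VertexFan) -> tuple[np.ndarray, np.ndarray]:
    """Median maximum of each region; two medians for even counts.

    Returns contour indices ``(NP, SP)`` (arrays of one or two indices).
    """
    if fan.north_members is None or fan.south_members is None:
        raise PoleSelectionError("pole selection failed: run split_north_south first")
    if len(fan.north_members) == 0 or len(fan.south_members) == 0:
        raise PoleSelectionError("pole selection failed: empty region")

    def median_of(members: np.ndarray) -> np.ndarray:
        run = _contiguous_cyclic(members, fan.m)
        n = len(run)
        if n % 2 == 1:
            chosen = run[[(n + 1) // 2 - 1]]
        else:
            chosen = run[[n // 2 - 1, n // 2]]
        return fan.maxima_indices[chosen]

    return median_of(fan.north_members), median_of(fan.south_members)


def locate_poles(
    contour: Contour,
    centroid: Centroid,
    signature: Signature,
    consolidated: ConsolidatedExtrema,
    config: RunConfig = DEFAULT_CONFIG,
) -> PoleRegions:
    """Poles + regions, falling back gracefully for unlobed leaves.

    With >= 3 maxima the vertex-fan route is used; with exactly 2 the maxima
    themselves are the poles; otherwise the signature's global maximum and
    the point half a contour away serve as poles (an entire, unlobed leaf
    has no angular structure to exploit).
    """
    maxima = consolidated.peak_positions
    minima = consolidated.valley_positions
    n = contour.n
    c = np.array([centroid.cx, centroid.cy])

    if len(maxima) > 12:
        # margin teeth have leaked into the consolidated maxima (deep teeth
        # approach lobe scale at the smallest threshold).  Apex and base are
        # features of the gross blade shape, so take the maxima of the
        # largest threshold that still shows structure.
        for es in reversed(consolidated.per_threshold):
            if 1 <= len(es.peaks) <= 12:
                maxima = es.peak_indices
                minima = es.valley_indices
                break

    def opposition(a: np.ndarray, b: np.ndarray) -> float:
        """Angle (deg) subtended at the centroid by the two pole centres."""
        u = contour.points[_pole_center(a, n)] - c
        v = contour.points[_pole_center(b, n)] - c
        cosv = np.dot(u, v) / max(np.linalg.norm(u) * np.linalg.norm(v), 1e-9)
        return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))

    np_idx = sp_idx = None
    method = "fan"
    if len(maxima) >= 3:
        try:
            fan = build_vertex_fan(maxima, contour, centroid)
            fan = split_north_south(fan, config.thres_norm)
            np_idx, sp_idx = select_poles(fan)
            # apex and base face each other; a fan that pairs neighbouring
            # maxima as poles is spurious (side bumps), so reject it
            if opposition(np_idx, sp_idx) < 120.0:
                np_idx = None
        except (DegenerateFanError, PoleSelectionError):
            np_idx = None
    if np_idx is None and len(maxima) == 2:
        np_idx, sp_idx = maxima[:1], maxima[1:]
        method = "two_maxima"
    if np_idx is None and len(maxima) >= 3:
        # most-opposite pair: the strongest maximum vs the maximum whose
        # centroid ray points farthest away from it
        dvals = signature.dist[maxima]
        p = maxima[int(np.argmax(dvals))]
        dirs = contour.points[maxima] - c
        dirs = dirs / np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-9)
        ref = contour.points[p] - c
        ref = ref / max(np.linalg.norm(ref), 1e-9)
        q = maxima[int(np.argmin(dirs @ ref))]
        np_idx = np.array([p], dtype=np.int64)
        sp_idx = np.array([q], dtype=np.int64)
        method = "opposite_maxima"
    if np_idx is None:
        p = int(np.argmax(signature.dist))
        np_idx = np.array([p], dtype=np.int64)
        sp_idx = np.array([(p + n // 2) % n], dtype=np.int64)
        method = "extreme_distance"
        minima = np.array([], dtype=np.int64)

    part_np, part_sp = extract_pole_regions(contour, np_idx, sp_idx, minima, config)
    return PoleRegions(
        np_indices=np_idx, sp_indices=sp_idx, part_np=part_np, part_sp=part_sp,
        method=method,
    )


# ---------------------------------------------------------------------------
# pole regions


def _cyclic_span(lo: int, hi: int, n: int) -> np.ndarray:
    if hi >= lo:
        return np.arange(lo, hi + 1, dtype=np.int64)
    return np.concatenate([np.arange(lo, n, dtype=np.int64), np.arange(0, hi + 1, dtype=np.int64)])


def _cyclic_mid(a: int, b: int, n: int) -> int:
    fwd = (b - a) % n
    return int((a + fwd // 2) % n)


def _pole_center(pole: np.ndarray, n: int) -> int:
    """Contour index at the middle of a 1- or 2-point pole (shorter arc)."""
    if len(pole) == 1:
        return int(pole[0])
    a, b = int(pole[0]), int(pole[-1])
    fwd = (b - a) % n
    if fwd <= n - fwd:
        return int((a + fwd // 2) % n)
    return int((b + (n - fwd) // 2) % n)


def extract_pole_regions(
    contour: Contour,
    np_indices: np.ndarray,
    sp_indices: np.ndarray,
    minima: np.ndarray,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Contour segments around each pole, bounded by flanking local minima.

    A single-point pole spans between the nearest minima on each side; a
    two-point pole spans between the outer flanking minima of the pair.
    With no minima (entire leaf) a fixed contour fraction around the pole is
    used.  Segments are capped to ``region_cap_fraction`` of the contour and
    trimmed if they would overlap.
    """
    n = contour.n
    minima = np.sort(np.asarray(minima, dtype=np.int64))

    def region(pole: np.ndarray) -> np.ndarray:
        lo_pole, hi_pole = int(pole[0]), int(pole[-1])
        center = _pole_center(pole, n)
        if len(minima) == 0:
            half = max(2, int(round(config.pole_fallback_fraction * n / 2)))
            seg = _cyclic_span((center - half) % n, (center + half) % n, n)
        else:
            before = minima[minima < lo_pole]
            left = int(before[-1]) if len(before) else int(minima[-1])
            after = minima[minima > hi_pole]
            right = int(after[0]) if len(after) else int(minima[0])
            seg = _cyclic_span(left, right, n)
        cap = max(5, int(round(config.region_cap_fraction * n)))
        if len(seg) > cap:
            hit = np.flatnonzero(seg == center)
            mid = int(hit[0]) if len(hit) else len(seg) // 2
            lo = min(max(0, mid - cap // 2), len(seg) - cap)
            seg = seg[lo : lo + cap]
        return seg

    part_np, part_sp = region(np.sort(np_indices)), region(np.sort(sp_indices))
    overlap = np.intersect1d(part_np, part_sp)
    if len(overlap):
        keep_np = ~np.isin(part_np, overlap)
        keep_sp = ~np.isin(part_sp, overlap)
        part_np, part_sp = part_np[keep_np], part_sp[keep_sp]

    def fallback(pole: np.ndarray) -> np.ndarray:
        center = _pole_center(pole, n)
        half = max(2, int(round(config.pole_fallback_fraction * n / 2)))
        return _cyclic_span((center - half) % n, (center + half) % n, n)

    # a pathological minima layout can empty a segment; fall back then
    if len(part_np) < 5:
        part_np = fallback(np.sort(np_indices))
        part_sp = part_sp[~np.isin(part_sp, part_np)]
    if len(part_sp) < 5:
        part_sp = fallback(np.sort(sp_indices))
        part_np = part_np[~np.isin(part_np, part_sp)]
    return part_np, part_sp


# ---------------------------------------------------------------------------
# mid-vein width and apex/base disambiguation


def _vein_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Classify mid-vein pixels inside the lamina.

    Colour input: the hue axis is discretised into 12 bins and pixels whose
    bin differs from the lamina's dominant bin are vein candidates.
    Greyscale input: an intensity ridge darker than the lamina median.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        hsv = skcolor.rgb2hsv(arr[..., :3])
        bins = np.minimum((hsv[..., 0] * 12).astype(int), 11)
        vals, counts = np.unique(bins[mask], return_counts=True)
        dominant = vals[np.argmax(counts)]
        return mask & (bins != dominant)
    gray = arr.astype(float)
    if gray.max() > 1.0:
        gray = gray / 255.0
    med = np.median(gray[mask])
    return mask & (gray < med - 0.1)


def measure_midvein_width(
    image: np.ndarray,
    mask: BinaryLeafImage,
    center: np.ndarray,
    axis_dir: np.ndarray,
    half_side: float,
) -> float:
    """Mean cross-axis run length of vein pixels in a square window.

    ``center`` is the window centre (x, y); ``axis_dir`` the unit NP->SP
    axis.  At each station along the axis the vein run nearest the axis is
    measured perpendicular to it.
    """
    vein = _vein_mask(image, mask.mask)
    if vein.sum() < 10:
        raise VeinUndetectableError("vein undetectable")
    h, w = vein.shape
    axis = np.asarray(axis_dir, float)
    axis = axis / max(np.linalg.norm(axis), 1e-9)
    perp = np.array([-axis[1], axis[0]])
    steps = np.arange(-half_side, half_side + 1.0)
    # sampling grid: rows = stations along the axis, cols = cross-axis offsets
    q = (
        np.asarray(center, float)[None, None, :]
        + steps[:, None, None] * axis[None, None, :]
        + steps[None, :, None] * perp[None, None, :]
    )
    cols = np.clip(np.round(q[..., 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(q[..., 1]).astype(int), 0, h - 1)
    inside = (q[..., 0] >= 0) & (q[..., 0] < w) & (q[..., 1] >= 0) & (q[..., 1] < h)
    hits = vein[rows, cols] & inside

    widths = []
    mid = len(steps) // 2
    for hit in hits:
        if not hit.any():
            continue
        runs = _runs(hit)
        best = min(runs, key=lambda ab: min(abs(ab[0] - mid), abs(ab[1] - 1 - mid)))
        widths.append(best[1] - best[0])
    if not widths:
        raise VeinUndetectableError("vein undetectable")
    return float(np.mean(widths))


def _runs(boolean: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    padded = np.concatenate([[False], boolean, [False]]).astype(int)
    d = np.diff(padded)
    starts, stops = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def disambiguate_apex_base(
    image: np.ndarray,
    mask: BinaryLeafImage,
    contour: Contour,
    poles: PoleRegions,
    centroid: Centroid,
) -> PoleRegions:
    """Assign apex/base by mid-vein width: the wider-vein pole is the base.

    Fills ``apex_is_north`` and the rotation (degrees, counterclockwise)
    that would put the apex at the top of the frame.  Raises
    ``VeinUndetectableError`` when no vein can be measured at either window.
    """
    n = contour.n
    np_pt = contour.points[_pole_center(poles.np_indices, n)].astype(float)
    sp_pt = contour.points[_pole_center(poles.sp_indices, n)].astype(float)
    axis = sp_pt - np_pt
    length = np.linalg.norm(axis)
    if length < 1e-6:
        raise PoleSelectionError("pole selection failed: coincident poles")
    axis = axis / length
    half_side = max(4.0, centroid.incircle_radius / 2.0)
    # windows at 1/4 and 3/4 of the pole-to-pole axis
    w_np = measure_midvein_width(image, mask, np_pt + 0.25 * length * axis, axis, half_side)
    w_sp = measure_midvein_width(image, mask, np_pt + 0.75 * length * axis, axis, half_side)

    poles.apex_is_north = w_sp >= w_np  # wider vein at the south end => south is base
    apex_pt = np_pt if poles.apex_is_north else sp_pt
    v = apex_pt - np.array([centroid.cx, centroid.cy])
    screen_angle = np.degrees(np.arctan2(-v[1], v[0]))  # y grows downward
    poles.rotation_deg = float((90.0 - screen_angle) % 360.0)
    return poles


def align_apex_up(image: np.ndarray, poles: PoleRegions) -> np.ndarray:
    """Rotated copy of ``image`` with the leaf apex pointing up."""
    if poles.rotation_deg is None:
        raise PoleSelectionError("apex/base not yet disambiguated")
    return ndimage.rotate(image, -poles.rotation_deg, reshape=True, order=0, mode="nearest")


# ---------------------------------------------------------------------------
# Centroid Contour Gradient


def ccg(
    region_pts: np.ndarray,
    pole_pt: np.ndarray,
    theta: float = DEFAULT_CONFIG.ccg_interval,
    gradient_cap: float = DEFAULT_CONFIG.gradient_cap,
    strict: bool = False,
    center: np.ndarray | None = None,
) -> CCGVector:
    """Chord gradients of the tip outline sampled per interval angle.

    One boundary point is chosen per angle in {0, theta, ..., 90} on the
    right side of the tip axis (nearest point in polar angle about the
    region centroid).  Gradients are ``|dY/dX|`` between consecutive
    samples in the tip frame; a vertical chord is capped at
    ``gradient_cap``.  With ``strict`` a ray with no nearby boundary point
    raises :class:`IncompleteCCGError`; otherwise it is dropped.
    """
    if theta <= 0 or 90.0 % theta != 0:
        raise ValueError("theta must divide 90")
    pts = np.asarray(region_pts, float)
    pole = np.asarray(pole_pt, float)
    if center is not None:
        c = np.asarray(center, float)
    else:
        # region centroid: midway between the pole and the mouth of the segment
        mouth = 0.5 * (pts[0] + pts[-1])
        c = 0.5 * (pole + mouth)
    yhat = pole - c
    ny = np.linalg.norm(yhat)
    if ny < 1e-9:
        yhat = np.array([0.0, -1.0])
        ny = 1.0
    yhat = yhat / ny
    # right side of the tip axis, screen convention (y grows downward)
    xhat = np.array([-yhat[1], yhat[0]])

    rel = pts - c
    a = rel @ xhat
    b = rel @ yhat
    ang = np.degrees(np.arctan2(b, a))

    targets = np.arange(0.0, 90.0 + 1e-9, theta)
    tol = max(1.5, theta / 6.0)
    sel_idx, sel_ang, missing = [], [], []
    for t in targets:
        diff = np.abs(ang - t)
        i = int(np.argmin(diff))
        if diff[i] <= tol:
            sel_idx.append(i)
            sel_ang.append(t)
        else:
            missing.append(float(t))
    if missing and strict:
        raise IncompleteCCGError(missing)
    if len(sel_idx) < 2:
        raise IncompleteCCGError(missing or targets.tolist())

    ax, by = a[sel_idx], b[sel_idx]
    dx, dy = np.diff(ax), np.diff(by)
    grads = np.where(np.abs(dx) < 1e-9, gradient_cap, np.abs(dy / np.where(dx == 0, 1e-9, dx)))
    grads = np.minimum(np.abs(grads), gradient_cap)
    return CCGVector(
        interval_angle=float(theta),
        angles=np.asarray(sel_ang),
        sample_points=pts[sel_idx],
        gradients=grads,
    )


# ---------------------------------------------------------------------------
# tip-type classification


def _flank_geometry(region_pts: np.ndarray, pole_pt: np.ndarray, centroid: Centroid):
    """Fitted-flank summary of a tip region.

    Returns (angle_deg, straightness, convexity, local_tip_angle,
    flank_angle_asymmetry).  Straightness is the worse of the two flanks'
    rms line-fit residual over chord length; convexity is positive when the
    flanks bulge away from the leaf centroid (a smooth arc) and negative
    when they are incurved.
    """
    pts = np.asarray(region_pts, float)
    pole = np.asarray(pole_pt, float)
    i = int(np.argmin(np.linalg.norm(pts - pole, axis=1)))
    flanks = [pts[: i + 1][::-1], pts[i:]]  # each runs pole -> outward
    c = np.array([centroid.cx, centroid.cy])
    axis = pole - c
    axis = axis / max(np.linalg.norm(axis), 1e-9)

    dirs, straight, convex, local_dirs, axis_angles = [], [], [], [], []
    for fl in flanks:
        if len(fl) < 6:
            return None
        fl = fl[2:]  # skip the rounded very tip
        d = fl - fl.mean(axis=0)
        _, _, vt = np.linalg.svd(d, full_matrices=False)
        direction = vt[0]
        if np.dot(direction, fl[-1] - fl[0]) < 0:
            direction = -direction
        chord = fl[-1] - fl[0]
        clen = max(np.linalg.norm(chord), 1e-9)
        u = chord / clen
        rel = fl - fl[0]
        resid = np.abs(u[0] * rel[:, 1] - u[1] * rel[:, 0])
        straight.append(float(np.sqrt(np.mean(resid**2)) / clen))
        # bulge sign: + when the mid-flank lies farther from the axis than the chord
        nvec = np.array([-(chord / clen)[1], (chord / clen)[0]])
        away = nvec if np.dot(nvec, fl.mean(axis=0) - c) > 0 else -nvec
        mid = fl[len(fl) // 3 : 2 * len(fl) // 3]
        convex.append(float(np.mean((mid - fl[0]) @ away) / clen))
        dirs.append(direction)
        local = fl[: max(4, len(fl) // 6)]
        ld = local[-1] - local[0]
        local_dirs.append(ld / max(np.linalg.norm(ld), 1e-9))
        axis_angles.append(
            float(np.degrees(np.arccos(np.clip(abs(np.dot(direction, axis)), -1, 1))))
        )

    def between(u, v):
        return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))

    angle = between(dirs[0], dirs[1])
    local_angle = between(local_dirs[0], local_dirs[1])
    return (
        angle,
        max(straight),
        float(np.mean(convex)),
        local_angle,
        abs(axis_angles[0] - axis_angles[1]),
    )


def _has_notch(region_pts: np.ndarray, centroid: Centroid, min_depth: float = 25.0) -> bool:
    """Central dip in centroid distance between two flanking humps (cordate)."""
    pts = np.asarray(region_pts, float)
    d = np.hypot(pts[:, 0] - centroid.cx, pts[:, 1] - centroid.cy)
    n = len(d)
    if n < 15:
        return False
    lo, hi = n // 4, 3 * n // 4
    mid = lo + int(np.argmin(d[lo:hi]))
    left_max = d[:mid].max()
    right_max = d[mid:].max()
    return bool(left_max - d[mid] >= min_depth and right_max - d[mid] >= min_depth)


_STRAIGHT_TOL = 0.035
_CONVEX_TOL = 0.015


def _tip_width_fraction(
    region_pts: np.ndarray, pole_pt: np.ndarray, centroid: Centroid, depth_frac: float = 0.03
) -> float:
    """Cross-axis width just behind the tip over the region's widest span.

    Candidate tip axes around the centroid->pole ray are swept and the
    maximum fraction returned: a flat, cut-off (truncate) tip exposes its
    full width at the right orientation, while a pointed tip or a smooth
    arc stays narrow at every orientation.  (The distance maximum of a
    flat tip sits on a corner, so no single axis can be trusted.)
    """
    pts = np.asarray(region_pts, float)
    c = np.array([centroid.cx, centroid.cy])
    base = np.asarray(pole_pt, float) - c
    base_ang = np.arctan2(base[1], base[0])
    best = 0.0
    for off in np.radians(np.arange(-30.0, 30.1, 6.0)):
        axis = np.array([np.cos(base_ang + off), np.sin(base_ang + off)])
        perp = np.array([-axis[1], axis[0]])
        depth = -(pts @ axis)
        span = depth.max() - depth.min()
        if span < 1e-6:
            return 1.0
        near = pts[depth <= depth.min() + depth_frac * span]
        if len(near) < 2:
            continue
        cross = near @ perp
        full = pts @ perp
        best = max(best, float((cross.max() - cross.min()) / max(full.max() - full.min(), 1e-9)))
    return best




def classify_apex_type(
    ccg_vec: CCGVector | None,
    region_pts: np.ndarray,
    pole_pt: np.ndarray,
    centroid: Centroid,
) -> tuple[str, float, float]:
    """Label the apex and return (label, apex_angle_deg, confidence).

    An abruptly incurved tip under 45 degrees is acuminate; straight flanks
    meeting between 45 and 90 degrees are acute; flanks curving outward
    into a smooth arc are rounded.  Obtuse (straight, > 90), cuspidate
    (arc with an abrupt terminal spike) and truncate (flat top) complete
    the vocabulary.
    """
    geom = _flank_geometry(region_pts, pole_pt, centroid)
    if geom is None:
        return "rounded", 180.0, 0.0
    angle, straightness, convexity, local_angle, _ = geom

    if local_angle < 50.0 and angle > local_angle + 40.0:
        return "cuspidate", local_angle, 0.7
    if _tip_width_fraction(region_pts, pole_pt, centroid, depth_frac=0.03) > 0.40:
        return "truncate", angle, 0.8
    if straightness < _STRAIGHT_TOL or abs(convexity) < _CONVEX_TOL:
        if angle < 45.0:
            return "acuminate", angle, 0.9
        if angle <= 95.0:
            return "acute", angle, 0.9
        return "obtuse", angle, 0.8
    if convexity < 0:
        return "acuminate", angle, 0.85
    return "rounded", angle, 0.85


def classify_base_type(
    ccg_vec: CCGVector | None,
    region_pts: np.ndarray,
    pole_pt: np.ndarray,
    centroid: Centroid,
) -> tuple[str, float, float]:
    """Label the base and return (label, base_angle_deg, confidence).

    A central notch between two rounded humps is cordate; straight flanks
    make a cuneate (wedge) base, or obtuse past 95 degrees; incurved
    tapering flanks are attenuate; an outward smooth arc is rounded;
    strongly asymmetric flank slopes are oblique.
    """
    if _has_notch(region_pts, centroid):
        geom = _flank_geometry(region_pts, pole_pt, centroid)
        return "cordate", geom[0] if geom else 120.0, 0.9
    geom = _flank_geometry(region_pts, pole_pt, centroid)
    if geom is None:
        return "rounded", 180.0, 0.0
    angle, straightness, convexity, _, asym = geom
    if asym > 25.0 and straightness < _STRAIGHT_TOL:
        return "oblique", angle, 0.7
    if straightness < _STRAIGHT_TOL or abs(convexity) < _CONVEX_TOL:
        if angle <= 95.0:
            return "cuneate", angle, 0.9
        return "obtuse", angle, 0.8
    if convexity < 0:
        return "attenuate", angle, 0.85
    return "rounded", angle, 0.85
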