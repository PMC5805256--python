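"""Synthetic single-leaf image generator with exact ground truth.

Two constructions are used:

* **lobed leaves** (``n_lobes >= 1``): a polar outline about the blade
  centre, ``r(phi) = E(phi) * (1 + a*cos(n_lobes*(phi - 90deg)))`` with
  ``E`` an ellipse envelope — the waveform frequency makes the lobe and
  sinus counts exact by construction;
* **unlobed leaves** (``n_lobes == 0``): a half-width profile ``w(u)`` along
  the midrib, ``u`` running 0 (base) to 1 (apex), whose taper shape and
  taper angle set the apex/base curvature type (straight, concave,
  elliptical arc, flat cut, notched).

Margin teeth are a displacement of the smooth outline along its outward
normal.  The displacement amplitude at each point is
``teeth_amplitude * (distance of the point to the midrib axis)``, so
``teeth_amplitude`` directly targets the tooth-height-to-midrib ratio that
separates diminutive (< 1/16) from regular (1/16..1/8) teeth.  Waveforms:
``saw`` an asymmetric ramp (unequal flank chords, type 1), ``triangular`` a
slightly concave symmetric ramp (triangularity < 1, type 2), ``rounded`` a
fat rectified sine (triangularity > 1, type 3).

All leaves carry an optional petiole and an optional mid-vein stripe that
is wider at the base than at the apex — the cue the pipeline uses to tell
apex from base.  Rasterisation is deterministic; the dataset generator
drives all jitter from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import InvalidSpecError

__all__ = ["LeafSpec", "GroundTruth", "generate_leaf", "generate_dataset", "write_dataset"]

APEX_TYPES = ("acuminate", "acute", "cuspidate", "obtuse", "rounded", "truncate")
BASE_TYPES = ("attenuate", "cuneate", "obtuse", "rounded", "cordate", "oblique")
WAVEFORMS = ("saw", "triangular", "rounded")

# colours (RGB) of the rendered leaf
_BG = (242, 242, 238)
_LAMINA = (70, 142, 78)
_VEIN = (128, 104, 64)
_BG_GRAY, _LAMINA_GRAY, _VEIN_GRAY = 242, 96, 46


@dataclass
class LeafSpec:
    """Generator parameters; amplitudes are fractions (see module docs)."""

    n_lobes: int = 0
    lobe_amplitude: float = 0.0
    teeth_count: int = 0
    teeth_waveform: str = "saw"
    teeth_amplitude: float = 0.0
    doubly_teeth: bool = False
    apex_type: str = "acute"
    base_type: str = "cuneate"
    apex_flank_angle: float = 70.0
    base_flank_angle: float = 70.0
    elongation: float = 1.6
    petiole: bool = False
    vein_stripe: bool = True
    color: bool = True
    rotation: float = 0.0
    scale: int = 470
    seed: int = 0

    def validate(self) -> None:
        if self.n_lobes < 0:
            raise InvalidSpecError("n_lobes must be >= 0")
        if self.n_lobes and not 0.0 < self.lobe_amplitude < 0.5:
            raise InvalidSpecError("lobe_amplitude must lie in (0, 0.5)")
        if self.teeth_count and not 0.0 < self.teeth_amplitude < 0.5:
            raise InvalidSpecError("teeth_amplitude must lie in (0, 0.5)")
        if self.teeth_count and self.n_lobes and self.teeth_amplitude >= self.lobe_amplitude:
            raise InvalidSpecError("teeth_amplitude must be below lobe_amplitude")
        if self.teeth_waveform not in WAVEFORMS:
            raise InvalidSpecError(f"unknown waveform {self.teeth_waveform!r}")
        if self.apex_type not in APEX_TYPES:
            raise InvalidSpecError(f"unknown apex type {self.apex_type!r}")
        if self.base_type not in BASE_TYPES:
            raise InvalidSpecError(f"unknown base type {self.base_type!r}")
        if self.elongation < 1.0:
            raise InvalidSpecError("elongation must be >= 1")
        if self.scale < 64:
            raise InvalidSpecError("scale too small to rasterise")


@dataclass
class GroundTruth:
    """The spec plus the labels the pipeline is expected to recover."""

    spec: LeafSpec
    lobes: int | None
    sinuses: int | None
    teeth: int
    margin_class: str
    apex_type: str | None
    base_type: str | None
    species_label: str | None = None


# ---------------------------------------------------------------------------
# smooth outline constructions


def _taper_span(angle_deg: float, half_width: float, length: float) -> float:
    half = np.tan(np.radians(min(max(angle_deg, 5.0), 170.0) / 2.0))
    return float(np.clip(half_width / (length * half), 0.12, 0.48))


def _apex_factor(u: np.ndarray, spec: LeafSpec, L: float, W2: float) -> np.ndarray:
    t = spec.apex_type
    span = _taper_span(spec.apex_flank_angle, W2, L)
    if t == "rounded":
        span = 0.38
    s = np.clip((u - (1.0 - span)) / span, 0.0, 1.0)
    if t in ("acute", "obtuse"):
        return 1.0 - s
    if t == "acuminate":
        return (1.0 - s) ** 2.2
    if t == "rounded":
        return np.sqrt(np.clip(1.0 - s**2, 0.0, 1.0))
    if t == "truncate":
        return 1.0 - 0.5 * s
    if t == "cuspidate":
        arc = 0.10 + 0.90 * np.sqrt(np.clip(1.0 - s**2, 0.0, 1.0))
        spike = 0.10 * np.clip((1.0 - u) / 0.10, 0.0, 1.0)
        return np.where(u < 0.90, arc, np.minimum(arc, np.maximum(spike, 0.0)))
    raise InvalidSpecError(f"unknown apex type {t!r}")


def _base_factor(u: np.ndarray, spec: LeafSpec, L: float, W2: float, side: int) -> np.ndarray:
    t = spec.base_type
    span = _taper_span(spec.base_flank_angle, W2, L)
    if t in ("rounded", "cordate"):
        span = 0.30
    if t == "oblique":
        span = 0.22 if side > 0 else 0.44
    s = np.clip(1.0 - u / span, 0.0, 1.0)  # 1 at base tip -> 0 at taper end
    if t in ("cuneate", "obtuse", "oblique"):
        return 1.0 - s
    if t == "attenuate":
        return (1.0 - s) ** 2.2
    if t in ("rounded", "cordate"):
        return np.sqrt(np.clip(1.0 - s**2, 0.0, 1.0))
    raise InvalidSpecError(f"unknown base type {t!r}")


def _profile_outline(spec: LeafSpec, pts_per_side: int = 1400) -> np.ndarray:
    """Closed smooth outline of an unlobed leaf, maths coords (y up)."""
    L = float(spec.scale)
    W2 = L / (2.0 * spec.elongation)
    u = np.linspace(0.0, 1.0, pts_per_side)
    apex = _apex_factor(u, spec, L, W2)
    # gentle width envelope: a real lamina has no parallel-sided stretch,
    # and straight sides would put spurious oscillations in the signature
    env = 1.0 - 0.18 * (2.0 * u - 1.0) ** 2
    apex = apex * env
    w_r = W2 * apex * _base_factor(u, spec, L, W2, side=+1)
    w_l = W2 * apex * _base_factor(u, spec, L, W2, side=-1)
    y = u * L
    right = np.column_stack([w_r, y])
    left = np.column_stack([-w_l[::-1], y[::-1]])
    pts = np.concatenate([right, left])
    # drop consecutive near-duplicates (tip points collapse)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-6
    return pts[keep]


def _polar_outline(spec: LeafSpec, n_pts: int = 4096) -> np.ndarray:
    """Closed lobed outline about the blade centre, maths coords (y up)."""
    L2 = spec.scale / 2.0
    W2 = L2 / spec.elongation
    phi = np.linspace(0.0, 2.0 * np.pi, n_pts, endpoint=False)
    # ellipse envelope: long axis along y (apex up)
    env = (L2 * W2) / np.hypot(W2 * np.sin(phi - np.pi / 2), L2 * np.cos(phi - np.pi / 2))
    a = spec.lobe_amplitude
    r = env * (1.0 + a * np.cos(spec.n_lobes * (phi - np.pi / 2))) / (1.0 + a)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


# ---------------------------------------------------------------------------
# margin teeth


def _tooth_profile(frac: np.ndarray, waveform: str) -> np.ndarray:
    if waveform == "saw":
        return np.where(frac < 0.75, frac / 0.75, (1.0 - frac) / 0.25)
    if waveform == "triangular":
        return (1.0 - np.abs(2.0 * frac - 1.0)) ** 1.35
    if waveform == "rounded":
        return np.abs(np.sin(np.pi * frac)) ** 0.6
    raise InvalidSpecError(f"unknown waveform {waveform!r}")


def _add_teeth(pts: np.ndarray, spec: LeafSpec, radial: bool = False) -> np.ndarray:
    """Displace the outline with the tooth wave.

    Unlobed (profile) leaves: displacement along the outward normal with
    amplitude proportional to the local midrib distance, so
    ``teeth_amplitude`` targets the height-to-midrib ratio directly.
    Lobed (polar) leaves: radial displacement of constant amplitude —
    uniform teeth superimposed on the lobe waveform.
    """
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen[:-1])])
    total = arclen[-1] + seglen[-1]

    phase = arclen / total * spec.teeth_count
    frac = phase % 1.0
    if radial:
        height = np.full(len(pts), spec.teeth_amplitude * 0.8 * np.abs(pts[:, 0]).max())
    else:
        height = spec.teeth_amplitude * np.abs(pts[:, 0])
    if spec.doubly_teeth:
        height = height * np.where(np.floor(phase).astype(int) % 2 == 0, 1.0, 0.45)

    wavelength = total / spec.teeth_count
    if np.max(height) > 0.9 * wavelength:
        raise InvalidSpecError("invalid spec: teeth amplitude causes self-intersection")

    if radial:
        direction = pts / np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1e-9)
    else:
        # outward normal of a counterclockwise (maths coords) polygon
        tang = np.vstack([pts[1:], pts[:1]]) - np.vstack([pts[-1:], pts[:-1]])
        direction = np.column_stack([tang[:, 1], -tang[:, 0]])
        direction /= np.maximum(np.linalg.norm(direction, axis=1, keepdims=True), 1e-9)
    return pts + direction * (height * _tooth_profile(frac, spec.teeth_waveform))[:, None]


# ---------------------------------------------------------------------------
# rasterisation


def _rotate(pts: np.ndarray, deg: float) -> np.ndarray:
    a = np.radians(deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pts @ rot.T


def _rasterise(polys: list[np.ndarray], rotation: float, pad: int = 12):
    """Rotate maths-coord polygons, map to image rows/cols, fill each."""
    rotated = [_rotate(p, rotation) for p in polys]
    allpts = np.concatenate([p for p in rotated if len(p)])
    xmin, ymin = allpts.min(axis=0)
    xmax, ymax = allpts.max(axis=0)
    width = int(np.ceil(xmax - xmin)) + 2 * pad
    height = int(np.ceil(ymax - ymin)) + 2 * pad
    masks = []
    for p in rotated:
        if len(p) < 3:
            masks.append(np.zeros((height, width), dtype=bool))
            continue
        rows = (ymax - p[:, 1]) + pad
        cols = (p[:, 0] - xmin) + pad
        im = Image.new("1", (width, height), 0)
        ImageDraw.Draw(im).polygon(
            list(zip(cols.tolist(), rows.tolist())), fill=1, outline=1
        )
        masks.append(np.asarray(im, dtype=bool))
    return masks


def _derive_truth(spec: LeafSpec) -> GroundTruth:
    if spec.teeth_count == 0 or spec.teeth_amplitude <= 0:
        margin = "entire"
    elif spec.teeth_waveform == "saw":
        if spec.doubly_teeth:
            margin = "doubly_serrate"
        else:
            margin = "serrulate" if spec.teeth_amplitude < 1.0 / 16.0 else "serrate"
    elif spec.teeth_waveform == "triangular":
        margin = "denticulate" if spec.teeth_amplitude < 1.0 / 16.0 else "dentate"
    else:
        margin = "crenulate" if spec.teeth_amplitude < 1.0 / 16.0 else "crenate"
    lobed = spec.n_lobes >= 2
    return GroundTruth(
        spec=spec,
        lobes=spec.n_lobes if lobed else None,
        sinuses=spec.n_lobes if lobed else None,
        teeth=spec.teeth_count,
        margin_class=margin,
        apex_type=None if lobed else spec.apex_type,
        base_type=None if lobed else spec.base_type,
    )


def generate_leaf(spec: LeafSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the leaf described by ``spec``; returns (image, ground truth).

    The image is uint8, RGB if ``spec.color`` else greyscale, leaf dark on a
    light background, with the mid-vein stripe (if any) in a distinct
    hue/intensity tapering from base to apex.
    """
    spec.validate()
    if spec.n_lobes >= 1:
        smooth = _polar_outline(spec)
    else:
        smooth = _profile_outline(spec)
    outline = (
        _add_teeth(smooth, spec, radial=spec.n_lobes >= 1)
        if spec.teeth_count
        else smooth
    )

    polys = [outline]
    ymin, ymax = smooth[:, 1].min(), smooth[:, 1].max()
    yrange = ymax - ymin

    if spec.base_type == "cordate" and spec.n_lobes == 0:
        W2 = spec.scale / (2.0 * spec.elongation)
        nw, nd = 0.35 * W2, 0.13 * spec.scale
        notch = np.array(
            [[-nw, ymin - 3.0], [-0.30 * nw, 0.55 * nd], [0.0, nd],
             [0.30 * nw, 0.55 * nd], [nw, ymin - 3.0]]
        )
        polys.append(notch)
    else:
        polys.append(np.empty((0, 2)))

    if spec.petiole:
        pet = np.array(
            [[-2.5, ymin - 0.16 * yrange], [2.5, ymin - 0.16 * yrange],
             [2.5, ymin + 2.0], [-2.5, ymin + 2.0]]
        )
        polys.append(pet)
    else:
        polys.append(np.empty((0, 2)))

    if spec.vein_stripe:
        yv = np.linspace(ymin + 0.03 * yrange, ymax - 0.05 * yrange, 60)
        uv = (yv - yv[0]) / (yv[-1] - yv[0])
        wv = 4.5 - 3.3 * uv
        vein = np.concatenate(
            [np.column_stack([wv, yv]), np.column_stack([-wv[::-1], yv[::-1]])]
        )
        polys.append(vein)
    else:
        polys.append(np.empty((0, 2)))

    leaf_m, notch_m, pet_m, vein_m = _rasterise(polys, spec.rotation)
    mask = leaf_m & ~notch_m
    mask |= pet_m
    vein = vein_m & mask

    if spec.color:
        img = np.empty(mask.shape + (3,), dtype=np.uint8)
        img[:] = _BG
        img[mask] = _LAMINA
        img[vein] = _VEIN
        img[pet_m] = _VEIN
    else:
        img = np.full(mask.shape, _BG_GRAY, dtype=np.uint8)
        img[mask] = _LAMINA_GRAY
        img[vein] = _VEIN_GRAY
        img[pet_m] = _VEIN_GRAY
    return img, _derive_truth(spec)


# ---------------------------------------------------------------------------
# dataset generation

# palette of distinct species morphologies; cycled when n_species is larger
_SPECIES_PALETTE: list[dict] = [
    dict(elongation=1.7, apex_type="acute", apex_flank_angle=70, base_type="cuneate"),
    dict(elongation=1.5, apex_type="acuminate", apex_flank_angle=32, base_type="attenuate",
         teeth_count=34, teeth_waveform="saw", teeth_amplitude=0.095),
    dict(elongation=1.25, apex_type="rounded", base_type="rounded",
         teeth_count=30, teeth_waveform="rounded", teeth_amplitude=0.095),
    dict(elongation=1.35, apex_type="acute", apex_flank_angle=75, base_type="rounded",
         teeth_count=32, teeth_waveform="triangular", teeth_amplitude=0.095),
    dict(n_lobes=3, lobe_amplitude=0.30, elongation=1.2),
    dict(n_lobes=5, lobe_amplitude=0.32, elongation=1.25),
    dict(n_lobes=7, lobe_amplitude=0.28, elongation=1.15),
    dict(elongation=1.8, apex_type="acute", apex_flank_angle=60, base_type="cuneate",
         teeth_count=38, teeth_waveform="saw", teeth_amplitude=0.045),
    dict(elongation=1.3, apex_type="rounded", base_type="cordate",
         teeth_count=34, teeth_waveform="rounded", teeth_amplitude=0.045),
    dict(elongation=1.5, apex_type="acute", apex_flank_angle=65, base_type="cuneate",
         teeth_count=28, teeth_waveform="saw", teeth_amplitude=0.095, doubly_teeth=True),
    dict(elongation=1.4, apex_type="acute", apex_flank_angle=80, base_type="rounded",
         teeth_count=36, teeth_waveform="triangular", teeth_amplitude=0.045),
    dict(n_lobes=5, lobe_amplitude=0.35, elongation=1.35),
]


def _jitter_spec(base: LeafSpec, rng: np.random.Generator) -> LeafSpec:
    kw = dict(
        rotation=float(rng.uniform(0.0, 360.0)),
        elongation=float(base.elongation * rng.normal(1.0, 0.03)),
        scale=int(base.scale * rng.normal(1.0, 0.03)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    if base.n_lobes:
        kw["lobe_amplitude"] = float(
            np.clip(base.lobe_amplitude * rng.normal(1.0, 0.05), 0.05, 0.45)
        )
    if base.teeth_count:
        kw["teeth_amplitude"] = float(base.teeth_amplitude * rng.normal(1.0, 0.05))
        kw["teeth_count"] = int(base.teeth_count + rng.integers(-2, 3))
    if base.apex_type in ("acute", "acuminate"):
        kw["apex_flank_angle"] = float(base.apex_flank_angle + rng.uniform(-4, 4))
    return replace(base, **kw)


def generate_dataset(
    n_species: int,
    samples_per_species: int,
    seed: int = 0,
    train_fraction: float = 0.67,
    color: bool = True,
    scale: int = 470,
):
    """Deterministic labelled dataset: per-species base spec + small jitter.

    Returns a list of records ``{image, truth, species, split}``; every
    species appears in both splits (train first, per the split fraction).
    """
    if n_species < 2:
        raise InvalidSpecError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    records = []
    n_train = max(1, min(samples_per_species - 1, round(samples_per_species * train_fraction)))
    for s in range(n_species):
        kw = dict(_SPECIES_PALETTE[s % len(_SPECIES_PALETTE)])
        if s >= len(_SPECIES_PALETTE):  # cycled: nudge elongation to stay distinct
            kw["elongation"] = kw.get("elongation", 1.5) * (1.0 + 0.15 * (s // len(_SPECIES_PALETTE)))
        base = LeafSpec(color=color, scale=scale, **kw)
        label = f"species_{s:02d}"
        for i in range(samples_per_species):
            spec = _jitter_spec(base, rng)
            img, truth = generate_leaf(spec)
            truth.species_label = label
            records.append(
                dict(
                    image=img,
                    truth=truth,
                    species=label,
                    split="train" if i < n_train else "test",
                )
            )
    return records


def write_dataset(records, out_dir: str | Path) -> Path:
    """Write PNG images and a manifest CSV; returns the manifest path."""
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        name = f"leaf_{i:04d}.png"
        iio.imwrite(out / name, rec["image"])
        t: GroundTruth = rec["truth"]
        rows.append(
            dict(
                filename=name,
                species=rec["species"],
                split=rec["split"],
                n_lobes=t.spec.n_lobes,
                margin_class=t.margin_class,
                apex_type=t.apex_type or "",
                base_type=t.base_type or "",
                teeth_count=t.teeth,
            )
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
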