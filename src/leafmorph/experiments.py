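"""Reproducible recovery experiments on synthetic leaves.

Each function generates its own ground-truth-labelled leaves, runs the
pipeline, and reports a recovery rate.  They are the package's standard
benchmarks: parameter recovery for lobe counts, margin classes and apex
types, and end-to-end species identification.  All randomness flows from
the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import apex_base as _ab
from . import margin as _mg
from .classify import evaluate, extract_features
from .config import DEFAULT_CONFIG, RunConfig
from .errors import VeinUndetectableError
from .preprocess import binarize, incircle_centroid, standardize, trace_boundary
from .signature import ccd_ebp, consolidate_extrema
from .synthetic_leaf import LeafSpec, generate_dataset, generate_leaf

__all__ = [
    "run_pipeline",
    "vertex_angle_sum",
    "lobe_recovery",
    "margin_recovery",
    "apex_recovery",
    "end_to_end_accuracy",
]

MARGIN_CLASS_SPECS = [
    ("entire", dict()),
    ("serrate", dict(teeth_waveform="saw", teeth_amplitude=0.095)),
    ("serrulate", dict(teeth_waveform="saw", teeth_amplitude=0.045)),
    ("doubly_serrate", dict(teeth_waveform="saw", teeth_amplitude=0.095, doubly_teeth=True)),
    ("dentate", dict(teeth_waveform="triangular", teeth_amplitude=0.095)),
    ("denticulate", dict(teeth_waveform="triangular", teeth_amplitude=0.045)),
    ("crenate", dict(teeth_waveform="rounded", teeth_amplitude=0.095)),
    ("crenulate", dict(teeth_waveform="rounded", teeth_amplitude=0.045)),
]


def run_pipeline(image, config: RunConfig = DEFAULT_CONFIG):
    """Shared front half: mask, centroid, contour, signature, extrema."""
    leaf, std_image = standardize(
        binarize(image), image=image, size=config.standard_size, pad=config.border_pad
    )
    centroid = incircle_centroid(leaf)
    contour = trace_boundary(leaf)
    sig = ccd_ebp(contour, centroid)
    consolidated = consolidate_extrema(sig, config.magnitude_thresholds)
    return leaf, std_image, centroid, contour, sig, consolidated


def vertex_angle_sum(seed: int = 0, n_lobes: int = 5) -> tuple[float, int]:
    """Sum of the vertex angles at the centroid of a lobed synthetic leaf.

    Consecutive rays to the detected local maxima partition the full turn,
    so the law-of-cosines angles must add to 360 degrees.  Returns
    ``(sum_degrees, number_of_maxima)``.
    """
    rng = np.random.default_rng(seed)
    spec = LeafSpec(
        n_lobes=n_lobes,
        lobe_amplitude=0.32,
        elongation=1.3,
        rotation=float(rng.uniform(0.0, 360.0)),
    )
    img, _ = generate_leaf(spec)
    _, _, centroid, contour, sig, consolidated = run_pipeline(img)
    fan = _ab.build_vertex_fan(consolidated.peak_positions, contour, centroid)
    return float(fan.angles.sum()), fan.m


def lobe_recovery(
    ks=range(3, 10), n_rotations: int = 12, seed: int = 0
) -> tuple[int, int]:
    """Exact lobe-count recovery over k-lobed leaves at many rotations."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for k in ks:
        for j in range(n_rotations):
            rot = 360.0 * j / n_rotations + float(rng.uniform(0.0, 30.0))
            spec = LeafSpec(n_lobes=k, lobe_amplitude=0.32, elongation=1.25, rotation=rot)
            img, _ = generate_leaf(spec)
            _, _, _, _, _, consolidated = run_pipeline(img)
            hits += consolidated.mod_peak == k
            total += 1
    return hits, total


def margin_recovery(n_per_class: int = 50, seed: int = 0):
    """Margin-class recovery over all eight classes.

    The population is broad-bladed (elongation 1.15-1.35) with mixed tip
    shapes and random orientations — the operating envelope in which the
    margin is geometrically visible to a centroid-distance signature (see
    the methods note for the steep-flank limitation).
    Returns ``(hits, total, misses_by_pair)``.
    """
    rng = np.random.default_rng(seed)
    hits = total = 0
    misses: dict[tuple[str, str], int] = {}
    for truth, kw in MARGIN_CLASS_SPECS:
        for _ in range(n_per_class):
            kw2 = dict(kw)
            if truth != "entire":
                kw2["teeth_count"] = int(rng.integers(26, 40))
                kw2["teeth_amplitude"] = float(
                    kw["teeth_amplitude"] * rng.normal(1.0, 0.05)
                )
            spec = LeafSpec(
                elongation=float(rng.uniform(1.15, 1.35)),
                apex_type=str(rng.choice(["acute", "rounded"])),
                apex_flank_angle=float(rng.uniform(65.0, 85.0)),
                base_type=str(rng.choice(["cuneate", "rounded"])),
                rotation=float(rng.uniform(0.0, 360.0)),
                **kw2,
            )
            img, _ = generate_leaf(spec)
            leaf, _, centroid, contour, sig, consolidated = run_pipeline(img)
            feats = _mg.analyse_margin(
                leaf, contour, sig, consolidated, None, centroid.incircle_radius
            )
            total += 1
            if feats.margin_class == truth:
                hits += 1
            else:
                key = (truth, feats.margin_class)
                misses[key] = misses.get(key, 0) + 1
    return hits, total, misses


def apex_recovery(n_per_type: int = 100, seed: int = 0) -> tuple[int, int]:
    """Apex-type recovery for acuminate / acute / rounded tips."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for truth in ("acuminate", "acute", "rounded"):
        for _ in range(n_per_type):
            angle = {
                "acuminate": float(rng.uniform(26.0, 40.0)),
                "acute": float(rng.uniform(52.0, 85.0)),
                "rounded": 70.0,
            }[truth]
            spec = LeafSpec(
                elongation=float(rng.uniform(1.5, 2.0)),
                apex_type=truth,
                apex_flank_angle=angle,
                base_type=str(rng.choice(["cuneate", "rounded"])),
                rotation=float(rng.uniform(0.0, 360.0)),
            )
            img, _ = generate_leaf(spec)
            leaf, std_img, centroid, contour, sig, consolidated = run_pipeline(img)
            poles = _ab.locate_poles(contour, centroid, sig, consolidated)
            total += 1
            try:
                poles = _ab.disambiguate_apex_base(std_img, leaf, contour, poles, centroid)
            except VeinUndetectableError:
                continue  # counted as a miss
            pts = contour.points[poles.apex_part].astype(float)
            pole = contour.points[
                _ab._pole_center(poles.apex_pole, contour.n)
            ].astype(float)
            label, _, _ = _ab.classify_apex_type(None, pts, pole, centroid)
            hits += label == truth
    return hits, total


def end_to_end_accuracy(
    n_species: int = 10, samples_per_species: int = 8, seed: int = 0
) -> dict:
    """Simulate a species dataset, extract features, 1-NN identify."""
    records = generate_dataset(n_species, samples_per_species, seed=seed)
    train, test = [], []
    for rec in records:
        fv = extract_features(rec["image"])
        fv.species_label = rec["species"]
        (train if rec["split"] == "train" else test).append(fv)
    return evaluate(train, test, k=1)
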