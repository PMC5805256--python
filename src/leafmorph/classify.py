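"""Per-leaf feature vector assembly and species identification.

The feature vector carries the four phenetic feature groups the pipeline
extracts — lobes/sinuses counts, apex descriptor (type + angle + CCG),
base descriptor, and margin descriptor (class, ripples ratio, tooth count).
Identification is nearest-neighbour under a mixed distance: z-scored
numeric features (statistics from the training set), Euclidean distance on
the CCG vectors, and a 0/1 penalty per categorical mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .config import DEFAULT_CONFIG, RunConfig
from .errors import EvaluationError, VeinUndetectableError
from . import apex_base as _ab
from . import margin as _mg
from .preprocess import incircle_centroid, preprocess_image, trace_boundary
from .signature import ccd_ebp, consolidate_extrema, count_lobes_sinuses

__all__ = [
    "LeafFeatureVector",
    "extract_features",
    "knn_classify",
    "accuracy",
    "evaluate",
    "feature_frame",
]


@dataclass
class LeafFeatureVector:
    lobes: int
    sinuses: int
    teeth_count: int
    ripples_ratio: float
    apex_type: str
    base_type: str
    apex_angle: float
    base_angle: float
    ccg_apex: tuple[float, ...]
    ccg_base: tuple[float, ...]
    margin_class: str
    vein_resolved: bool = True  # False when the petiole-side heuristic decided
    species_label: str | None = None
    source_path: str | None = None

    def to_record(self) -> dict:
        d = asdict(self)
        for key in ("ccg_apex", "ccg_base"):
            vec = d.pop(key)
            for i, g in enumerate(vec):
                d[f"{key}_{i}"] = g
        return d


def _ccg_feature(region_pts, pole_pt, config: RunConfig) -> tuple[np.ndarray, ...]:
    """Fixed-length CCG gradient vector (one slot per interval)."""
    n_slots = int(round(90.0 / config.ccg_interval))
    try:
        vec = _ab.ccg(region_pts, pole_pt, config.ccg_interval, config.gradient_cap)
    except Exception:
        return np.zeros(n_slots)
    mids = vec.angles[:-1] + np.diff(vec.angles) / 2.0
    targets = np.arange(n_slots) * config.ccg_interval + config.ccg_interval / 2.0
    if len(mids) == 0:
        return np.zeros(n_slots)
    return np.interp(targets, mids, vec.gradients)


def extract_features(
    image: np.ndarray,
    config: RunConfig = DEFAULT_CONFIG,
    source_path: str | None = None,
) -> LeafFeatureVector:
    """Run the full pipeline on one image.

    Deterministic for a fixed image and configuration.  When the mid-vein
    cannot be measured (greyscale, uniform lamina) the apex is assigned to
    the sharper pole and ``vein_resolved`` is set False.
    """
    leaf, std_image = preprocess_image(image, config, source_path=source_path)
    centroid = incircle_centroid(leaf)
    contour = trace_boundary(leaf)
    sig = ccd_ebp(contour, centroid, mask=leaf)
    if config.normalise_signature:
        consolidated = consolidate_extrema(sig.normalised(), config.magnitude_thresholds)
    else:
        consolidated = consolidate_extrema(sig, config.magnitude_thresholds)
    lobes, sinuses, _ = count_lobes_sinuses(consolidated)

    poles = _ab.locate_poles(contour, centroid, sig, consolidated, config)
    vein_resolved = True
    try:
        poles = _ab.disambiguate_apex_base(
            std_image if std_image is not None else leaf.mask.astype(np.uint8) * 255,
            leaf, contour, poles, centroid,
        )
    except VeinUndetectableError:
        vein_resolved = False
        poles.apex_is_north = _sharper_is_north(contour, poles, centroid)

    n = contour.n
    apex_pts = contour.points[poles.apex_part].astype(float)
    base_pts = contour.points[poles.base_part].astype(float)
    apex_pole = contour.points[_ab._pole_center(poles.apex_pole, n)].astype(float)
    base_pole = contour.points[_ab._pole_center(poles.base_pole, n)].astype(float)

    ccg_apex = _ccg_feature(apex_pts, apex_pole, config)
    ccg_base = _ccg_feature(base_pts, base_pole, config)
    apex_type, apex_angle, _ = _ab.classify_apex_type(None, apex_pts, apex_pole, centroid)
    base_type, base_angle, _ = _ab.classify_base_type(None, base_pts, base_pole, centroid)

    feats = _mg.analyse_margin(
        leaf, contour, sig, consolidated, None, centroid.incircle_radius, config
    )
    valid_teeth = _mg.valid_teeth(feats.teeth, config)

    return LeafFeatureVector(
        lobes=int(lobes),
        sinuses=int(sinuses),
        teeth_count=len(valid_teeth),
        ripples_ratio=float(feats.ripples_ratio),
        apex_type=apex_type,
        base_type=base_type,
        apex_angle=float(apex_angle),
        base_angle=float(base_angle),
        ccg_apex=tuple(float(g) for g in ccg_apex),
        ccg_base=tuple(float(g) for g in ccg_base),
        margin_class=feats.margin_class,
        vein_resolved=vein_resolved,
        species_label=None,
        source_path=source_path,
    )


def _sharper_is_north(contour, poles, centroid) -> bool:
    """Vein-free fallback: the apex is usually the sharper pole."""
    def angle_of(part, pole_idx):
        pts = contour.points[part].astype(float)
        pole = contour.points[_ab._pole_center(pole_idx, contour.n)].astype(float)
        geom = _ab._flank_geometry(pts, pole, centroid)
        return geom[0] if geom else 180.0

    a_np = angle_of(poles.part_np, poles.np_indices)
    a_sp = angle_of(poles.part_sp, poles.sp_indices)
    return a_np <= a_sp


# ---------------------------------------------------------------------------
# nearest-neighbour identification

_NUMERIC = ("lobes", "sinuses", "teeth_count", "ripples_ratio", "apex_angle", "base_angle")
_CATEGORICAL = ("apex_type", "base_type", "margin_class")


def _numeric_matrix(records: list[LeafFeatureVector]) -> np.ndarray:
    rows = []
    for r in records:
        rows.append(
            [getattr(r, k) for k in _NUMERIC] + list(r.ccg_apex) + list(r.ccg_base)
        )
    return np.asarray(rows, dtype=float)


def knn_classify(
    train: list[LeafFeatureVector],
    query: LeafFeatureVector | list[LeafFeatureVector],
    k: int = 1,
) -> str | list[str]:
    """Label of the nearest training record(s) under the mixed distance.

    Numeric columns are z-scored with training statistics; categorical
    mismatches add one unit each.  Ties (equal distance, or tied vote for
    k > 1) resolve to the first-indexed record.
    """
    if not train:
        raise EvaluationError("no reference set")
    queries = [query] if isinstance(query, LeafFeatureVector) else list(query)
    X = _numeric_matrix(train)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    train_cats = [[getattr(r, c) for c in _CATEGORICAL] for r in train]
    labels = [r.species_label for r in train]

    out = []
    for q in queries:
        qn = (_numeric_matrix([q])[0] - mu) / sd
        d = np.sqrt(((Xz - qn) ** 2).sum(axis=1))
        qc = [getattr(q, c) for c in _CATEGORICAL]
        d = d + np.array(
            [sum(a != b for a, b in zip(cats, qc)) for cats in train_cats], dtype=float
        )
        kk = min(max(1, k), len(train))
        nearest = np.argsort(d, kind="stable")[:kk]
        votes: dict[str, int] = {}
        for i in nearest:
            votes[labels[i]] = votes.get(labels[i], 0) + 1
        best = max(votes.values())
        for i in nearest:  # first-indexed tie-break
            if votes[labels[i]] == best:
                out.append(labels[i])
                break
    return out[0] if isinstance(query, LeafFeatureVector) else out


def accuracy(predictions: list[str], truth: list[str]) -> float:
    """Fraction of queries whose predicted species matches the truth."""
    if len(predictions) != len(truth):
        raise EvaluationError("misaligned evaluation")
    if not truth:
        return 0.0
    return float(sum(p == t for p, t in zip(predictions, truth)) / len(truth))


def evaluate(
    train: list[LeafFeatureVector],
    test: list[LeafFeatureVector],
    k: int = 1,
) -> dict:
    """Accuracy + confusion matrix of the nearest-neighbour matcher."""
    train_species = {r.species_label for r in train}
    missing = {r.species_label for r in test} - train_species
    if missing:
        raise EvaluationError(f"label mismatch: test species not in train: {sorted(missing)}")
    preds = knn_classify(train, test, k=k)
    truth = [r.species_label for r in test]
    species = sorted(train_species)
    idx = {s: i for i, s in enumerate(species)}
    cm = np.zeros((len(species), len(species)), dtype=int)
    for t, p in zip(truth, preds):
        cm[idx[t], idx[p]] += 1
    return {
        "accuracy": accuracy(preds, truth),
        "labels": species,
        "confusion_matrix": cm.tolist(),
        "n_train": len(train),
        "n_test": len(test),
    }


def feature_frame(records: list[LeafFeatureVector]):
    """Feature table as a pandas DataFrame (CSV/JSON export)."""
    import pandas as pd

    return pd.DataFrame([r.to_record() for r in records])
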