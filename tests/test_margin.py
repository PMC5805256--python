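"""Margin teeth: detection, ripples ratio, tooth geometry, taxonomy."""

import numpy as np
import pytest

from leafmorph.config import RunConfig
from leafmorph.errors import DegenerateToothError, EmptySegmentationError
from leafmorph.margin import (
    MarginFeatures,
    ToothMeasurement,
    analyse_margin,
    classify_margin,
    detect_teeth,
    diminutive_test,
    measure_tooth,
    midrib_axis_from_mask,
    pair_teeth,
    ripples_ratio,
    smooth_silhouette,
    tooth_type,
)
from leafmorph.preprocess import (
    BinaryLeafImage,
    Contour,
    binarize,
    incircle_centroid,
    standardize,
    trace_boundary,
)
from leafmorph.signature import ccd_ebp, consolidate_extrema, find_extrema
from leafmorph.synthetic_leaf import LeafSpec, generate_leaf

from conftest import disc_mask

VERTICAL_AXIS = (np.array([0.0, 0.0]), np.array([0.0, 1.0]))


def margin_of(spec):
    img, _ = generate_leaf(spec)
    leaf, _ = standardize(binarize(img), image=img)
    c = incircle_centroid(leaf)
    ct = trace_boundary(leaf)
    sig = ccd_ebp(ct, c)
    ce = consolidate_extrema(sig)
    return analyse_margin(leaf, ct, sig, ce, None, c.incircle_radius)


class TestDetectTeeth:
    def test_smooth_ellipse_has_no_teeth(self):
        yy, xx = np.mgrid[:260, :260]
        m = ((xx - 130) / 115) ** 2 + ((yy - 130) / 85) ** 2 <= 1.0
        leaf = BinaryLeafImage(mask=m)
        c = incircle_centroid(leaf)
        sig = ccd_ebp(trace_boundary(leaf), c)
        peaks, _ = detect_teeth(sig, consolidate_extrema(sig))
        assert len(peaks) <= 2  # rasterisation quirks at most

    def test_lobed_toothed_leaf_counts(self):
        # shallow lobes: teeth must out-slope the lobe flanks to register
        # in a radial signature, so deep lobes would hide them
        spec = LeafSpec(n_lobes=5, lobe_amplitude=0.15, elongation=1.15,
                        teeth_count=32, teeth_waveform="rounded", teeth_amplitude=0.12)
        img, _ = generate_leaf(spec)
        leaf, _ = standardize(binarize(img))
        c = incircle_centroid(leaf)
        sig = ccd_ebp(trace_boundary(leaf), c)
        ce = consolidate_extrema(sig)
        assert ce.mod_peak == 5  # lobes still counted as lobes
        peaks, _ = detect_teeth(sig, ce)
        # teeth riding the lobe extrema are subtracted with them
        assert 24 <= len(peaks) <= 34
        dist = np.abs(peaks[:, None] - ce.peak_positions[None, :])
        dist = np.minimum(dist, sig.n - dist)
        assert dist.min() > 0.01 * sig.n  # lobes excluded from the teeth set

    def test_count_monotone_in_threshold(self, five_lobed_run):
        sig, ce = five_lobed_run["signature"], five_lobed_run["consolidated"]
        n1 = len(detect_teeth(sig, ce, small_threshold=1.0)[0])
        n2 = len(detect_teeth(sig, ce, small_threshold=2.0)[0])
        n4 = len(detect_teeth(sig, ce, small_threshold=4.0)[0])
        assert n1 >= n2 >= n4


class TestRipplesRatio:
    def test_solid_disc_is_smooth(self):
        leaf = disc_mask(100)
        assert ripples_ratio(leaf, 12.0) < 0.01

    def test_equals_xor_pixel_oracle(self):
        spec = LeafSpec(elongation=1.3, apex_type="rounded", base_type="rounded",
                        teeth_count=30, teeth_waveform="saw", teeth_amplitude=0.09)
        img, _ = generate_leaf(spec)
        leaf, _ = standardize(binarize(img))
        ratio, ripples, smoothed = ripples_ratio(leaf, 20.0, return_masks=True)
        direct = np.count_nonzero(leaf.mask ^ smoothed) / np.count_nonzero(leaf.mask)
        assert ratio == direct
        assert ratio > 0.01

    def test_sawtooth_margin_raises_ratio(self):
        yy, xx = np.mgrid[:300, :300]
        rr = np.hypot(xx - 150, yy - 150)
        ang = np.arctan2(yy - 150, xx - 150)
        saw = 8.0 * ((ang * 30 / (2 * np.pi)) % 1.0)
        toothed = BinaryLeafImage(mask=rr <= 100 + saw)
        assert ripples_ratio(toothed, 12.0) > 0.01

    def test_scale_covariance(self):
        spec = LeafSpec(elongation=1.3, apex_type="rounded", base_type="rounded",
                        teeth_count=30, teeth_waveform="rounded", teeth_amplitude=0.09)
        img1, _ = generate_leaf(spec)
        leaf1 = binarize(img1)
        r1 = ripples_ratio(leaf1, incircle_centroid(leaf1).incircle_radius / 8)
        img2, _ = generate_leaf(LeafSpec(**{**spec.__dict__, "scale": 2 * spec.scale}))
        leaf2 = binarize(img2)
        r2 = ripples_ratio(leaf2, incircle_centroid(leaf2).incircle_radius / 8)
        assert r2 == pytest.approx(r1, rel=0.2)

    def test_empty_mask_rejected(self):
        with pytest.raises(EmptySegmentationError):
            ripples_ratio(np.zeros((10, 10), dtype=bool), 2.0)


def tooth_contour(apex_xy, left_xy, right_xy, arc=None):
    """Synthetic open tooth contour: left valley -> peak -> right valley."""
    if arc is None:
        pts = np.array([left_xy, apex_xy, right_xy])
        dense = []
        for a, b in zip(pts[:-1], pts[1:]):
            t = np.linspace(0, 1, 60)[:-1, None]
            dense.append(a + t * (b - a))
        dense.append(np.array([right_xy], dtype=float))
        return np.round(np.concatenate(dense)).astype(int)
    return arc


class TestMeasureTooth:
    def _measure(self, pts, peak, left, right):
        ct = Contour(points=pts)
        return measure_tooth(ct, peak, left, right, (np.array([0.0, 0.0]), np.array([0.0, 1.0])))

    def test_isoceles_tooth_equal_flanks(self):
        pts = tooth_contour((100, 60), (80, 100), (120, 100))
        t = self._measure(pts, peak=59, left=0, right=len(pts) - 1)
        assert t.A == pytest.approx(t.B, rel=0.03)
        assert t.L_teeth == pytest.approx(40.0, abs=1.5)
        assert t.L_teeth2midrib == pytest.approx(100.0, abs=1.0)

    def test_leaning_saw_tooth_unequal_flanks(self):
        pts = tooth_contour((112, 60), (80, 100), (120, 100))
        t = self._measure(pts, peak=59, left=0, right=len(pts) - 1)
        assert t.A > t.B

    def test_semicircular_tooth_triangularity_is_half_pi(self):
        r = 40.0
        a = np.linspace(np.pi, 0.0, 400)
        arc = np.column_stack([100 + r * np.cos(a), 100 - r * np.sin(a)])
        pts = np.round(arc).astype(int)
        keep = np.ones(len(pts), bool)
        keep[1:] = (np.diff(pts, axis=0) != 0).any(axis=1)
        pts = pts[keep]
        t = self._measure(pts, peak=len(pts) // 2, left=0, right=len(pts) - 1)
        assert t.triangularity == pytest.approx(np.pi / 2, rel=0.10)

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(50), np.full(50, 10)])
        with pytest.raises(DegenerateToothError):
            self._measure(pts, peak=25, left=0, right=49)


class TestDiminutive:
    def _tooth(self, height, midrib):
        return ToothMeasurement(0, 0, 0, A=1, B=1, tooth_area=1, triangle_area=1,
                                L_teeth=height, L_teeth2midrib=midrib)

    def test_small_ratio_is_diminutive(self):
        ratio, dim = diminutive_test(self._tooth(1.0, 20.0))
        assert ratio == pytest.approx(0.05)
        assert dim

    def test_mid_ratio_is_regular(self):
        ratio, dim = diminutive_test(self._tooth(1.0, 10.0))
        assert ratio == pytest.approx(0.1)
        assert not dim

    def test_large_ratio_is_lobe_scale(self):
        ratio, dim = diminutive_test(self._tooth(2.0, 10.0))
        assert ratio > 1.0 / 8.0  # excluded from teeth by callers


class TestToothType:
    def _tooth(self, A, B, tooth_area=1.0, triangle_area=1.0):
        return ToothMeasurement(0, 0, 0, A=A, B=B, tooth_area=tooth_area,
                                triangle_area=triangle_area, L_teeth=5, L_teeth2midrib=50)

    def test_unequal_flanks_type1(self):
        assert tooth_type(self._tooth(1.8, 1.0)) == "type1"

    def test_equal_flanks_triangular_type2(self):
        assert tooth_type(self._tooth(1.0, 1.0, tooth_area=0.97)) == "type2"

    def test_equal_flanks_rounded_type3(self):
        assert tooth_type(self._tooth(1.0, 1.0, tooth_area=1.5)) == "type3"


class TestClassifyMargin:
    @pytest.mark.parametrize(
        "truth,kw",
        [
            ("entire", dict()),
            ("serrate", dict(teeth_count=34, teeth_waveform="saw", teeth_amplitude=0.095)),
            ("serrulate", dict(teeth_count=38, teeth_waveform="saw", teeth_amplitude=0.045)),
            ("doubly_serrate", dict(teeth_count=28, teeth_waveform="saw",
                                    teeth_amplitude=0.095, doubly_teeth=True)),
            ("dentate", dict(teeth_count=32, teeth_waveform="triangular", teeth_amplitude=0.095)),
            ("denticulate", dict(teeth_count=36, teeth_waveform="triangular", teeth_amplitude=0.045)),
            ("crenate", dict(teeth_count=30, teeth_waveform="rounded", teeth_amplitude=0.095)),
            ("crenulate", dict(teeth_count=34, teeth_waveform="rounded", teeth_amplitude=0.045)),
        ],
    )
    def test_all_eight_classes_recovered(self, truth, kw):
        spec = LeafSpec(elongation=1.3, apex_type="acute", apex_flank_angle=75.0,
                        base_type="rounded", rotation=67.0, **kw)
        feats = margin_of(spec)
        assert feats.margin_class == truth

    def test_reported_teeth_within_lobe_bound(self):
        feats = margin_of(
            LeafSpec(elongation=1.25, apex_type="rounded", base_type="rounded",
                     teeth_count=30, teeth_waveform="saw", teeth_amplitude=0.095)
        )
        from leafmorph.margin import valid_teeth

        for t in valid_teeth(feats.teeth):
            assert 0.0 < t.ratio_dt <= 1.0 / 8.0

    def test_rotation_invariance_of_class(self):
        labels = set()
        for rot in (0.0, 95.0, 211.0):
            labels.add(
                margin_of(
                    LeafSpec(elongation=1.3, apex_type="acute", base_type="rounded",
                             teeth_count=32, teeth_waveform="triangular",
                             teeth_amplitude=0.095, rotation=rot)
                ).margin_class
            )
        assert labels == {"dentate"}


class TestMidribAxis:
    def test_principal_axis_of_upright_leaf_is_vertical(self):
        img, _ = generate_leaf(LeafSpec(elongation=1.8, apex_type="acute", rotation=0.0))
        leaf, _ = standardize(binarize(img))
        point, direction = midrib_axis_from_mask(leaf)
        assert abs(direction[1]) > 0.99  # vertical within ~8 degrees
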