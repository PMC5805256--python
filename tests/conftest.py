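"""Shared fixtures: analytic shapes and standard synthetic leaves."""

import numpy as np
import pytest

from leafmorph.preprocess import (
    BinaryLeafImage,
    binarize,
    incircle_centroid,
    standardize,
    trace_boundary,
)
from leafmorph.signature import ccd_ebp, consolidate_extrema
from leafmorph.synthetic_leaf import LeafSpec, generate_leaf


def disc_mask(radius: int, size: int | None = None) -> BinaryLeafImage:
    size = size or (2 * radius + 21)
    yy, xx = np.mgrid[:size, :size]
    c = size // 2
    return BinaryLeafImage(mask=(xx - c) ** 2 + (yy - c) ** 2 <= radius**2)


def rect_mask(w: int, h: int, pad: int = 10) -> BinaryLeafImage:
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    m[pad : pad + h, pad : pad + w] = True
    return BinaryLeafImage(mask=m)


@pytest.fixture(scope="session")
def disc40() -> BinaryLeafImage:
    return disc_mask(40)


@pytest.fixture(scope="session")
def five_lobed_run():
    """Standardised pipeline products for a rotated five-lobed leaf."""
    img, gt = generate_leaf(
        LeafSpec(n_lobes=5, lobe_amplitude=0.32, elongation=1.3, rotation=20.0)
    )
    leaf, std_img = standardize(binarize(img), image=img)
    centroid = incircle_centroid(leaf)
    contour = trace_boundary(leaf)
    sig = ccd_ebp(contour, centroid)
    consolidated = consolidate_extrema(sig)
    return {
        "image": img,
        "std_image": std_img,
        "truth": gt,
        "mask": leaf,
        "centroid": centroid,
        "contour": contour,
        "signature": sig,
        "consolidated": consolidated,
    }


@pytest.fixture(scope="session")
def plain_leaf_run():
    """Pipeline products for an unlobed acute/cuneate leaf with a vein."""
    img, gt = generate_leaf(
        LeafSpec(elongation=1.6, apex_type="acute", apex_flank_angle=70.0,
                 base_type="cuneate", rotation=30.0)
    )
    leaf, std_img = standardize(binarize(img), image=img)
    centroid = incircle_centroid(leaf)
    contour = trace_boundary(leaf)
    sig = ccd_ebp(contour, centroid)
    consolidated = consolidate_extrema(sig)
    return {
        "image": img,
        "std_image": std_img,
        "truth": gt,
        "mask": leaf,
        "centroid": centroid,
        "contour": contour,
        "signature": sig,
        "consolidated": consolidated,
    }
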