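import warnings

import numpy as np
import pytest

from rdmorph.morphometry import (
    BoundaryCurve,
    align_profile_arc,
    thickness_profile,
)
from rdmorph.phantom import PhantomSpec, attached_only_spec, generate_phantom_tile

# calliper stations near band ends are noisy by construction; the profiling
# code warns when it drops them, which is expected on every phantom
warnings.filterwarnings("ignore", message=".*dropped.*station")


@pytest.fixture(scope="session")
def full_phantom():
    """One default detached phantom: (spec, image, labels, ground truth)."""
    spec = PhantomSpec()
    image, labels, gt = generate_phantom_tile(spec, 1)
    return spec, image, labels, gt


@pytest.fixture(scope="session")
def full_phantom_curves(full_phantom):
    _, _, _, gt = full_phantom
    rpe = BoundaryCurve(gt.rpe_curve, 1.0)
    onl_outer = BoundaryCurve(gt.onl_outer_curve, 1.0)
    return rpe, onl_outer


@pytest.fixture(scope="session")
def full_phantom_profiles(full_phantom, full_phantom_curves):
    """ONL and INL calliper profiles aligned to the tile's ONL arc."""
    _, _, labels, _ = full_phantom
    _, onl_outer = full_phantom_curves
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        onl = align_profile_arc(
            thickness_profile(labels == 2, 1.0, layer="onl"), onl_outer
        )
        inl = align_profile_arc(
            thickness_profile(labels == 3, 1.0, layer="inl"), onl_outer
        )
    return onl, inl


@pytest.fixture(scope="session")
def small_phantom():
    """Compact fully-attached phantom for counting and CLI tests."""
    spec = attached_only_spec()
    image, labels, gt = generate_phantom_tile(spec, 0)
    return spec, image, labels, gt


def rect_mask(height_px: int = 94, width_px: int = 400, pad: int = 40):
    m = np.zeros((height_px + 2 * pad, width_px), dtype=bool)
    m[pad : pad + height_px, :] = True
    return m


def annulus_mask(r_in: int = 100, r_out: int = 150, size: int = 400):
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - size / 2, xx - size / 2)
    # half-open radii so the discrete band is exactly r_out - r_in pixels wide
    return (r >= r_in) & (r < r_out)
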