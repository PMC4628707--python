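import numpy as np
import pytest
from hypothesis import settings
from scipy import ndimage

import vtseg as v

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def disk_image():
    """128^2 cross-section image: dark disk of radius 30 px in bright tissue,
    blurred border plus seeded noise — the canonical single-slice test case."""
    n = 128
    r = 30.0
    u, vv = np.mgrid[0:n, 0:n]
    d = np.hypot(u - 64, vv - 64)
    img = np.where(d < r, 20.0, 120.0)
    img = ndimage.gaussian_filter(img, 1.5)
    img = img + np.random.default_rng(0).normal(0, 5, img.shape)
    img = ndimage.gaussian_filter(img, 0.8)
    return img, (64.0, 64.0), r


@pytest.fixture(scope="session")
def straight_phantom():
    """Small noiseless straight-tube stack with analytic ground truth."""
    spec = v.PhantomSpec(centerline_kind="straight", shape=(48, 48, 48),
                         spacing=(1.0, 1.0, 1.0), length_mm=30.0, radius_mm=6.0,
                         noise_sd=0.0, blur_sd_mm=0.0)
    return spec, *v.generate(spec, 0)


@pytest.fixture(scope="session")
def arc_phantom_small():
    """Curved-tube stack at reduced grid size for fast end-to-end tests."""
    spec = v.PhantomSpec(centerline_kind="arc", shape=(72, 64, 72),
                         spacing=(1.0, 1.0, 1.0), radius_mm=6.0,
                         curvature_radius_mm=25.0, arc_angle_deg=80.0,
                         noise_sd=2.5, blur_sd_mm=0.5, end_padding_mm=5.0,
                         truth_step_mm=1.0)
    return spec, *v.generate(spec, 0)
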