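import numpy as np
import pytest
from scipy.stats import qmc

from epidqa import BeamGeometry, EpidImage, FieldModel, RoiSpec


@pytest.fixture(scope="session")
def geom() -> BeamGeometry:
    return BeamGeometry()


@pytest.fixture
def quiet_fm() -> FieldModel:
    """Noise-free field model: analyses must recover injected ground truth."""
    return FieldModel(noise_sd=0.0)


def mc_roi_mean(img: EpidImage, roi: RoiSpec, sad: float = 1000.0,
                n_pow2: int = 16, seed: int = 0) -> float:
    """Independent area-integration oracle for roi_mean.

    Integrates the piecewise-constant pixel function over the projected ROI
    with scrambled-Sobol quasi-Monte-Carlo points (rejection sampling for
    circles), entirely bypassing the fractional-pixel weighting under test.
    """
    mag = img.sid / sad
    pitch = img.pixel_pitch
    r0, c0 = img.origin
    pts = qmc.Sobol(d=2, scramble=True, rng=np.random.default_rng(seed)
                    ).random_base2(n_pow2)
    cx, cy = roi.center[0] * mag, roi.center[1] * mag
    if roi.shape == "circle":
        r = roi.radius * mag
        x = cx + (2 * pts[:, 0] - 1) * r
        y = cy + (2 * pts[:, 1] - 1) * r
        keep = (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        x, y = x[keep], y[keep]
    else:
        x = cx + (pts[:, 0] - 0.5) * roi.width * mag
        y = cy + (pts[:, 1] - 0.5) * roi.height * mag
    cols = np.rint(x / pitch + c0).astype(int)
    rows = np.rint(r0 - y / pitch).astype(int)
    return float(img.pixels[rows, cols].mean())
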