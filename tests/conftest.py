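import warnings

import numpy as np
import pytest

from fibergrade.synthetic import (
    SyntheticSpec,
    sample_fiber_population,
    render_shg_image,
)

# statsmodels and skimage emit benign convergence/precision warnings on
# degenerate synthetic inputs; keep test output readable
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def single_fiber_image():
    """One horizontal 80-px fiber through the image center, noise-free."""
    spec = SyntheticSpec(
        image_size_px=(128, 128),
        fiber_count_mean=1,
        background_level=0.0,
        poisson_scale=0.0,
        gaussian_read_sd=0.0,
        seed=0,
    )
    from fibergrade.synthetic import Fiber, FiberGroundTruth

    pts = np.array([[24.0, 64.0], [104.0, 64.0]])
    fiber = Fiber(points=pts, orientation_deg=0.0, length_um=80 * spec.shg_pixel_size_um)
    truth = FiberGroundTruth((fiber,), spec)
    return truth, render_shg_image(truth, noise=False)


@pytest.fixture(scope="session")
def sparse_roi(rng):
    """A well-separated ~25-fiber field with modest noise, plus its truth."""
    spec = SyntheticSpec(
        image_size_px=(400, 400),
        fiber_count_mean=35,
        min_separation_px=8,
        max_fiber_count=50,
        seed=103,
    )
    truth = sample_fiber_population(spec)
    return truth, render_shg_image(truth)
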