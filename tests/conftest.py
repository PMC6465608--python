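import numpy as np
import pytest

from tls2d.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def smooth_image():
    """A brain-like smooth template: flat background, structure inside."""
    from scipy import ndimage

    from tls2d.phantom import _anatomy_template

    rng = np.random.default_rng(5)
    return ndimage.gaussian_filter(_anatomy_template(48, 48, rng), 1.2)


@pytest.fixture(scope="session")
def standard_phantom():
    """The reference study stack: 20 images, 64x64, rank-3 background,
    40% tumor images, +-2 px / +-2 deg jitter, seed 7."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, fast stack for solver unit tests."""
    return generate_phantom(
        PhantomConfig(
            n_images=8, width=32, height=32, background_rank=2,
            tumor_fraction=0.25, tumor_radius_range=(4.0, 6.0),
            max_translation=1.0, max_rotation=1.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def pipeline_run(standard_phantom):
    """One full two-pass recovery/segmentation of the reference stack,
    shared by every test that inspects its outputs."""
    from tls2d.solver import recover_and_segment

    return recover_and_segment(standard_phantom.observed_images)
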