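import numpy as np
import pytest

from bhctvi import ImageVolume, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def supine_pair():
    """Default-condition supine phantom at a test-friendly size (120 mm extent)."""
    return generate_phantom(
        PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(2.5, 2.5, 2.5), seed=7)
    )


@pytest.fixture(scope="session")
def quiet_pair():
    """Noise-free, texture-free supine phantom (clean geometry checks)."""
    return generate_phantom(
        PhantomSpec(
            grid_shape=(48, 48, 48), spacing_mm=(2.5, 2.5, 2.5),
            noise_sd_hu=0.0, texture_sd_hu=0.0, seed=7,
        )
    )


@pytest.fixture()
def small_volume():
    rng = np.random.default_rng(0)
    return ImageVolume(
        data=rng.normal(size=(6, 5, 4)),
        spacing_mm=(2.0, 2.0, 2.0),
        origin_mm=(1.0, 1.0, 1.0),
    )
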