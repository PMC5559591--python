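import numpy as np
import pytest

from necrofract.synthetic import PhantomSpec, make_tumor_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A clean two-band phantom (no intensity noise) plus its truth mask."""
    spec = PhantomSpec(canvas_size=96, boundary_roughness=0.0, n_holes=0, seed=3)
    image, tumor, truth = make_tumor_phantom(spec)
    clean = np.full(image.shape, 0.05)
    clean[tumor] = 0.8
    clean[truth] = 0.2
    return clean, tumor, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = PhantomSpec(canvas_size=96, boundary_roughness=2.0, n_holes=4, seed=11)
    return make_tumor_phantom(spec)
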