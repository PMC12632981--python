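import numpy as np
import pytest

from hippodti.laplace import LabeledVolume, compute_all_axes
from hippodti.synthetic import PhantomSpec, make_dwi, make_phantom


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def solved_fields(phantom):
    """Numerical Laplace fields on the default phantom (solved once)."""
    return compute_all_axes(phantom.volume, tol=1e-7)


@pytest.fixture(scope="session")
def ap_dwi(phantom):
    """Noiseless DWI with V1 aligned to the anterior-posterior axis."""
    return make_dwi(phantom, weights=(1.0, 0.0, 0.0))


@pytest.fixture()
def slab_volume():
    """10x3x3 slab: source plane x=0, sink plane x=9, AP codes."""
    labels = np.ones((10, 3, 3), dtype=np.int16)
    labels[0] = 2
    labels[9] = 3
    return LabeledVolume(labels=labels, spacing=np.ones(3), affine=np.eye(4))
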