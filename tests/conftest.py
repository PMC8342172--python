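import numpy as np
import pytest

from symseg import evolution, phantom, symmetry


@pytest.fixture(scope="session")
def disk():
    """High-contrast disk phantom (radius 40 on 128², centre 63.5, 63.5)."""
    return phantom.generate_disk()


@pytest.fixture(scope="session")
def clean_phantom():
    """One clean tongue-like phantom with ground truth."""
    return phantom.phantom_suite("clean", 1, 7)[0]


@pytest.fixture()
def vertical_reflection():
    """Reflection across the vertical axis x = 31.5 of a 64² grid."""
    axis = symmetry.axis_from_points((31.5, 0.0), (31.5, 63.0), (64, 64))
    return symmetry.reflection_matrix(axis)


@pytest.fixture()
def notched_circle(vertical_reflection):
    """Circular SDF on 64² with a half-plane notch on one side.

    The notch clips the inside region for x > 40, breaking mirror symmetry
    about x = 31.5; returns (symmetric φ, notched φ, reflection, uniform g).
    """
    phi = evolution.init_circular_sdf((64, 64), (31.5, 31.5), 18.0)
    yy, xx = np.mgrid[0:64, 0:64]
    notch = (xx > 40) & (np.abs(yy - 31.5) < 6)
    phi_notched = np.where(notch, np.maximum(phi, 2.0), phi)
    g = np.ones((64, 64))
    return phi, phi_notched, vertical_reflection, g
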