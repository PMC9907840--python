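import numpy as np
import pytest

from vesswall import VesselSpec, build_geometry, generate_vessel


def annulus_mask(size=256, r_in=40.0, r_out=100.0, center=None):
    c = (size - 1) / 2 if center is None else center
    rows, cols = np.mgrid[0:size, 0:size]
    rho = np.hypot(rows - c, cols - c)
    return (rho >= r_in) & (rho <= r_out)


@pytest.fixture(scope="session")
def annulus():
    """Perfect annulus r_in=40, r_out=100 centered in a 256x256 raster."""
    return annulus_mask()


@pytest.fixture(scope="session")
def annulus_geometry(annulus):
    return build_geometry(annulus)


@pytest.fixture(scope="session")
def media_vessel():
    """Noise-free synthetic vessel with DAB confined to the media third."""
    return generate_vessel(VesselSpec(stain_fill_fraction=(0.0, 0.3, 0.0), noise_sd=0.0))


@pytest.fixture(scope="session")
def uniform_vessel():
    """Noise-free vessel with every wall pixel stained."""
    return generate_vessel(VesselSpec(stain_fill_fraction=(1.0, 1.0, 1.0), noise_sd=0.0))


def random_density(rng, n=100):
    v = rng.random(n)
    return v / v.sum()
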