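import numpy as np
import pytest
import scipy.sparse as sp

from msinmf import datacube, phantom

#: Axis used for phantom-scale cubes (~5e4 channels over m/z 400-1000).
PHANTOM_AXIS_KW = dict(mz_lo=400.0, mz_hi=1000.0, ref_mz=850.0,
                       ref_bin_width=0.015, ref_sigma=0.001)

REGION_NAMES = {1: "ovary", 2: "uterus", 3: "tumor", 4: "cyst"}


@pytest.fixture(scope="session")
def phantom_axis():
    return datacube.build_mz_axis(**PHANTOM_AXIS_KW)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default 4-region phantom with all noise sources on."""
    spec = phantom.default_phantom_spec(seed=1)
    labels, profiles = phantom.make_phantom(spec)
    stream, track = phantom.simulate_acquisition(labels, profiles, spec)
    return spec, labels, profiles, stream, track


@pytest.fixture(scope="session")
def noisy_cube(noisy_phantom, phantom_axis):
    _, labels, _, stream, track = noisy_phantom
    cube = datacube.build_cube(stream, track, phantom_axis)
    return cube, labels


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: zero gain/jitter/background."""
    spec = phantom.default_phantom_spec(
        seed=2, pixel_gain_sigma=0.0, mz_jitter_sigma_at_ref=0.0,
        background_peak_rate=0.0)
    labels, profiles = phantom.make_phantom(spec)
    stream, track = phantom.simulate_acquisition(labels, profiles, spec)
    return spec, labels, profiles, stream, track


@pytest.fixture(scope="session")
def clean_cube(clean_phantom, phantom_axis):
    _, labels, _, stream, track = clean_phantom
    cube = datacube.build_cube(stream, track, phantom_axis)
    return cube, labels


@pytest.fixture()
def random_cube():
    """Small dense-backed random cube (5 x 5 x 100) for brute-force oracles."""
    rng = np.random.default_rng(123)
    axis = datacube.build_mz_axis(400.0, 1000.0, 850.0, 7.8, 3.9)
    axis = datacube.MzAxis(axis.mz_lo, axis.mz_hi, axis.ref_mz, axis.ref_bin_width,
                           axis.ref_sigma, axis.centers[:100])
    dense = rng.uniform(0.0, 10.0, size=(25, 100))
    dense[rng.uniform(size=dense.shape) < 0.5] = 0.0
    cube = datacube.DataCube(values=sp.csr_matrix(dense), rows=5, cols=5, axis=axis,
                             pixel_pitch_x_um=200.0, pixel_pitch_y_um=200.0)
    return cube, dense
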