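import warnings

import numpy as np
import pytest

from grinsim import activity as act
from grinsim import optics as opt
from grinsim import render as rnd
from grinsim import tissue as tis


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_optics():
    """Minimal distortion-free optics: flat focal surface at 25 µm depth,
    constant 4 µm lateral / 10 µm axial PSF, unit intensity."""
    return opt.OpticsModel(
        probe_type="corrected-6.4",
        focal_surface=opt.FocalSurfaceModel(
            "polynomial", poly_coeffs=(0.0,), center_depth=25.0
        ),
        psf=opt.PSFSizeModel(axial=(0.0, 0.0, 10.0), lateral=(0.0, 0.0, 4.0)),
        magnification=opt.MagnificationModel(),
        intensity=opt.RadialIntensityProfile(),
        fov_um=50.0,
        edge_radius_um=40.0,
    )


@pytest.fixture
def single_neuron_tissue():
    """One 10 µm neuron (5 µm nucleus) centred in a 50 µm cube."""
    n = tis.NeuronGeom(0, np.array([25.0, 25.0, 25.0]), 10.0, 5.0)
    tv = tis.TissueVolume(
        dims=np.array([50.0, 50.0, 50.0]),
        voxel_size=np.array([0.8, 0.8, 1.0]),
        neurons=[n],
        density_target=0.0,
        realized_density=0.0,
        seed=0,
    )
    return tv


@pytest.fixture
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
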