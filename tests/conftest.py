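import numpy as np
import pytest

from stimmap.des import ElectrodeConfig, solve_des
from stimmap.phantom import GM, assign_conductivity, build_spherical_phantom, extract_surface
from stimmap.tms import CoilModel, solve_secondary


@pytest.fixture(scope="session")
def phantom2mm():
    """The stock 5-layer head phantom at 2 mm with sigma field and GM surface."""
    vol = build_spherical_phantom(spacing=2.0)
    sigma = assign_conductivity(vol)
    patch = extract_surface(vol, GM)
    return vol, sigma, patch


@pytest.fixture(scope="session")
def phantom_fields(phantom2mm):
    """Co-located nTMS and DES fields over the +z pole of the phantom.

    The figure-8 coil sits 10 mm above the scalp, centered over the DES
    electrode target on the GM surface directly beneath the junction.
    """
    vol, sigma, patch = phantom2mm
    target = np.array([0.0, 0.0, 78.0])
    coil = CoilModel.figure8(center=(0, 0, 102.0), normal=(0, 0, -1), junction_axis=(1, 0, 0))
    e_ntms = solve_secondary(sigma, vol.affine, coil)
    electrode = ElectrodeConfig(anode_mm=tuple(target), mode="bipolar", bipolar_axis=(0, 1, 0))
    e_des = solve_des(sigma, vol.affine, electrode)
    return e_ntms, e_des, target


@pytest.fixture(scope="session")
def coarse_report():
    """One full pipeline run on a coarse (3 mm) grid shared across tests."""
    from stimmap.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(seed=7, spacing=3.0))


@pytest.fixture(scope="session")
def small_sphere():
    """Homogeneous 40 mm conductor ball at 2 mm for fast solver properties."""
    from tests.oracles import sphere_sigma

    sigma, affine, r = sphere_sigma(40.0, 2.0)
    return sigma, affine, r
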