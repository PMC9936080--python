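"""DES electrode solve: point-source physics, conservation, symmetry properties."""

import numpy as np
import pytest

from stimmap.des import ElectrodeConfig, current_density, solve_des
from stimmap.errors import GeometryError
from stimmap.volume_conductor import GridSystem
from tests.oracles import grounded_sphere_point_phi, sphere_sigma


@pytest.fixture(scope="module")
def central_monopolar():
    """1 mm ball at the center of a grounded homogeneous 40 mm ball, 2 mA."""
    sigma, affine, r = sphere_sigma(40.0, 2.0)
    cfg = ElectrodeConfig(
        anode_mm=(0, 0, 0), mode="monopolar", current_ma=2.0, return_region="boundary"
    )
    return solve_des(sigma, affine, cfg), sigma, affine, r


class TestMonopolar:
    def test_shell_averaged_potential_matches_point_source(self, central_monopolar):
        sol, sigma, _, r = central_monopolar
        act = sigma > 0
        rr, pv = r[act], sol.phi[act]
        for rad in (5.0, 8.0, 12.0, 16.0, 20.0):
            shell = np.abs(rr - rad) < 1.0
            exact = grounded_sphere_point_phi(rad, 2.0e-3, 0.2765, 40.0)
            assert pv[shell].mean() == pytest.approx(exact, rel=0.05)

    def test_current_density_matches_inverse_square(self, central_monopolar):
        sol, sigma, _, r = central_monopolar
        j = np.linalg.norm(current_density(sol, sigma), axis=-1)
        shell = (sigma > 0) & (np.abs(r - 10.0) < 1.0)
        exact = 2.0e-3 / (4 * np.pi * (10e-3) ** 2)
        assert j[shell].mean() == pytest.approx(exact, rel=0.05)

    def test_net_injected_current_matches_configuration(self, central_monopolar):
        sol, sigma, _, r = central_monopolar
        gs = GridSystem(sigma, (2.0, 2.0, 2.0))
        box = r <= 12.0
        i_net = gs.net_current(sol.phi[gs.active], box)
        assert i_net == pytest.approx(2.0e-3, rel=0.01)

    def test_current_scales_linearly(self, central_monopolar):
        sol, sigma, affine, r = central_monopolar
        cfg = ElectrodeConfig(
            anode_mm=(0, 0, 0), mode="monopolar", current_ma=4.0, return_region="boundary"
        )
        sol2 = solve_des(sigma, affine, cfg)
        act = sigma > 0
        assert np.allclose(sol2.e_field[act], 2 * sol.e_field[act], rtol=1e-6, atol=1e-9)

    def test_maximum_principle(self, central_monopolar):
        sol, sigma, _, _ = central_monopolar
        act = sigma > 0
        anode_value = np.nanmax(sol.phi)
        # extrema sit on the electrode (max) and the grounded boundary (min = 0)
        assert sol.phi[act].max() == pytest.approx(anode_value)
        assert sol.phi[act].min() >= -1e-12


class TestBipolar:
    def test_midplane_antisymmetry(self):
        sigma, affine, r = sphere_sigma(30.0, 2.0)
        # electrodes mirror-symmetric about the x-y voxel plane through z=0
        cfg = ElectrodeConfig(anode_mm=(0, 0, 6), cathode_mm=(0, 0, -6), mode="bipolar")
        sol = solve_des(sigma, affine, cfg)
        phi = np.nan_to_num(sol.phi)
        flipped = phi[:, :, ::-1]
        scale = np.abs(phi).max()
        assert np.abs(phi + flipped).max() / scale < 1e-6

    def test_swapping_electrodes_negates_potential(self):
        sigma, affine, _ = sphere_sigma(30.0, 2.0)
        a = solve_des(sigma, affine, ElectrodeConfig(anode_mm=(0, 2, 8), cathode_mm=(0, -4, 8)))
        b = solve_des(sigma, affine, ElectrodeConfig(anode_mm=(0, -4, 8), cathode_mm=(0, 2, 8)))
        pa, pb = np.nan_to_num(a.phi), np.nan_to_num(b.phi)
        assert np.abs(pa + pb).max() / np.abs(pa).max() < 1e-6

    def test_overlapping_electrodes_rejected(self):
        # sub-voxel balls that inflate onto the same grid voxel must be refused
        sigma, affine, _ = sphere_sigma(30.0, 2.0)
        cfg = ElectrodeConfig(
            anode_mm=(0, 0, 8), cathode_mm=(0, 0.9, 8), ball_radius=0.4, mode="bipolar"
        )
        with pytest.raises(GeometryError):
            solve_des(sigma, affine, cfg)

    def test_sub_ball_separation_rejected_at_construction(self):
        with pytest.raises(GeometryError):
            ElectrodeConfig(anode_mm=(0, 0, 8), cathode_mm=(0, 1.5, 8), ball_radius=1.0)


class TestConfigValidation:
    def test_current_outside_clinical_range_rejected(self):
        with pytest.raises(GeometryError):
            ElectrodeConfig(anode_mm=(0, 0, 0), current_ma=7.5)
        with pytest.raises(GeometryError):
            ElectrodeConfig(anode_mm=(0, 0, 0), current_ma=0.0)

    def test_default_bipolar_separation_is_4_4mm(self):
        cfg = ElectrodeConfig(anode_mm=(0, 0, 0))
        sep = np.linalg.norm(np.asarray(cfg.cathode_mm) - np.asarray(cfg.anode_mm))
        assert sep == pytest.approx(4.4)

    def test_electrode_outside_domain_rejected(self):
        sigma, affine, _ = sphere_sigma(30.0, 2.0)
        cfg = ElectrodeConfig(anode_mm=(200, 0, 0), mode="monopolar", return_region="boundary")
        with pytest.raises(GeometryError):
            solve_des(sigma, affine, cfg)

    def test_unknown_mode_rejected(self):
        with pytest.raises(GeometryError):
            ElectrodeConfig(anode_mm=(0, 0, 0), mode="tripolar")


class TestCurrentDensity:
    def test_zero_sigma_background_carries_no_current(self, central_monopolar):
        sol, sigma, _, _ = central_monopolar
        j = current_density(sol, sigma)
        assert np.all(j[sigma == 0] == 0)

    def test_grid_mismatch_rejected(self, central_monopolar):
        sol, _, _, _ = central_monopolar
        with pytest.raises(ValueError):
            current_density(sol, np.ones((3, 3, 3)))
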