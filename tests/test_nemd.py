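"""Velocity profiles, interface location and friction arithmetic.

The expensive sheared-interface runs live in the acceptance suite; here
the analysis chain is exercised on constructed frames and profiles.
"""

import numpy as np
import pytest

from sidm import (FrictionEstimate, SlabProfiles, friction_coefficient,
                  locate_interface, velocity_profile)
from sidm.md import O, W


BOX = np.array([10.0, 10.0, 30.0])


def frames_from_profile(vfunc, n_particles=3000, n_frames=30, seed=0,
                        thermal_sd=0.0):
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        pos = rng.uniform(0, 1, (n_particles, 3)) * BOX
        vel = np.zeros((n_particles, 3))
        vel[:, 0] = vfunc(pos[:, 2])
        if thermal_sd:
            vel[:, 0] += rng.normal(0, thermal_sd, n_particles)
        frames.append((pos, vel))
    return frames


class TestVelocityProfile:
    def test_uniform_translation(self):
        frames = frames_from_profile(lambda z: 0.42 * np.ones_like(z))
        p = velocity_profile(frames, BOX, 20)
        np.testing.assert_allclose(p.vx_mean, 0.42, atol=1e-12)

    def test_imposed_linear_profile_slope_recovered(self):
        frames = frames_from_profile(lambda z: 0.05 * (z - 15.0),
                                     thermal_sd=0.3, seed=1)
        p = velocity_profile(frames, BOX, 20)
        coef = np.polyfit(p.z_centers, p.vx_mean, 1)
        assert coef[0] == pytest.approx(0.05, rel=0.01)

    def test_empty_bins_flagged_not_zeroed(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 1, (500, 3)) * BOX
        pos[:, 2] = np.clip(pos[:, 2], 5.0, 25.0)  # leave edge bins empty
        frames = [(pos, np.zeros((500, 3)))]
        p = velocity_profile(frames, BOX, 30)
        assert p.empty_bins[0] and p.empty_bins[-1]
        assert np.isnan(p.vx_mean[0])

    def test_no_frames_rejected(self):
        with pytest.raises(ValueError):
            velocity_profile([], BOX, 10)


def make_profiles(density_w, density_o=None, vx=None, n_bins=None):
    n_bins = n_bins or len(density_w)
    z = (np.arange(n_bins) + 0.5) * BOX[2] / n_bins
    dens = np.zeros((4, n_bins))
    dens[W] = density_w
    if density_o is not None:
        dens[O] = density_o
    vx = np.zeros(n_bins) if vx is None else vx
    return SlabProfiles(z_centers=z, density=dens, vx_mean=vx,
                        vx_stderr=np.full(n_bins, 1e-3),
                        counts=np.full(n_bins, 100),
                        empty_bins=np.zeros(n_bins, dtype=bool),
                        sigma_xz=1.0, sigma_xz_stderr=0.0, n_frames=10,
                        box=BOX)


class TestLocateInterface:
    def test_step_density_midpoint(self):
        n = 60
        z = (np.arange(n) + 0.5) * BOX[2] / n
        rho = np.where((z > 10.0) & (z < 20.0), 0.8, 0.0)
        planes = locate_interface(make_profiles(rho))
        assert planes == pytest.approx([10.0, 20.0], abs=BOX[2] / n)

    def test_tanh_profile_center_recovered(self):
        n = 120
        z = (np.arange(n) + 0.5) * BOX[2] / n
        rho = 0.4 * (np.tanh((z - 8.3) / 1.2) - np.tanh((z - 21.7) / 1.2))
        planes = locate_interface(make_profiles(rho))
        half_bin = 0.5 * BOX[2] / n
        assert abs(planes[0] - 8.3) < half_bin
        assert abs(planes[1] - 21.7) < half_bin

    def test_two_planes_symmetric_about_center(self):
        n = 90
        z = (np.arange(n) + 0.5) * BOX[2] / n
        rho = np.where(np.abs(z - 15.0) < 6.0, 0.8, 0.01)
        planes = locate_interface(make_profiles(rho))
        assert (planes[0] + planes[1]) / 2 == pytest.approx(15.0, abs=0.5)

    def test_liquid_liquid_crossing(self):
        n = 60
        z = (np.arange(n) + 0.5) * BOX[2] / n
        rho_o = 0.35 * (1 + np.tanh((z - 10.0) / 1.0)) * (z < 15) \
            + 0.35 * (1 + np.tanh((20.0 - z) / 1.0)) * (z >= 15)
        rho_w = 0.7 - rho_o
        planes = locate_interface(make_profiles(rho_w, rho_o))
        assert planes == pytest.approx([10.0, 20.0], abs=BOX[2] / n)

    def test_no_transition_rejected(self):
        flat = np.full(40, 0.8)
        with pytest.raises(ValueError, match="transition"):
            locate_interface(make_profiles(flat))


class TestFrictionCoefficient:
    def _profiles_with_jump(self, v_surface=1.0, slope=0.1, v_at_iface=1.5,
                            iface=10.0):
        n = 60
        z = (np.arange(n) + 0.5) * BOX[2] / n
        vx = np.where(np.abs(z - iface) <= 2.0, v_surface,
                      v_at_iface + slope * (z - iface))
        rho = np.where((z > iface) & (z < 25.0), 0.8, 0.05)
        return make_profiles(rho, vx=vx)

    def test_arithmetic_exact(self):
        # sigma=1, v_bulk extrapolates to 1.5, v_surf=1.0 -> zeta = 2
        p = self._profiles_with_jump()
        est = friction_coefficient(p, 10.0, bulk_fit_region=(13.0, 20.0),
                                   surface_region=(8.0, 12.0))
        assert est.resolved
        assert est.v_bulk_extrapolated == pytest.approx(1.5, rel=1e-6)
        assert est.v_surface == pytest.approx(1.0, rel=1e-6)
        assert est.zeta_xx == pytest.approx(2.0, rel=1e-4)

    def test_degenerate_jump_reports_unresolved(self):
        p = self._profiles_with_jump(v_at_iface=1.0)
        est = friction_coefficient(p, 10.0, bulk_fit_region=(13.0, 20.0),
                                   surface_region=(8.0, 12.0))
        assert not est.resolved
        assert np.isnan(est.zeta_xx)
        assert "coupling" in est.note

    def test_overlapping_regions_rejected(self):
        p = self._profiles_with_jump()
        with pytest.raises(ValueError, match="overlap"):
            friction_coefficient(p, 10.0, bulk_fit_region=(9.0, 20.0),
                                 surface_region=(8.0, 12.0))

    def test_estimate_invariant_under_bin_doubling(self):
        ests = []
        for n_bins in (30, 60):
            n = n_bins
            z = (np.arange(n) + 0.5) * BOX[2] / n
            vx = np.where(np.abs(z - 10.0) <= 2.0, 1.0, 1.5 + 0.1 * (z - 10.0))
            rho = np.where((z > 10.0) & (z < 25.0), 0.8, 0.05)
            p = make_profiles(rho, vx=vx, n_bins=n)
            ests.append(friction_coefficient(
                p, 10.0, bulk_fit_region=(13.0, 20.0),
                surface_region=(8.5, 11.5)).zeta_xx)
        assert ests[0] == pytest.approx(ests[1], rel=0.02)

    def test_profiles_json_round_trip(self):
        p = self._profiles_with_jump()
        q = SlabProfiles.from_dict(p.to_dict())
        np.testing.assert_allclose(q.vx_mean, p.vx_mean)
        assert q.sigma_xz == p.sigma_xz
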