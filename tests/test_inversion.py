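import math

import numpy as np
import pytest

from conftest import SPACING3, interior, make_plane_wavefield
from neuromre.inversion import (InversionConfig, directional_filter,
                                estimate_wavenumber, invert, invert_loss_angle,
                                invert_stiffness)
from neuromre.phantom import make_phantom, uniform_phantom_spec
from neuromre.waves import simulate_plane_wave, simulate_wavefield

SP2 = (0.18, 0.18)


class TestDirectionalFilter:
    def test_energy_concentrates_in_wave_sector(self):
        u = simulate_plane_wave(3.0, 0.0, 1000.0, (0, 1), (60, 90), SP2)
        parts = directional_filter(u, 8, SP2)
        energies = np.array([np.sum(np.abs(p) ** 2) for p in parts])
        frac = energies / energies.sum()
        assert frac[0] > 0.96  # sector centred on +x
        assert all(f <= 0.02 for f in frac[1:])

    def test_single_sector_full_band_is_identity(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((40, 50)) + 1j * rng.standard_normal((40, 50))
        (out,) = directional_filter(u, 1, SP2)
        assert np.allclose(out, u, atol=1e-10)

    def test_sector_sum_reconstructs_input(self):
        u = simulate_plane_wave(3.0, 0.7, 1200.0, (1, 1), (40, 60), SP2)
        rec = sum(directional_filter(u, 8, SP2))
        assert np.allclose(rec, u, atol=1e-10)

    def test_two_wave_superposition_separates(self):
        """+x and +y waves land in their own sectors, each recovered to 5%."""
        ux = simulate_plane_wave(3.0, 0.0, 1000.0, (0, 1), (60, 90), SP2)
        uy = simulate_plane_wave(3.0, 0.0, 1000.0, (1, 0), (60, 90), SP2)
        parts = directional_filter(ux + uy, 8, SP2)
        box = interior((1, 60, 90), 17)[0]
        for comp, truth in ((parts[0], ux), (parts[2], uy)):
            amp_err = np.abs(np.abs(comp[box]) - np.abs(truth[box]))
            assert amp_err.mean() < 0.05

    def test_zero_image_passes_through(self):
        parts = directional_filter(np.zeros((20, 30), complex), 4, SP2)
        assert all(np.allclose(p, 0) for p in parts)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            directional_filter(np.zeros((4, 4), complex), 0, SP2)
        with pytest.raises(ValueError):
            directional_filter(np.zeros(4, complex), 2, SP2)


class TestEstimateWavenumber:
    def test_plane_wave_wavenumber_exact(self):
        u = simulate_plane_wave(3.0, 0.0, 1200.0, (0, 1), (60, 90), SP2)
        k, amp = estimate_wavenumber(u, SP2, smoothing_sigma_px=0.0)
        kt = 2 * math.pi * 1200 / 3.0
        assert np.isclose(kt, 2513.27, atol=0.01)
        assert np.abs(k[5:-5, 5:-5] - kt).max() / kt < 1e-3
        assert np.allclose(amp, 1.0)

    def test_gauge_invariance(self):
        u = simulate_plane_wave(3.0, 0.4, 1000.0, (1, 2), (40, 60), SP2)
        k1, _ = estimate_wavenumber(u, SP2)
        k2, _ = estimate_wavenumber(u * (0.3 - 1.7j), SP2)
        assert np.allclose(k1, k2, rtol=1e-12)

    def test_two_region_field_transition_width(self):
        """k is piecewise constant away from the interface; the transition is
        no wider than twice the smoothing kernel."""
        k1, k2 = 2000.0, 3000.0
        x = np.arange(90) * 0.18e-3
        phase = np.where(x < x[45], k1 * x, k1 * x[45] + k2 * (x - x[45]))
        u = np.tile(np.exp(1j * phase), (40, 1))
        sigma = 1.0
        k, _ = estimate_wavenumber(u, SP2, smoothing_sigma_px=sigma)
        inner = k[10:-10]
        assert np.allclose(inner[:, 10:45 - 3], k1, rtol=1e-3)
        assert np.allclose(inner[:, 45 + 3:-10], k2, rtol=1e-3)
        # transition no wider than ~2 smoothing kernels on either side
        mid = inner[0, 45 - 3:45 + 3]
        assert mid.min() >= k1 * 0.999 and mid.max() <= k2 * 1.001


class TestStiffnessInversion:
    def test_homogeneous_analytic_recovery(self, plane_wf_elastic):
        """Five-frequency analytic stack: mean |c-3|/3 < 1% over the interior."""
        pm = invert(plane_wf_elastic)
        v = pm.valid_mask & interior(pm.c_map.shape, 17)
        assert np.abs(pm.c_map[v] - 3.0).mean() / 3.0 < 0.01

    def test_single_frequency_single_direction_reduces_to_omega_over_k(self):
        wf = make_plane_wavefield(3.0, 0.0, freqs=(1200.0,))
        cfg = InversionConfig(n_directions=1, smoothing_sigma_px=0.0,
                              flatten_sigma_px=0.0,
                              bandpass_k_min=0.0, bandpass_k_max=1e9)
        c_map, w = invert_stiffness(wf, cfg)
        k, _ = estimate_wavenumber(wf.components[0, 0, 0], SP2, 0.0)
        omega = 2 * math.pi * 1200
        ok = w[0] > 0
        assert np.allclose(c_map[0][ok], (omega / k)[ok], rtol=1e-6)

    def test_two_compartment_phantom_recovery(self):
        """Compartments at the group-mean speeds 3.03 / 2.55 m/s recover to
        better than 3% in the per-compartment medians."""
        ph = make_phantom(uniform_phantom_spec(3.03, 0.0, grid_shape=(1, 60, 90)))
        right = np.zeros_like(ph.brain)
        right[:, :, 45:] = True
        ph.c_true[right] = 2.55
        wf = simulate_wavefield(ph, refine=2)
        pm = invert(wf)
        box = interior(pm.c_map.shape, 17)
        away = np.ones_like(right)
        away[:, :, 41:49] = False
        mL = np.median(pm.c_map[pm.valid_mask & box & away & ~right])
        mR = np.median(pm.c_map[pm.valid_mask & box & away & right])
        assert abs(mL - 3.03) / 3.03 < 0.03
        assert abs(mR - 2.55) / 2.55 < 0.03

    def test_monotone_scaling(self):
        """Scaling the medium speed scales the recovered speed (1% tolerance)."""
        pm1 = invert(make_plane_wavefield(3.0, 0.0))
        pm2 = invert(make_plane_wavefield(3.3, 0.0))
        box = interior(pm1.c_map.shape, 17)
        r = pm2.c_map[box & pm2.valid_mask].mean() / pm1.c_map[box & pm1.valid_mask].mean()
        assert abs(r - 1.1) < 0.011

    def test_empty_frequency_list_rejected(self):
        wf = make_plane_wavefield(3.0, 0.0, freqs=(1000.0,))
        object.__setattr__(wf, "frequencies_hz", ())
        wf.components = wf.components[:0]
        with pytest.raises(ValueError):
            invert_stiffness(wf)


class TestLossAngleInversion:
    def test_elastic_limit_is_zero(self, plane_wf_elastic):
        phi, den = invert_loss_angle(plane_wf_elastic)
        box = interior(phi.shape, 14)  # clear of smoothing-boundary support
        assert np.abs(phi[box & (den > 0)]).max() < 1e-6

    def test_viscoelastic_plane_wave_recovery(self, plane_wf_visco):
        """phi = 0.70 rad (whole-brain fluidity level) recovered within 0.02."""
        phi, den = invert_loss_angle(plane_wf_visco)
        box = interior(phi.shape, 10)
        assert np.abs(phi[box & (den > 0)] - 0.7).max() < 0.02

    def test_scale_invariance(self, plane_wf_visco):
        phi1, _ = invert_loss_angle(plane_wf_visco)
        scaled = make_plane_wavefield(3.0, 0.7)
        scaled.components = scaled.components * 37.5
        phi2, _ = invert_loss_angle(scaled)
        assert np.allclose(phi1, phi2, atol=1e-9)

    def test_recovered_phi_within_physical_range(self, plane_wf_visco):
        phi, den = invert_loss_angle(plane_wf_visco)
        box = interior(phi.shape, 10) & (den > 0)
        assert (phi[box] >= 0).all() and (phi[box] <= math.pi / 2).all()


class TestJointInversion:
    def test_homogeneous_elastic_joint_oracle(self, solver_wf_elastic):
        wf, ph = solver_wf_elastic
        pm = invert(wf)
        v = pm.valid_mask & interior(pm.c_map.shape, 17)
        assert abs(np.median(pm.c_map[v]) - 3.0) / 3.0 < 0.02
        assert np.median(pm.phi_map[v]) < 0.02

    def test_all_invalid_input_rejected(self):
        wf = make_plane_wavefield(3.0, 0.0, freqs=(1000.0,))
        wf.components = wf.components * np.nan
        with pytest.raises(ValueError):
            invert(wf)

    def test_deterministic_and_carries_provenance(self, plane_wf_visco):
        a = invert(plane_wf_visco)
        b = invert(plane_wf_visco)
        assert np.array_equal(a.c_map, b.c_map)
        assert np.array_equal(a.phi_map, b.phi_map)
        assert a.provenance["input_sha256"] == b.provenance["input_sha256"]

    def test_noise_robustness_at_20db(self):
        """Homogeneous phantom with complex noise at 20 dB below the median
        brain amplitude: interior medians within 5% (c) and 0.05 rad (phi)."""
        ph = make_phantom(uniform_phantom_spec(3.0, 0.3, grid_shape=(1, 60, 90)))
        wf = simulate_wavefield(ph, noise_sigma=0.1, seed=12, refine=2)
        pm = invert(wf)
        v = pm.valid_mask & interior(pm.c_map.shape, 17)
        assert abs(np.median(pm.c_map[v]) - 3.0) / 3.0 < 0.05
        assert abs(np.median(pm.phi_map[v]) - 0.3) < 0.05

    def test_brain_mask_and_edge_margin_restrict_validity(self, plane_wf_visco):
        mask = np.zeros((1, 60, 90), bool)
        mask[0, 20:40, 30:60] = True
        pm = invert(plane_wf_visco, InversionConfig(edge_margin_px=2),
                    brain_mask=mask)
        assert pm.valid_mask.sum() <= (20 - 4) * (30 - 4)
        assert not (pm.valid_mask & ~mask).any()


def test_config_validation():
    with pytest.raises(ValueError):
        InversionConfig(n_directions=0)
    with pytest.raises(ValueError):
        InversionConfig(bandpass_k_min=10.0, bandpass_k_max=5.0)
    with pytest.raises(ValueError):
        InversionConfig(edge_margin_px=-1)
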