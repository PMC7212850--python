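"""Diffusion closed form, voxel Monte Carlo, DVH and radial summaries."""

import numpy as np
import pytest

from pdtdose.light_transport import (
    FluenceField,
    Phantom,
    TissueOptics,
    diffusion_fluence,
    dose_volume_histogram,
    effective_penetration_depth,
    mc_fluence,
    radial_average,
)
from pdtdose.photonics import LightSource

EMITTER = LightSource(
    "emitter", power=0.2, wavelength_nm=808.0, duration_s=3000.0,
    geometry="isotropic_point", mode="power",
)


class TestTissueOptics:
    def test_derived_quantities_consistent(self):
        opt = TissueOptics(mu_a=0.02, mu_s_prime=16.62, g=0.9)
        mu_t_prime = opt.mu_a + opt.mu_s_prime
        assert opt.diffusion_constant == pytest.approx(1 / (3 * mu_t_prime), rel=1e-12)
        assert opt.mu_eff == pytest.approx(
            np.sqrt(3 * opt.mu_a * mu_t_prime), rel=1e-12)
        assert opt.mu_s == pytest.approx(16.62 / 0.1, rel=1e-12)
        assert 0.99 < opt.albedo < 1.0

    @pytest.mark.parametrize(
        "kwargs", [dict(mu_a=0.0), dict(mu_s_prime=-1.0), dict(g=1.0)])
    def test_invalid_optics(self, kwargs):
        base = dict(mu_a=0.02, mu_s_prime=16.62, g=0.9)
        base.update(kwargs)
        with pytest.raises(ValueError):
            TissueOptics(**base)


class TestDiffusionFluence:
    def test_anchor_value(self):
        opt = TissueOptics(mu_a=0.02, mu_s_prime=16.62, g=0.9)
        assert opt.mu_eff == pytest.approx(1.0, rel=1e-3)
        assert diffusion_fluence(1.0, 0.2, opt) == pytest.approx(0.29, rel=0.01)

    def test_monotone_and_linear(self):
        opt = TissueOptics(mu_a=0.05, mu_s_prime=10.0)
        r = np.linspace(0.1, 2.0, 50)
        phi = diffusion_fluence(r, 0.2, opt)
        assert np.all(np.diff(phi) < 0)
        assert diffusion_fluence(r, 0.4, opt) == pytest.approx(2 * phi, rel=1e-12)

    def test_singularity(self):
        opt = TissueOptics(mu_a=0.05, mu_s_prime=10.0)
        with pytest.raises(ValueError):
            diffusion_fluence(0.0, 0.2, opt)


class TestPenetrationDepth:
    def test_definition_and_scaling(self):
        opt = TissueOptics(mu_a=0.02, mu_s_prime=16.62)
        assert effective_penetration_depth(opt) == pytest.approx(1 / opt.mu_eff)
        deeper = TissueOptics(mu_a=0.08, mu_s_prime=16.56)  # mu_eff doubled
        assert effective_penetration_depth(deeper) == pytest.approx(
            effective_penetration_depth(opt) / 2, rel=1e-2)

    def test_gray_deeper_than_white_at_equal_absorption(self):
        gray = TissueOptics(mu_a=0.02, mu_s_prime=16.62, label="gray")
        white = TissueOptics(mu_a=0.02, mu_s_prime=40.0, label="white")
        assert effective_penetration_depth(gray) > effective_penetration_depth(white)


class TestPhantom:
    def test_source_must_be_inside(self):
        opt = TissueOptics(mu_a=0.1, mu_s_prime=10.0)
        with pytest.raises(ValueError):
            Phantom(np.zeros((10, 10, 10), np.uint8), 0.1, {0: opt},
                    source_cm=(2.0, 0.5, 0.5))

    def test_undefined_label(self):
        opt = TissueOptics(mu_a=0.1, mu_s_prime=10.0)
        labels = np.zeros((5, 5, 5), np.uint8)
        labels[2, 2, 2] = 3
        with pytest.raises(ValueError):
            Phantom(labels, 0.1, {0: opt})


@pytest.fixture(scope="module")
def small_run():
    opt = TissueOptics(mu_a=0.1, mu_s_prime=10.0, g=0.0)
    phantom = Phantom.homogeneous(opt, shape=(31, 31, 31), voxel_cm=0.1)
    field = mc_fluence(phantom, EMITTER, packets=20000, seed=42)
    return opt, phantom, field


class TestMonteCarlo:
    def test_seed_determinism(self, small_run):
        opt, phantom, field = small_run
        again = mc_fluence(phantom, EMITTER, packets=20000, seed=42)
        assert np.array_equal(field.fluence_per_packet, again.fluence_per_packet)
        other = mc_fluence(phantom, EMITTER, packets=20000, seed=43)
        assert not np.array_equal(field.fluence_per_packet, other.fluence_per_packet)

    def test_energy_conservation(self, small_run):
        _, _, field = small_run
        assert field.weight_balance_error < 1e-6

    def test_nonnegative_and_absorbed_below_launched(self, small_run):
        _, _, field = small_run
        assert np.all(field.fluence_per_packet >= 0)
        assert field.absorbed_weight <= field.packets

    def test_geometry_and_mode_audit(self, small_run):
        _, phantom, _ = small_run
        flat = LightSource("well", power=0.36, wavelength_nm=530,
                           duration_s=55.6, geometry="flat_field")
        with pytest.raises(ValueError):
            mc_fluence(phantom, flat, packets=20000)
        with pytest.raises(ValueError):
            mc_fluence(phantom, EMITTER, packets=100)

    def test_matches_diffusion_with_anisotropic_scattering(self):
        # similarity: (mu_s', g) pairs with equal reduced scattering give the
        # same diffusive field; validates the Henyey-Greenstein sampling
        opt = TissueOptics(mu_a=0.05, mu_s_prime=8.0, g=0.5)
        phantom = Phantom.homogeneous(opt, shape=(41, 41, 41), voxel_cm=0.075)
        field = mc_fluence(phantom, EMITTER, packets=150000, seed=3)
        r = phantom.voxel_radii_cm()
        edges = np.linspace(0.25, 0.9, 6)
        _, mc = radial_average(field.fluence_rate_w_cm2, phantom, edges)
        _, diff = radial_average(
            diffusion_fluence(np.maximum(r, 1e-9), 0.2, opt), phantom, edges)
        assert np.nanmax(np.abs(mc - diff) / diff) < 0.15

    def test_standard_error_scales_as_inverse_sqrt_packets(self):
        opt = TissueOptics(mu_a=0.1, mu_s_prime=10.0, g=0.0)
        phantom = Phantom.homogeneous(opt, shape=(21, 21, 21), voxel_cm=0.1)
        edges = np.array([0.3, 0.5])
        budgets = [10000, 20000, 40000, 80000]
        sds = []
        for n in budgets:
            vals = []
            for rep in range(6):
                f = mc_fluence(phantom, EMITTER, packets=n, seed=100 * n + rep)
                _, m = radial_average(f.fluence_per_packet, phantom, edges)
                vals.append(m[0])
            sds.append(np.std(vals, ddof=1))
        slope = np.polyfit(np.log(budgets), np.log(sds), 1)[0]
        assert -0.75 < slope < -0.25

    def test_field_invariant_under_source_and_grid_translation(self):
        opt = TissueOptics(mu_a=0.1, mu_s_prime=10.0, g=0.0)
        labels = np.zeros((41, 41, 41), np.uint8)
        a = Phantom(labels, 0.1, {0: opt}, source_cm=(2.05, 2.05, 2.05))
        b = Phantom(labels, 0.1, {0: opt}, source_cm=(2.35, 2.05, 2.05))
        edges = np.linspace(0.3, 1.0, 5)
        fa = mc_fluence(a, EMITTER, packets=100000, seed=9)
        fb = mc_fluence(b, EMITTER, packets=100000, seed=9)
        _, ma = radial_average(fa.fluence_per_packet, a, edges)
        _, mb = radial_average(fb.fluence_per_packet, b, edges)
        assert np.nanmax(np.abs(ma - mb) / ma) < 0.05


class TestRadialAverage:
    def test_matches_brute_force(self, small_run):
        _, phantom, field = small_run
        edges = np.array([0.2, 0.5, 0.8])
        _, means = radial_average(field.fluence_per_packet, phantom, edges)
        r = phantom.voxel_radii_cm()
        for b in range(2):
            sel = (r >= edges[b]) & (r < edges[b + 1])
            assert means[b] == pytest.approx(field.fluence_per_packet[sel].mean())


class TestDoseVolumeHistogram:
    def test_uniform_field_is_step_function(self, small_run):
        _, phantom, field = small_run
        uniform = np.full(phantom.labels.shape, 7.0)
        dose, vol = dose_volume_histogram(field, phantom, values=uniform)
        assert dose.tolist() == [0.0, 7.0]
        assert vol[0] == pytest.approx(phantom.total_volume_cm3)
        assert vol[1] == pytest.approx(phantom.total_volume_cm3)

    def test_total_volume_at_zero_dose(self, small_run):
        _, phantom, field = small_run
        dose, vol = dose_volume_histogram(field, phantom)
        assert dose[0] == 0.0
        assert vol[0] == pytest.approx(
            phantom.labels.size * phantom.voxel_volume_cm3)
        assert np.all(np.diff(vol) <= 0)

    def test_against_voxel_sort_oracle(self, rng):
        opt = TissueOptics(mu_a=0.1, mu_s_prime=10.0)
        phantom = Phantom.homogeneous(opt, shape=(20, 20, 20), voxel_cm=0.1)
        values = rng.random(phantom.labels.shape)
        field = FluenceField(
            fluence_per_packet=values, packets=1, seed=0, source=EMITTER,
            phantom=phantom, absorbed_weight=1, escaped_weight=0,
            roulette_killed_weight=0, roulette_gained_weight=0)
        dose, vol = dose_volume_histogram(field, phantom, values=values)
        for d, v in zip(dose[::500], vol[::500]):
            assert v == pytest.approx(
                np.sum(values >= d) * phantom.voxel_volume_cm3)
        # strictly decreasing over the support (dose[0]=0 shares V with the min)
        assert np.all(np.diff(vol[1:]) < 0)

    def test_grid_mismatch(self, small_run):
        _, phantom, field = small_run
        opt = TissueOptics(mu_a=0.1, mu_s_prime=10.0)
        other = Phantom.homogeneous(opt, shape=(10, 10, 10), voxel_cm=0.1)
        with pytest.raises(ValueError):
            dose_volume_histogram(field, other)
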