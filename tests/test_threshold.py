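"""Threshold estimation/inversion, selectivity heuristic, edema helpers."""

import numpy as np
import pytest
from scipy import stats

from pdtdose import presets
from pdtdose.light_transport import TissueOptics
from pdtdose.photonics import LightSource
from pdtdose.synthetic import ThresholdDesign, gen_boundaries
from pdtdose.threshold import (
    BoundaryObservation,
    absorbed_density_profile,
    edema_fold_change,
    mask_volume_cm3,
    predict_necrosis_radius,
    selectivity_depths,
    threshold_at_boundary,
    two_sample_t,
    ug_per_g_to_molar,
)

SRC = presets.INTERSTITIAL_808
OPT = presets.TUMOR_808
PS = presets.RUTHERRIN_808
CONC = ug_per_g_to_molar(5.0, 1007.0)


def test_ug_per_g_to_molar():
    assert ug_per_g_to_molar(19.93, 1007.0) == pytest.approx(1.98e-5, rel=1e-2)
    with pytest.raises(ValueError):
        ug_per_g_to_molar(-1.0, 1007.0)


class TestForwardInverse:
    def test_round_trip_recovers_threshold(self):
        true_t = 8.86e18
        r = predict_necrosis_radius(true_t, SRC, OPT, PS, CONC, xtol_cm=1e-12)
        obs = [BoundaryObservation("a1", r, r)]
        est = threshold_at_boundary(obs, SRC, OPT, PS, CONC)
        assert est.threshold_hv_cm3 == pytest.approx(true_t, rel=1e-9)

    def test_inverse_round_trip_over_random_configurations(self, rng):
        for _ in range(20):
            opt = TissueOptics(
                mu_a=rng.uniform(0.01, 0.2), mu_s_prime=rng.uniform(5, 30))
            conc = rng.uniform(1e-7, 1e-4)
            r_target = rng.uniform(0.1, 1.5)
            t = absorbed_density_profile(r_target, SRC, opt, PS, conc)
            r_back = predict_necrosis_radius(
                t, SRC, opt, PS, conc, xtol_cm=1e-10)
            assert r_back == pytest.approx(r_target, abs=1e-8)

    def test_threshold_decreasing_in_radius(self):
        radii = np.linspace(0.1, 1.0, 20)
        t = absorbed_density_profile(radii, SRC, OPT, PS, CONC)
        assert np.all(np.diff(t) < 0)

    def test_radius_increasing_in_exposure_time(self):
        t = 1e19
        slow = LightSource("s", power=SRC.power, wavelength_nm=808.0,
                           duration_s=2 * SRC.duration_s,
                           geometry="isotropic_point", mode="power")
        assert (predict_necrosis_radius(t, slow, OPT, PS, CONC)
                > predict_necrosis_radius(t, SRC, OPT, PS, CONC))

    def test_huge_threshold_gives_zero_radius(self):
        assert predict_necrosis_radius(1e40, SRC, OPT, PS, CONC) == 0.0


class TestCohortEstimation:
    def test_jitterless_cohort_recovers_exactly(self):
        design = ThresholdDesign(
            name="t", true_threshold_hv_cm3=8.86e18, source=SRC, optics=OPT,
            ps=PS, tissue_concentration_m=CONC, radius_jitter_cv=0.0)
        obs = gen_boundaries(design, seed=0)
        est = threshold_at_boundary(obs, SRC, OPT, PS, CONC)
        assert est.threshold_hv_cm3 == pytest.approx(8.86e18, rel=1e-4)
        assert est.sd_hv_cm3 == pytest.approx(0.0, abs=1e-6 * 8.86e18)

    def test_jittered_cohort_mean_near_truth(self, rng):
        design = ThresholdDesign(
            name="t", true_threshold_hv_cm3=8.86e18, source=SRC, optics=OPT,
            ps=PS, tissue_concentration_m=CONC)
        hits = 0
        n_seeds = 40
        for seed in rng.integers(0, 2**31 - 1, size=n_seeds):
            obs = gen_boundaries(design, int(seed))
            est = threshold_at_boundary(obs, SRC, OPT, PS, CONC)
            hits += abs(est.threshold_hv_cm3 - 8.86e18) <= est.sd_hv_cm3
        assert hits / n_seeds >= 0.8

    def test_first_order_se_matches_bootstrap(self, rng):
        design = ThresholdDesign(
            name="t", true_threshold_hv_cm3=8.86e18, source=SRC, optics=OPT,
            ps=PS, tissue_concentration_m=CONC)
        obs = gen_boundaries(design, seed=5)
        est = threshold_at_boundary(obs, SRC, OPT, PS, CONC)
        se_first_order = est.sd_hv_cm3 / np.sqrt(len(obs))
        boot = [
            rng.choice(est.per_animal, size=len(obs), replace=True).mean()
            for _ in range(2000)
        ]
        se_boot = np.std(boot, ddof=1)
        assert se_boot == pytest.approx(se_first_order, rel=0.2)

    def test_mc_transport_agrees_with_diffusion(self):
        opt = TissueOptics(mu_a=0.02, mu_s_prime=16.62, g=0.0, label="tumor")
        obs = [BoundaryObservation("a", 0.4, 0.5)]
        diff = threshold_at_boundary(obs, SRC, opt, PS, CONC)
        mc = threshold_at_boundary(
            obs, SRC, opt, PS, CONC, transport="mc",
            mc_packets=100000, mc_seed=2)
        assert mc.threshold_hv_cm3 == pytest.approx(
            diff.threshold_hv_cm3, rel=0.15)

    def test_boundary_choice(self):
        obs = [BoundaryObservation("a", 0.3, 0.6)]
        upper = threshold_at_boundary(obs, SRC, OPT, PS, CONC, boundary="min")
        lower = threshold_at_boundary(obs, SRC, OPT, PS, CONC, boundary="max")
        assert upper.threshold_hv_cm3 > lower.threshold_hv_cm3

    def test_tumor_normal_ordering_under_study_configuration(self):
        """Normal brain necroses at a lower absorbed photon density than tumor."""
        c_tumor = ug_per_g_to_molar(presets.TUMOR_TLD1433_UG_PER_G, 1007.0)
        tum_design = ThresholdDesign(
            name="tumor", true_threshold_hv_cm3=presets.THRESHOLD_RUTHERRIN_TUMOR[0],
            source=SRC, optics=OPT, ps=PS, tissue_concentration_m=c_tumor)
        nrm_design = ThresholdDesign(
            name="normal", true_threshold_hv_cm3=presets.THRESHOLD_RUTHERRIN_NORMAL[0],
            source=SRC, optics=presets.GRAY_808, ps=PS,
            tissue_concentration_m=c_tumor / presets.SUR_RUTHERRIN)
        tum = threshold_at_boundary(
            gen_boundaries(tum_design, 11), SRC, OPT, PS, c_tumor)
        nrm = threshold_at_boundary(
            gen_boundaries(nrm_design, 12), SRC, presets.GRAY_808, PS,
            c_tumor / presets.SUR_RUTHERRIN)
        assert nrm.threshold_hv_cm3 < tum.threshold_hv_cm3


class TestSelectivity:
    @pytest.mark.parametrize(
        "sur, depths", [(3.0, 1.0), (20.0, 2.7268), (10.6, 2.1489)])
    def test_depth_anchors(self, sur, depths):
        assert selectivity_depths(sur) == pytest.approx(depths, abs=5e-4)

    def test_distance_uses_penetration_depth(self):
        depths, dist = selectivity_depths(9.0, presets.GRAY_808)
        assert depths == pytest.approx(2.0)
        assert dist == pytest.approx(2.0 / presets.GRAY_808.mu_eff)

    def test_domain(self):
        with pytest.raises(ValueError):
            selectivity_depths(0.5)
        assert selectivity_depths(1.0) == 0.0


class TestEdema:
    def test_fold_change_identity_and_errors(self):
        assert edema_fold_change(2.0, 2.0) == 1.0
        assert edema_fold_change(1.0, 2.5) == 2.5
        with pytest.raises(ValueError):
            edema_fold_change(0.0, 1.0)

    def test_mask_volume(self):
        # N voxels of 0.2 x 0.2 x 0.5 mm -> N * 0.02 mm^3
        assert mask_volume_cm3(1000, (0.2, 0.2, 0.5)) == pytest.approx(
            1000 * 0.02 * 1e-3)

    def test_equal_mean_groups_give_zero_t(self):
        x = [1.0, 1.2, 0.8, 1.0]
        y = [0.9, 1.1, 1.2, 0.8]
        t, p = two_sample_t(x, y)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_t_matches_scipy(self, rng):
        x = rng.normal(1.0, 0.3, 8)
        y = rng.normal(2.0, 0.3, 6)
        t, p = two_sample_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)
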