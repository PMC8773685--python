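"""SNR formula, fit-mask rule and the kPL estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hp13c import kinetics
from hp13c.coil_combination import apply_weights, compute_weights, sum_time_maps
from hp13c.kinetics import (
    NoiseEstimate,
    build_fit_mask,
    compute_snr,
    estimate_noise,
    fit_kpl_frequency_domain,
    fit_kpl_map,
    fit_kpl_time_domain_oracle,
    lac_pyr_ratio,
)
from hp13c.synthetic_data import (
    AcquisitionGeometry,
    BolusModel,
    KineticModelParams,
    make_phantom_scene,
    simulate_phantom,
    simulate_two_site_exchange,
)


class TestComputeSNR:
    def test_null_signal(self):
        noise = NoiseEstimate(mean_noise=2.0, sd_noise=1.5)
        assert compute_snr(np.full(10, 2.0), noise) == 0.0

    def test_worked_example(self):
        noise = NoiseEstimate(mean_noise=2.0, sd_noise=2.0)
        snr = compute_snr(np.full(5, 10.0), noise)
        assert snr == pytest.approx((10 - 2) / (np.sqrt(2) * 2), rel=1e-12)
        assert snr == pytest.approx(2.8284, abs=1e-4)

    @settings(deadline=None, max_examples=30)
    @given(c=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_offset_and_scale_equivariance(self, c, scale):
        rng = np.random.default_rng(0)
        roi = rng.uniform(5, 15, 40)
        noise_vals = rng.uniform(0.5, 2.5, 200)
        n1 = estimate_noise(noise_vals, min_voxels=100)
        base = compute_snr(roi, n1)
        # shared offset cancels
        n2 = estimate_noise(noise_vals + c, min_voxels=100)
        assert compute_snr(roi + c, n2) == pytest.approx(base, abs=1e-9)
        # shared positive scale cancels
        n3 = estimate_noise(noise_vals * scale, min_voxels=100)
        assert compute_snr(roi * scale, n3) == pytest.approx(base, rel=1e-9)

    def test_errors(self):
        noise = NoiseEstimate(mean_noise=0.0, sd_noise=1.0)
        with pytest.raises(ValueError):
            compute_snr(np.array([]), noise)
        with pytest.raises(ValueError):
            NoiseEstimate(mean_noise=0.0, sd_noise=0.0)

    def test_rayleigh_background_mean_snr_near_zero(self):
        # Formula applied to pure Rayleigh ROIs averages to ~0
        rng = np.random.default_rng(3)
        sigma = 1.0
        mags = np.abs(rng.normal(0, sigma, 10_000)
                      + 1j * rng.normal(0, sigma, 10_000))
        noise = estimate_noise(mags)
        snrs = [compute_snr(m, noise) for m in mags.reshape(1000, 10)]
        assert abs(np.mean(snrs)) < 0.05


class TestFitMask:
    def test_inclusive_boundary(self):
        noise = NoiseEstimate(mean_noise=0.0, sd_noise=1.0)
        s2 = np.sqrt(2.0)
        vals = np.array([[[4.9 * s2, 5.0 * s2, 5.1 * s2]]])
        mask = build_fit_mask(vals, noise, threshold=5.0)
        assert mask.tolist() == [[[False, True, True]]]

    def test_infinite_threshold_empty(self, rng):
        noise = NoiseEstimate(mean_noise=0.0, sd_noise=1.0)
        assert not build_fit_mask(rng.uniform(0, 100, (2, 4, 4)), noise,
                                  threshold=np.inf).any()

    def test_monotone_in_threshold(self, rng):
        noise = NoiseEstimate(mean_noise=1.0, sd_noise=2.0)
        vals = rng.uniform(0, 40, (3, 8, 8))
        m5 = build_fit_mask(vals, noise, threshold=5.0)
        m6 = build_fit_mask(vals, noise, threshold=6.0)
        assert np.all(m5 | ~m6)  # m6 subset of m5


PAPER_KPL_VALUES = (0.0065, 0.0043, 0.0152, 0.0086, 0.0022)


class TestFrequencyDomainFit:
    def test_zero_lactate_gives_zero_kpl(self, noiseless_courses):
        pyr, _ = noiseless_courses
        res = fit_kpl_frequency_domain(pyr, np.zeros_like(pyr), 4.0)
        assert res.k_pl_hat == pytest.approx(0.0, abs=1e-9)
        assert kinetics.FLAG_ZERO_LACTATE in res.flags

    @pytest.mark.parametrize("kpl", PAPER_KPL_VALUES)
    def test_noiseless_recovery_within_two_percent(self, kpl, default_geometry,
                                                   bolus):
        pyr, lac = simulate_two_site_exchange(
            KineticModelParams(k_pl=kpl, t1_eff=30.0), bolus, default_geometry)
        res = fit_kpl_frequency_domain(pyr, lac, default_geometry.frame_spacing)
        assert res.k_pl_hat == pytest.approx(kpl, rel=0.02)
        assert res.method == "frequency_domain"

    def test_scale_invariance(self, noiseless_courses):
        pyr, lac = noiseless_courses
        r1 = fit_kpl_frequency_domain(pyr, lac, 4.0)
        r2 = fit_kpl_frequency_domain(pyr * 1e4, lac * 1e4, 4.0)
        assert r2.k_pl_hat == pytest.approx(r1.k_pl_hat, rel=1e-12)
        assert r2.inv_t1_eff_hat == pytest.approx(r1.inv_t1_eff_hat, rel=1e-12)

    def test_errors(self, noiseless_courses):
        pyr, lac = noiseless_courses
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_kpl_frequency_domain(np.zeros_like(pyr), lac, 4.0)
        with pytest.raises(ValueError):
            fit_kpl_frequency_domain(pyr[:-1], lac, 4.0)
        with pytest.raises(ValueError):
            fit_kpl_frequency_domain(pyr[:3], lac[:3], 4.0)

    def test_monte_carlo_median_bias_below_ten_percent(self, default_geometry,
                                                       bolus):
        # phase-corrected real channel at the reported pyruvate SNR (~27):
        # median kPL bias over Monte-Carlo repetitions stays below 10%
        kpl = 0.0065
        pyr, lac = simulate_two_site_exchange(
            KineticModelParams(k_pl=kpl), bolus, default_geometry)
        s_sum = pyr.sum()
        sigma_s = s_sum / (np.sqrt(np.pi / 2)
                           + 27.0 * np.sqrt(2) * np.sqrt(2 - np.pi / 2))
        sigma = sigma_s / np.sqrt(default_geometry.n_frames)
        rng = np.random.default_rng(0)
        n_rep = 2000
        ests = np.empty(n_rep)
        for i in range(n_rep):
            p = pyr + rng.normal(0, sigma, pyr.size)
            l = lac + rng.normal(0, sigma, lac.size)
            ests[i] = fit_kpl_frequency_domain(p, l, 4.0, noise_sd=sigma).k_pl_hat
        bias = np.median(ests) - kpl
        assert abs(bias) < 0.10 * kpl


class TestTimeDomainOracle:
    def test_zero_kpl(self, default_geometry, bolus):
        pyr, lac = simulate_two_site_exchange(
            KineticModelParams(k_pl=0.0), bolus, default_geometry)
        res = fit_kpl_time_domain_oracle(pyr, lac, 4.0)
        assert res.k_pl_hat == pytest.approx(0.0, abs=1e-8)

    def test_liposarcoma_value_recovered(self, default_geometry, bolus):
        pyr, lac = simulate_two_site_exchange(
            KineticModelParams(k_pl=0.0152), bolus, default_geometry)
        res = fit_kpl_time_domain_oracle(pyr, lac, 4.0)
        assert res.k_pl_hat == pytest.approx(0.0152, rel=0.02)
        assert res.method == "time_domain_oracle"

    def test_scale_invariance(self, noiseless_courses):
        pyr, lac = noiseless_courses
        r1 = fit_kpl_time_domain_oracle(pyr, lac, 4.0)
        r2 = fit_kpl_time_domain_oracle(2 * pyr, 2 * lac, 4.0)
        assert r2.k_pl_hat == pytest.approx(r1.k_pl_hat, rel=1e-6)


class TestLacPyrRatio:
    def _maps(self, pyr, lac):
        from hp13c.coil_combination import MetaboliteMaps

        return MetaboliteMaps(pyruvate=pyr, lactate=lac,
                              total_carbon=pyr + lac)

    def test_identity(self, rng):
        pyr = rng.uniform(1, 5, (1, 4, 4))
        maps = self._maps(pyr, pyr.copy())
        assert lac_pyr_ratio(maps, np.ones_like(pyr, bool)) == pytest.approx(1.0)

    def test_zero_lactate(self, rng):
        pyr = rng.uniform(1, 5, (1, 4, 4))
        maps = self._maps(pyr, np.zeros_like(pyr))
        assert lac_pyr_ratio(maps, np.ones_like(pyr, bool)) == 0.0

    def test_constructed_ratio(self, rng):
        # voxel-wise lac = 0.35 * pyr forces the ROI ratio to 0.35
        pyr = rng.uniform(1, 5, (1, 4, 4))
        maps = self._maps(pyr, 0.35 * pyr)
        mask = np.zeros_like(pyr, bool)
        mask[0, :2] = True
        assert lac_pyr_ratio(maps, mask) == pytest.approx(0.35, rel=1e-12)

    def test_zero_pyruvate_raises(self):
        maps = self._maps(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)))
        with pytest.raises(ValueError):
            lac_pyr_ratio(maps, np.ones((1, 2, 2), bool))


@pytest.fixture(scope="module")
def uniform_setup(bolus):
    g = AcquisitionGeometry(acq_matrix=(8, 8), recon_matrix=(8, 8),
                            n_slices=1, n_coils=2)
    scene = make_phantom_scene(g, KineticModelParams(0.0086), noise_sd=0.0)
    img = simulate_phantom(scene, bolus, g)
    combined = apply_weights(img, compute_weights(img))
    return g, scene, combined


class TestFitKplMap:
    def test_uniform_noiseless_constant_map(self, uniform_setup):
        g, scene, combined = uniform_setup
        tumor = scene.label_map == 3
        res = fit_kpl_map(combined, tumor, g.frame_spacing)
        vals = res.k_pl[tumor]
        assert np.all(np.isfinite(vals))
        np.testing.assert_allclose(vals, 0.0086, rtol=0.02)
        assert np.all(np.isnan(res.k_pl[~tumor]))

    def test_empty_mask_warns_all_missing(self, uniform_setup, caplog):
        g, scene, combined = uniform_setup
        with caplog.at_level("WARNING", logger="hp13c"):
            res = fit_kpl_map(combined, np.zeros_like(scene.label_map, bool),
                              g.frame_spacing)
        assert np.all(np.isnan(res.k_pl))
        assert any("empty mask" in r.message for r in caplog.records)

    def test_map_matches_per_voxel_estimator(self, uniform_setup):
        g, scene, combined = uniform_setup
        tumor = scene.label_map == 3
        res = fit_kpl_map(combined, tumor, g.frame_spacing)
        s, y, x = np.argwhere(tumor)[0]
        course = combined[:, :, s, y, x]
        vals = kinetics.phase_corrected_real(course[None])[0]
        single = fit_kpl_frequency_domain(vals[0], vals[1], g.frame_spacing)
        assert res.k_pl[s, y, x] == pytest.approx(single.k_pl_hat, rel=1e-9)


def test_mask_region_matches_snr_rule_on_noisy_phantom(bolus):
    """Every retained voxel has magnitude-convention SNR >= 5; in-body excluded < 5."""
    g = AcquisitionGeometry(acq_matrix=(32, 32), recon_matrix=(32, 32),
                            n_slices=1, n_coils=2)
    scene = make_phantom_scene(g, KineticModelParams(0.0065), noise_sd=0.6,
                               seed=21)
    img = simulate_phantom(scene, bolus, g)
    maps = sum_time_maps(apply_weights(img, compute_weights(img)))
    noise = estimate_noise(maps.total_carbon[scene.label_map == 0])
    mask = build_fit_mask(maps.total_carbon, noise, threshold=5.0)
    body = scene.label_map > 0
    # brute-force per-voxel SNR via the scalar formula
    for s, y, x in np.argwhere(mask):
        assert compute_snr(maps.total_carbon[s:s + 1, y, x], noise) >= 5.0
    for s, y, x in np.argwhere(body & ~mask):
        assert compute_snr(maps.total_carbon[s:s + 1, y, x], noise) < 5.0
    assert mask.any() and (body & ~mask).any()
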