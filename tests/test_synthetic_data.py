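"""Generator-level tests: bolus, exchange integration, phantoms, IHC, cohorts."""

import numpy as np
import pytest

from hp13c import ihc_quant
from hp13c.kinetics import _lactate_model
from hp13c.synthetic_data import (
    AcquisitionGeometry,
    BolusModel,
    KineticModelParams,
    PhantomScene,
    RegionSpec,
    evaluate_bolus,
    generate_cohort,
    generate_ihc_image,
    make_phantom_scene,
    simulate_phantom,
    simulate_two_site_exchange,
)


class TestBolus:
    def test_zero_before_arrival(self):
        b = BolusModel(arrival_time=5.0)
        assert evaluate_bolus(b, 4.999) == 0.0
        assert np.all(evaluate_bolus(b, np.array([-3.0, 0.0, 5.0])) == 0.0)

    def test_peak_value_is_amplitude_at_shape_times_scale(self):
        b = BolusModel(arrival_time=2.0, shape=3.0, scale=2.0, amplitude=7.5)
        t_peak = b.arrival_time + b.shape * b.scale
        assert evaluate_bolus(b, t_peak) == pytest.approx(7.5, rel=1e-12)
        # strict maximum: neighbors are lower
        assert evaluate_bolus(b, t_peak - 0.1) < 7.5
        assert evaluate_bolus(b, t_peak + 0.1) < 7.5

    def test_zero_amplitude(self):
        b = BolusModel(amplitude=0.0)
        t = np.linspace(0, 60, 50)
        assert np.all(evaluate_bolus(b, t) == 0.0)

    def test_nonnegative_and_finite_integral(self):
        b = BolusModel()
        t = np.linspace(0, 500, 20000)
        vals = evaluate_bolus(b, t)
        assert np.all(vals >= 0)
        assert np.trapezoid(vals, t) < np.inf
        assert vals[-1] < 1e-12  # decays

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            BolusModel(shape=-1.0)
        with pytest.raises(ValueError):
            BolusModel(scale=np.nan)
        with pytest.raises(ValueError):
            evaluate_bolus(BolusModel(), np.inf)


class TestTwoSiteExchange:
    def test_zero_kpl_gives_zero_lactate(self, default_geometry, bolus):
        pyr, lac = simulate_two_site_exchange(
            KineticModelParams(k_pl=0.0), bolus, default_geometry)
        assert np.all(lac == 0.0)
        assert pyr.max() > 0

    def test_linearity_in_bolus_amplitude(self, default_geometry):
        params = KineticModelParams(k_pl=0.008)
        p1, l1 = simulate_two_site_exchange(params, BolusModel(amplitude=1.0),
                                            default_geometry)
        p2, l2 = simulate_two_site_exchange(params, BolusModel(amplitude=2.0),
                                            default_geometry)
        np.testing.assert_allclose(p2, 2 * p1, rtol=1e-10)
        np.testing.assert_allclose(l2, 2 * l1, rtol=1e-10)

    def test_constant_input_closed_form(self):
        # dL/dt = kPL*P0 - L/t1_eff with constant P0 has the closed form
        # L(T) = kPL * t1_eff * P0 * (1 - exp(-T/t1_eff)); the exact
        # piecewise solution used throughout must match to 0.1%.
        kpl, t1_eff, p0, T = 0.01, 30.0, 5.0, 60.0
        times = np.linspace(0.0, T, 601)
        lac = _lactate_model(kpl, 1.0 / t1_eff, np.full(times.size, p0),
                             times, lac0=0.0)
        expected = kpl * t1_eff * p0 * (1 - np.exp(-T / t1_eff))
        assert lac[-1] == pytest.approx(expected, rel=1e-3)

    def test_coarse_fine_dt_refused(self, default_geometry, bolus):
        with pytest.raises(ValueError, match="fine_dt"):
            simulate_two_site_exchange(KineticModelParams(0.005), bolus,
                                       default_geometry, fine_dt=1.0)

    def test_steady_state_bound(self, default_geometry, bolus):
        # noiseless lactate never exceeds kPL * t1_eff * max(pyruvate)
        for kpl in (0.002, 0.0065, 0.02):
            params = KineticModelParams(k_pl=kpl, t1_eff=30.0)
            pyr, lac = simulate_two_site_exchange(params, bolus,
                                                  default_geometry,
                                                  rf_depletion=False)
            assert np.all(lac <= kpl * params.t1_eff * pyr.max() * (1 + 1e-9))

    def test_depletion_factors_compound(self, default_geometry, bolus):
        params = KineticModelParams(k_pl=0.0065)
        p0, l0 = simulate_two_site_exchange(params, bolus, default_geometry,
                                            rf_depletion=False)
        p1, l1 = simulate_two_site_exchange(params, bolus, default_geometry,
                                            rf_depletion=True)
        fac = default_geometry.depletion_factors()
        np.testing.assert_allclose(p1, p0 * fac, rtol=1e-12)
        np.testing.assert_allclose(l1, l0 * fac, rtol=1e-12)


class TestPhantom:
    def test_identity_sensitivity_no_noise_reproduces_courses(self, bolus):
        g = AcquisitionGeometry(acq_matrix=(8, 8), recon_matrix=(8, 8),
                                n_slices=1, n_coils=1)
        params = KineticModelParams(k_pl=0.0065)
        label = np.ones((1, 8, 8), dtype=np.int16)
        scene = PhantomScene(
            label_map=label,
            region_params={1: RegionSpec(params, delivery=1.0)},
            coil_sens=np.ones((1, 8, 8), dtype=complex),
            noise_sd=0.0,
        )
        img = simulate_phantom(scene, bolus, g)
        expected_p, expected_l = simulate_two_site_exchange(params, bolus, g)
        np.testing.assert_allclose(img.data[0, 0, :, 0, 3, 3].real, expected_p,
                                   rtol=1e-10)
        np.testing.assert_allclose(img.data[1, 0, :, 0, 5, 5].real, expected_l,
                                   rtol=1e-10)

    def test_seeded_determinism(self, small_geometry, bolus):
        scene = make_phantom_scene(small_geometry, KineticModelParams(0.0065),
                                   noise_sd=0.3, seed=42)
        a = simulate_phantom(scene, bolus, small_geometry)
        b = simulate_phantom(scene, bolus, small_geometry)
        assert np.array_equal(a.data, b.data)

    def test_background_magnitude_is_rayleigh(self, bolus):
        # single-frame magnitudes in empty voxels: mean = sigma*sqrt(pi/2)
        g = AcquisitionGeometry(acq_matrix=(64, 64), recon_matrix=(64, 64),
                                n_slices=2, n_coils=1, n_frames=4)
        sigma = 0.7
        label = np.zeros((2, 64, 64), dtype=np.int16)
        label[:, 30:34, 30:34] = 1
        scene = PhantomScene(
            label_map=label,
            region_params={1: RegionSpec(KineticModelParams(0.005))},
            coil_sens=np.ones((1, 64, 64), dtype=complex),
            noise_sd=sigma, seed=9,
        )
        img = simulate_phantom(scene, bolus, g)
        bg = label == 0
        mags = np.abs(img.data[0, 0][:, bg])
        assert mags.size >= 10_000
        assert mags.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)

    def test_shape_mismatch_raises(self, small_geometry, bolus):
        scene = make_phantom_scene(small_geometry, KineticModelParams(0.0065))
        other = AcquisitionGeometry(acq_matrix=(8, 8), recon_matrix=(8, 8),
                                    n_slices=1, n_coils=2)
        with pytest.raises(ValueError):
            simulate_phantom(scene, bolus, other)


class TestIHCGeneration:
    def test_zero_fractions_zero_positive(self):
        img = generate_ihc_image({}, nuclei_count=10, seed=1)
        res = ihc_quant.quantify_image(img.rgb)
        assert res.percent_positive == 0.0

    def test_forty_percent_positive_recovered(self):
        img = generate_ihc_image({"weak": 0.30, "moderate": 0.10}, seed=2,
                                 nuclei_count=0)
        assert img.percent_positive_truth == pytest.approx(40.0, abs=0.2)
        res = ihc_quant.quantify_image(img.rgb)
        assert res.percent_positive == pytest.approx(40.0, abs=1.0)

    def test_seeded_determinism(self):
        a = generate_ihc_image({"weak": 0.2}, seed=7)
        b = generate_ihc_image({"weak": 0.2}, seed=7)
        assert np.array_equal(a.rgb, b.rgb)
        assert a.nucleus_count == b.nucleus_count

    def test_fractions_above_one_rejected(self):
        with pytest.raises(ValueError):
            generate_ihc_image({"weak": 0.7, "strong": 0.4})

    def test_painted_od_strictly_inside_class_interval(self):
        # after 8-bit rendering, re-derived DAB OD of each painted pixel
        # must stay strictly inside its class's interval
        img = generate_ihc_image({"weak": 0.2, "moderate": 0.2, "strong": 0.2},
                                 seed=3)
        od = ihc_quant.rgb_to_od(img.rgb)
        _, dab = ihc_quant.deconvolve_stains(od)
        thr = ihc_quant.StainClassifier().od_thresholds
        lo = {"weak": thr["weak"], "moderate": thr["moderate"],
              "strong": thr["strong"]}
        hi = {"weak": thr["moderate"], "moderate": thr["strong"],
              "strong": np.inf}
        for name, mask in img.class_masks.items():
            vals = dab[mask]
            assert vals.min() > lo[name]
            assert vals.max() < hi[name]

    def test_nucleus_count_matches_truth(self):
        img = generate_ihc_image({"weak": 0.1}, nuclei_count=30, seed=4)
        res = ihc_quant.quantify_image(img.rgb)
        assert res.cell_count == img.nucleus_count == 30


@pytest.fixture(scope="module")
def cohort(small_geometry):
    return generate_cohort(n_patients=6, seed=11, geometry=small_geometry)


class TestCohort:
    def test_biopsies_inside_tumor(self, cohort):
        for p in cohort.patients:
            tumor_labels = set(p.scene.meta["tumor_labels"])
            for b in p.biopsies:
                s, r, c = b.location
                assert int(p.scene.label_map[s, r, c]) in tumor_labels

    def test_grade_kpl_monotone_in_expectation(self, small_geometry):
        # noiseless link: patient kPL strictly ordered by grade
        from hp13c.synthetic_data import GradeKplLink

        cohort = generate_cohort(
            n_patients=6, seed=5, geometry=small_geometry,
            grade_kpl_link=GradeKplLink(noise_cv=0.0),
        )
        by_grade = {}
        for p in cohort.patients:
            by_grade.setdefault(p.grade, set()).add(round(p.true_median_kpl, 9))
        grades = sorted(by_grade)
        for g1, g2 in zip(grades, grades[1:]):
            assert max(by_grade[g1]) < min(by_grade[g2])

    def test_determinism(self, small_geometry):
        a = generate_cohort(n_patients=4, seed=3, geometry=small_geometry)
        b = generate_cohort(n_patients=4, seed=3, geometry=small_geometry)
        assert a.biopsy_table().equals(b.biopsy_table())

    def test_too_few_patients_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            generate_cohort(n_patients=2, geometry=small_geometry)

    def test_biopsy_table_schema(self, cohort):
        df = cohort.biopsy_table()
        for col in ("patient_id", "biopsy_id", "slice", "row", "col", "grade",
                    "kpl", "mct1_pct", "mct4_pct", "cell_density",
                    "viable_fraction"):
            assert col in df.columns
        assert (df["viable_fraction"] <= 1).all()
        assert (df["kpl"] > 0).all()


class TestPhantomIO:
    def test_nifti_roundtrip(self, bolus, tmp_path):
        from hp13c.synthetic_data import load_phantom, save_phantom

        g = AcquisitionGeometry(acq_matrix=(8, 8), recon_matrix=(8, 8),
                                n_slices=1, n_coils=2, n_frames=4)
        scene = make_phantom_scene(g, KineticModelParams(0.01), noise_sd=0.1,
                                   seed=2)
        img = simulate_phantom(scene, bolus, g)
        save_phantom(img, tmp_path, scene=scene)
        back = load_phantom(tmp_path)
        np.testing.assert_allclose(back.data, img.data, rtol=1e-6, atol=1e-6)
        assert back.geometry == g
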