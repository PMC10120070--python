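"""Wing DoP photometry, trend fits, spectra, and tetrahedral colour space."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ommapol import synthgen
from ommapol.wingoptics import (
    PolarizationImagePair,
    QuantumCatch,
    ReflectanceSpectrum,
    ViewingGeometry,
    color_distance,
    compute_dop,
    dop_sweep,
    fit_dop_trend,
    image_pair_dop,
    quantum_catches,
    spectral_peak,
    tetra_coordinates,
)


class TestComputeDop:
    @pytest.mark.parametrize(
        "h, v, expected", [(1.0, 1.0, 0.0), (2.0, 1.0, 1 / 3), (1.0, 0.0, 1.0)]
    )
    def test_printed_formula(self, h, v, expected):
        assert compute_dop(h, v) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_dop(0.0, 0.0)

    @given(h=st.floats(0, 1e6), v=st.floats(0, 1e6),
           c=st.floats(1e-3, 1e3))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_scale_invariant(self, h, v, c):
        if h + v < 1e-6:  # guard against zero totals and underflow
            return
        d = compute_dop(h, v)
        assert 0.0 <= d <= 1.0
        assert compute_dop(c * h, c * v) == pytest.approx(d, abs=1e-9)


class TestImagePairDop:
    def test_round_trip_with_generator(self):
        i_h, i_v = synthgen.generate_polarization_image_pair(0.5)
        dop, dominant = image_pair_dop(PolarizationImagePair(i_h, i_v))
        assert dop == 0.5
        assert dominant == "H"

    def test_vertical_dominance_labelled(self):
        i_h, i_v = synthgen.generate_polarization_image_pair(0.4)
        dop, dominant = image_pair_dop(PolarizationImagePair(i_v, i_h))
        assert dominant == "V"

    def test_mask_restricts_photometry(self):
        i_h = np.ones((10, 10))
        i_v = np.zeros((10, 10))
        i_v[:5] = 1.0  # masked-out half is unpolarized
        mask = np.zeros((10, 10), bool)
        mask[5:] = True
        dop, _ = image_pair_dop(PolarizationImagePair(i_h, i_v, mask))
        assert dop == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        pair = PolarizationImagePair(
            np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), bool)
        )
        with pytest.raises(ValueError, match="mask"):
            image_pair_dop(pair)

    def test_noisy_estimate_unbiased_within_propagated_error(self):
        # Monte-Carlo oracle: mean estimate over 100 seeds within
        # 3 * SE/sqrt(100) of the generating DoP
        truth, total, noise_sd, shape = 0.5, 1000.0, 50.0, (64, 64)
        ests = []
        for seed in range(100):
            i_h, i_v = synthgen.generate_polarization_image_pair(
                truth, total, shape, noise_sd=noise_sd, seed=seed
            )
            ests.append(image_pair_dop(PolarizationImagePair(i_h, i_v))[0])
        n_pix = shape[0] * shape[1]
        mean_h = total * (1 + truth) / 2
        mean_v = total * (1 - truth) / 2
        se = (2.0 / (total**2)) * np.hypot(mean_v, mean_h) * (
            noise_sd / np.sqrt(n_pix)
        )
        assert abs(np.mean(ests) - truth) < 3.0 * se / np.sqrt(100) + 1e-12


class TestDopSweep:
    def test_geometry_arithmetic(self):
        assert ViewingGeometry(60.0, 70.0).angular_contrast_deg == 130.0
        assert ViewingGeometry(0.0, 10.0).angular_contrast_deg == 10.0

    def test_acquisition_constraint_enforced(self):
        with pytest.raises(ValueError):
            ViewingGeometry(70.0, 60.0)

    def test_row_count_matches_combinatorial_enumeration(self):
        thetas = range(-60, 71, 10)
        phis = range(10, 71, 10)
        valid = [(t, p) for t, p in itertools.product(thetas, phis)
                 if abs(t) < p]
        pairs = {}
        for t, p in valid:
            i_h, i_v = synthgen.generate_polarization_image_pair(
                0.3, shape=(8, 8), seed=(t + 100) * 100 + p
            )
            pairs[ViewingGeometry(float(t), float(p))] = (
                PolarizationImagePair(i_h, i_v)
            )
        sweep = dop_sweep(pairs)
        assert len(sweep) == len(valid)
        np.testing.assert_allclose(
            sweep.angular_contrast_deg,
            sweep.theta_inc_deg + sweep.phi_det_deg,
        )

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            dop_sweep({})


def synthetic_sweep(coeffs):
    """Sweep table whose DoP is an exact polynomial of angular contrast."""
    contrasts = np.arange(20.0, 141.0, 10.0)
    dop = np.polyval(coeffs, (contrasts - 80.0) / 60.0)
    return pd.DataFrame({
        "theta_inc_deg": 0.0,
        "phi_det_deg": contrasts,
        "angular_contrast_deg": contrasts,
        "dop": dop,
    })


class TestFitDopTrend:
    def test_exact_quadratic_recovered_with_zero_residual(self):
        sweep = synthetic_sweep([0.3, 0.1, 0.4])
        res = fit_dop_trend(sweep, order=2)
        assert res.ssr == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(
            res.fittedvalues, sweep["dop"], atol=1e-10
        )

    def test_cubic_truth_fits_better_at_order_3(self):
        sweep = synthetic_sweep([0.2, -0.3, 0.1, 0.4])
        r2 = fit_dop_trend(sweep, order=2)
        r3 = fit_dop_trend(sweep, order=3)
        assert r3.ssr < r2.ssr

    def test_constant_data_gives_zero_polynomial_terms(self):
        sweep = synthetic_sweep([0.25])
        res = fit_dop_trend(sweep, order=2)
        np.testing.assert_allclose(res.params[1:], 0.0, atol=1e-10)

    def test_too_few_rows_rejected(self):
        sweep = synthetic_sweep([0.25]).head(3)
        with pytest.raises(ValueError):
            fit_dop_trend(sweep, order=2)


class TestSpectralPeak:
    def test_boundary_peak_flagged(self):
        spec = ReflectanceSpectrum(
            wavelengths_nm=np.arange(350.0, 701.0),
            reflectance=np.linspace(0.0, 1.0, 351),
        )
        peak = spectral_peak(spec)
        assert peak.on_boundary
        assert peak.wavelength_nm == 700.0

    def test_tie_resolves_to_smallest_wavelength(self):
        rf = np.zeros(351)
        rf[[100, 200]] = 1.0
        spec = ReflectanceSpectrum(np.arange(350.0, 701.0), rf)
        peak = spectral_peak(spec)
        assert peak.tie
        assert peak.wavelength_nm == 450.0

    def test_constant_spectrum_rejected(self):
        spec = ReflectanceSpectrum(np.arange(350.0, 701.0), np.full(351, 0.5))
        with pytest.raises(ValueError):
            spectral_peak(spec)


class TestQuantumCatches:
    def test_flat_reflectance_with_symmetric_curves_gives_equal_catches(self):
        # four identical Gaussians far from the range edges see the same
        # flat reflectance
        sens = synthgen.generate_sensitivity_templates(
            (460.0, 500.0, 540.0, 580.0), fwhm_nm=30.0
        )
        spec = ReflectanceSpectrum(
            np.arange(350.0, 701.0), np.full(351, 0.5)
        )
        catch = quantum_catches(spec, sens)
        np.testing.assert_allclose(catch.relative, 0.25, atol=1e-6)

    def test_reflectance_matching_one_curve_dominates(self):
        sens = synthgen.generate_sensitivity_templates(
            (380.0, 460.0, 540.0, 650.0), fwhm_nm=20.0
        )
        spec = ReflectanceSpectrum(
            sens["wavelength_nm"].to_numpy(), sens["m"].to_numpy()
        )
        catch = quantum_catches(spec, sens)
        assert catch.relative[2] > 0.9

    def test_numeric_integral_matches_gaussian_overlap_formula(self):
        # closed-form Gaussian x Gaussian overlap integral, peaks well
        # inside the truncation range
        fwhm_r, fwhm_s = 60.0, 40.0
        mu_r, mu_s = 520.0, 540.0
        spec_frame = synthgen.generate_reflectance_spectrum(
            mu_r, fwhm_nm=fwhm_r, amplitude=1.0, pedestal=0.0
        )
        sens = synthgen.generate_sensitivity_templates(
            (360.0, 450.0, mu_s, 680.0), fwhm_nm=fwhm_s
        )
        catch = quantum_catches(
            ReflectanceSpectrum.from_frame(spec_frame), sens
        )
        s1 = fwhm_r / np.sqrt(8 * np.log(2))
        s2 = fwhm_s / np.sqrt(8 * np.log(2))
        expected = np.sqrt(
            2 * np.pi * s1**2 * s2**2 / (s1**2 + s2**2)
        ) * np.exp(-((mu_r - mu_s) ** 2) / (2 * (s1**2 + s2**2)))
        assert catch.m == pytest.approx(expected, rel=0.005)

    def test_all_zero_catches_rejected(self):
        with pytest.raises(ValueError):
            QuantumCatch(0.0, 0.0, 0.0, 0.0)


class TestTetraColorSpace:
    def test_achromatic_centre(self):
        xyz = tetra_coordinates(QuantumCatch(0.25, 0.25, 0.25, 0.25))
        np.testing.assert_allclose(xyz, 0.0, atol=1e-12)

    @pytest.mark.parametrize("idx, name", list(enumerate("usml")))
    def test_pure_catch_maps_to_vertex_at_three_quarters(self, idx, name):
        raw = [0.0] * 4
        raw[idx] = 1.0
        xyz = tetra_coordinates(QuantumCatch(*raw))
        assert np.linalg.norm(xyz) == pytest.approx(0.75, abs=1e-12)

    def test_vertices_are_a_regular_tetrahedron(self):
        pts = [tetra_coordinates(QuantumCatch(*(1.0 if i == j else 0.0
                                                for j in range(4))))
               for i in range(4)]
        dists = [np.linalg.norm(a - b)
                 for a, b in itertools.combinations(pts, 2)]
        np.testing.assert_allclose(dists, dists[0], atol=1e-12)

    def test_distance_symmetric_zero_iff_equal(self):
        a = QuantumCatch(0.4, 0.3, 0.2, 0.1)
        b = QuantumCatch(0.1, 0.2, 0.3, 0.4)
        assert color_distance(a, b) == pytest.approx(color_distance(b, a))
        assert color_distance(a, a) == 0.0
        assert color_distance(a, b) > 0.0

    def test_distance_invariant_to_flat_reflectance_scaling(self):
        a = QuantumCatch(0.4, 0.3, 0.2, 0.1)
        a_scaled = QuantumCatch(0.8, 0.6, 0.4, 0.2)
        b = QuantumCatch(0.1, 0.2, 0.3, 0.4)
        assert color_distance(a_scaled, b) == pytest.approx(
            color_distance(a, b)
        )

    def test_triangle_inequality_on_random_catches(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c = (QuantumCatch(*rng.uniform(0.01, 1.0, 4))
                       for _ in range(3))
            assert color_distance(a, c) <= (
                color_distance(a, b) + color_distance(b, c) + 1e-12
            )
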