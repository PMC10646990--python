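import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import quad
from scipy.special import j1

from conftest import py_hard_sphere_sq
from stackmap.sans_model import (
    SANSModelParams,
    StagedFitConfig,
    StageFitError,
    charged_structure_factor,
    composite_intensity,
    elliptical_cylinder_form_factor,
    model_terms,
    stack_metrics,
    staged_fit,
)
from stackmap.synthetic_data import REFERENCE_SANS_PARAMS, synth_sans_curve


def circular_cylinder_pq(q, radius, length):
    """Independent adaptive-quadrature oracle for the circular cylinder."""

    def kernel(alpha):
        a = q * radius * np.sin(alpha)
        b = q * length / 2 * np.cos(alpha)
        radial = 2 * j1(a) / a if a > 1e-12 else 1.0
        axial = np.sin(b) / b if abs(b) > 1e-12 else 1.0
        return (radial * axial) ** 2 * np.sin(alpha)

    val, _ = quad(kernel, 0, np.pi / 2, limit=400)
    return val


def mc_orientation_average(q, length, r_minor, r_major, n=1_000_000, seed=11):
    """Monte Carlo orientational average of the elliptical-cylinder kernel."""
    rng = np.random.default_rng(seed)
    cos_a = rng.uniform(0.0, 1.0, n)
    sin_a = np.sqrt(1 - cos_a**2)
    psi = rng.uniform(0.0, 2 * np.pi, n)
    r_psi = np.sqrt((r_minor * np.sin(psi)) ** 2 + (r_major * np.cos(psi)) ** 2)
    a = q * sin_a * r_psi
    b = q * cos_a * length / 2
    radial = np.where(a > 1e-12, 2 * j1(a) / np.where(a > 1e-12, a, 1), 1.0)
    axial = np.where(np.abs(b) > 1e-12, np.sin(b) / np.where(np.abs(b) > 1e-12, b, 1), 1.0)
    f2 = (radial * axial) ** 2
    return f2.mean(), f2.std(ddof=1) / np.sqrt(n)


class TestFormFactor:
    def test_normalised_at_zero(self):
        p = elliptical_cylinder_form_factor(np.array([0.0, 1e-5]), 60, 6.5, 12.6)
        assert p[0] == pytest.approx(1.0, abs=1e-10)
        assert p[1] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("q", [0.05, 0.2, 1.0])
    def test_matches_circular_closed_form_when_radii_equal(self, q):
        mine = elliptical_cylinder_form_factor(q, 60.0, 8.0, 8.0, order=(256, 8))
        oracle = circular_cylinder_pq(q, 8.0, 60.0)
        assert mine == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("q", [0.05, 0.2, 1.0])
    def test_matches_monte_carlo_average(self, q):
        length, r_min, r_maj = 47.0, 5.1, 14.8
        mine = elliptical_cylinder_form_factor(q, length, r_min, r_maj, order=(128, 64))
        mc, se = mc_orientation_average(q, length, r_min, r_maj)
        assert abs(mine - mc) < 3 * se

    def test_bounded_and_guinier_monotone(self):
        q = np.geomspace(1e-4, 0.02, 60)
        p = elliptical_cylinder_form_factor(q, 60, 6.5, 12.6)
        assert np.all(p > 0) and np.all(p <= 1 + 1e-12)
        assert np.all(np.diff(p) < 0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            elliptical_cylinder_form_factor(0.1, 60, 10.0, 5.0)


class TestStructureFactor:
    def test_uncharged_equals_percus_yevick(self):
        sigma = 30.0
        q = np.linspace(0.02, 0.8, 50)
        for phi in (0.1, 0.2, 0.3):
            mine = charged_structure_factor(q, phi, 0.0, sigma)
            oracle = py_hard_sphere_sq(q * sigma, phi)
            assert np.max(np.abs(mine / oracle - 1)) < 1e-3

    def test_dilute_limit_is_unity(self):
        q = np.linspace(0.02, 1.0, 20)
        s = charged_structure_factor(q, 1e-6, -14.0, 30.9)
        np.testing.assert_allclose(s, 1.0, atol=1e-3)

    def test_high_q_limit_is_unity(self):
        q = np.array([55.0 / 30.9, 70.0 / 30.9])  # q·σ > 50
        s = charged_structure_factor(q, 0.11, -14.0, 30.9)
        np.testing.assert_allclose(s, 1.0, atol=1e-2)

    def test_charge_suppresses_low_q(self):
        q = np.array([0.05])
        charged = charged_structure_factor(q, 0.11, -14.0, 30.9)[0]
        neutral = charged_structure_factor(q, 0.11, 0.0, 30.9)[0]
        assert charged < neutral

    def test_positive_everywhere(self):
        q = np.geomspace(0.005, 3.0, 80)
        s = charged_structure_factor(q, 0.11, -14.0, 30.9)
        assert np.all(s > 0)


class TestCompositeModel:
    def test_background_only(self):
        p = replace(REFERENCE_SANS_PARAMS, phi=1e-9, gauss_ip_amp=0, gauss_is_amp=0,
                    powerlaw_amp=0, background=0.042, scale=0.0)
        q = np.geomspace(0.01, 1, 20)
        np.testing.assert_allclose(composite_intensity(q, p).intensity, 0.042)

    def test_pure_power_law_value(self):
        p = replace(REFERENCE_SANS_PARAMS, gauss_ip_amp=0, gauss_is_amp=0,
                    powerlaw_amp=1.0, powerlaw_exp=3.0, background=0.0, scale=0.0)
        q = np.array([0.1, 0.2])
        out = composite_intensity(q, p).intensity
        assert out[0] == pytest.approx(1000.0)

    def test_sum_of_terms_is_exact(self):
        q = np.geomspace(0.003, 3, 60)
        terms = model_terms(q, REFERENCE_SANS_PARAMS)
        total = composite_intensity(q, REFERENCE_SANS_PARAMS).intensity
        # the structure-factor solver is iterative (warm-started), so repeated
        # evaluations agree to solver precision rather than bit-for-bit
        np.testing.assert_allclose(sum(terms.values()), total, rtol=1e-12)

    def test_reference_curve_shape(self):
        """Two stacking peaks near 1 Å⁻¹ and a repulsion inflection near 0.1 Å⁻¹."""
        q = np.geomspace(0.003, 3, 500)
        i = composite_intensity(q, REFERENCE_SANS_PARAMS).intensity
        mid = (q > 0.5) & (q < 2.0)
        iv = i[mid]
        interior = np.flatnonzero((iv[1:-1] > iv[:-2]) & (iv[1:-1] > iv[2:])) + 1
        peaks = q[mid][interior]
        assert len(peaks) == 2
        assert 0.6 < peaks[0] < 0.9 and 1.2 < peaks[1] < 1.6
        # inflection: log-log slope has a local extremum around Q ~ 0.1
        window = (q > 0.04) & (q < 0.25)
        slope = np.gradient(np.log(i[window]), np.log(q[window]))
        assert slope.min() < -0.2 and slope[-1] > slope.min()

    def test_discharging_raises_low_q(self):
        charged = REFERENCE_SANS_PARAMS
        neutral = replace(charged, charge=0.0, phi=0.02,
                          scale=charged.effective_scale)
        q = np.array([0.05])
        assert (
            composite_intensity(q, neutral).intensity[0]
            > composite_intensity(q, charged).intensity[0]
        )


class TestStagedFit:
    def test_noiseless_self_consistency(self):
        """With polish on, a noiseless model curve is recovered essentially exactly."""
        q = np.geomspace(0.003, 3.0, 150)
        truth = REFERENCE_SANS_PARAMS
        curve = synth_sans_curve(truth, q, 0.0, seed=0)
        cfg = StagedFitConfig(polish=True)
        result = staged_fit(curve, replace(truth), cfg)
        p = result.params
        for name in ("length", "r_minor", "r_major", "q_ip", "q_is", "powerlaw_exp"):
            assert getattr(p, name) == pytest.approx(getattr(truth, name), rel=1e-3), name
        assert p.effective_scale == pytest.approx(truth.effective_scale, rel=5e-3)

    def test_single_noisy_fit_within_quoted_uncertainties(self):
        q = np.geomspace(0.003, 3.0, 400)
        curve = synth_sans_curve(REFERENCE_SANS_PARAMS, q, 0.01, seed=42)
        init = replace(REFERENCE_SANS_PARAMS,
                       length=70.0, r_minor=5.5, r_major=14.5, charge=-10.0)
        result = staged_fit(curve, init)
        p = result.params
        assert p.length == pytest.approx(60.0, abs=10.0)
        assert p.r_minor == pytest.approx(6.5, abs=0.6)
        assert p.r_major == pytest.approx(12.6, abs=0.8)
        assert result.uncertainties["length"] > 0
        assert result.stage_chi2["cylinder"] > 0

    def test_missing_low_q_raises_from_powerlaw_stage(self):
        q = np.geomspace(0.02, 3.0, 100)
        curve = synth_sans_curve(REFERENCE_SANS_PARAMS, q, 0.0, seed=0)
        with pytest.raises(StageFitError, match="powerlaw"):
            staged_fit(curve, REFERENCE_SANS_PARAMS)


class TestStackMetrics:
    def test_reference_geometry(self):
        p = replace(REFERENCE_SANS_PARAMS, length=60.0, r_minor=6.5, r_major=12.6,
                    q_ip=2 * np.pi / 8.5, q_is=2 * np.pi / 4.5)
        m = stack_metrics(p, per_monomer_charge=-2.0)
        assert m.n_units == 7
        assert round(m.aspect_ratio, 2) == pytest.approx(1.94)
        assert m.total_charge == pytest.approx(-14.0)
        assert m.d_ip == pytest.approx(8.5)
        assert m.d_is == pytest.approx(4.5)

    def test_swapped_peaks_warn_and_relabel(self):
        p = replace(REFERENCE_SANS_PARAMS, q_ip=2 * np.pi / 4.5, q_is=2 * np.pi / 8.5)
        with pytest.warns(UserWarning, match="swap"):
            m = stack_metrics(p, -2.0)
        assert m.d_ip > m.d_is

    def test_validation(self):
        with pytest.raises(ValueError):
            SANSModelParams(phi=0.9)
        with pytest.raises(ValueError):
            SANSModelParams(r_minor=10.0, r_major=5.0)
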