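"""Fourier phase-stepping retrieval and phase integration."""

import numpy as np
import pytest

from xpci.constants import wavenumber_from_energy
from xpci.materials import compute_delta, get_material
from xpci.retrieval import (
    extract_contrasts,
    fourier_coefficients,
    integrate_phase,
    refraction_angle,
    unwrap_despike,
    wrap_phase,
)


class TestFourierCoefficients:
    @pytest.mark.parametrize("m", range(3, 13))
    def test_exact_for_pure_first_harmonic(self, m, rng):
        """Exact (machine precision) recovery for any harmonic-0/1 curve."""
        a0, a1, phi = 2.0, 1.0, 0.7
        steps = np.arange(m)
        curve = a0 + a1 * np.cos(2 * np.pi * steps / m + phi)
        ra0, ra1, rphi = fourier_coefficients(curve)
        assert ra0 == pytest.approx(a0, abs=1e-12)
        assert ra1 == pytest.approx(a1, abs=1e-12)
        assert wrap_phase(rphi - phi) == pytest.approx(0.0, abs=1e-12)

    def test_constant_curve(self):
        a0, a1, _ = fourier_coefficients(np.full(5, 5.0))
        assert a0 == 5.0
        assert a1 == pytest.approx(0.0, abs=1e-14)

    def test_phase_wraps_into_interval(self, rng):
        for phi in rng.uniform(-10, 10, 20):
            m = 7
            curve = 1 + 0.5 * np.cos(2 * np.pi * np.arange(m) / m + phi)
            _, _, rphi = fourier_coefficients(curve)
            assert -np.pi < rphi <= np.pi

    def test_step_validation(self):
        with pytest.raises(ValueError):
            fourier_coefficients(np.ones(2))
        with pytest.raises(ValueError):
            fourier_coefficients(np.ones(5), steps=np.array([0, 1, 2, 3, 5.0]))


class TestExtractContrasts:
    def test_identical_curves(self):
        m = np.arange(5)
        ref = 2 + np.cos(2 * np.pi * m / 5)
        c = extract_contrasts(ref, ref)
        assert c.transmission == pytest.approx(1.0)
        assert c.dphi == pytest.approx(0.0, abs=1e-12)
        assert c.darkfield == pytest.approx(1.0)

    def test_pure_scaling(self):
        m = np.arange(5)
        ref = 2 + np.cos(2 * np.pi * m / 5)
        c = extract_contrasts(0.5 * ref, ref)
        assert c.transmission == pytest.approx(0.5)
        assert c.dphi == pytest.approx(0.0, abs=1e-12)
        assert c.darkfield == pytest.approx(1.0)

    def test_mixed_example(self):
        m = np.arange(6)
        th = 2 * np.pi * m / 6
        ref = 2 + np.cos(th)
        sam = 1.6 + 0.6 * np.cos(th + 0.3)
        c = extract_contrasts(sam, ref)
        assert c.transmission == pytest.approx(0.8, abs=1e-12)
        assert c.dphi == pytest.approx(0.3, abs=1e-12)
        assert c.darkfield == pytest.approx(0.75, abs=1e-12)

    def test_common_scale_invariance(self, rng):
        m = np.arange(5)
        ref = 2 + 0.8 * np.cos(2 * np.pi * m / 5)
        sam = 1.5 + 0.5 * np.cos(2 * np.pi * m / 5 + 0.4)
        a = extract_contrasts(sam, ref)
        b = extract_contrasts(7.3 * sam, 7.3 * ref)
        assert b.transmission == pytest.approx(a.transmission, rel=1e-12)
        assert b.dphi == pytest.approx(a.dphi, abs=1e-12)
        assert b.darkfield == pytest.approx(a.darkfield, rel=1e-12)

    def test_invalid_reference_flagged_not_nan(self):
        sam = np.stack([2 + np.cos(2 * np.pi * np.arange(5) / 5),
                        2 + np.cos(2 * np.pi * np.arange(5) / 5)])
        ref = sam.copy()
        ref[1] = 0.0  # dead reference pixel
        c = extract_contrasts(sam, ref)
        assert c.valid[0] and not c.valid[1]
        assert np.all(np.isfinite(c.transmission))
        assert np.all(np.isfinite(c.darkfield))


class TestRefractionAngle:
    def test_values(self):
        assert refraction_angle(0.0, 2e-6, 0.121) == 0.0
        assert refraction_angle(np.pi, 2e-6, 0.121) == pytest.approx(8.26e-6,
                                                                     rel=1e-3)
        assert refraction_angle(0.4, 2e-6, 0.121) == \
            pytest.approx(2 * refraction_angle(0.2, 2e-6, 0.121), rel=1e-12)
        with pytest.raises(ValueError):
            refraction_angle(0.1, 2e-6, 0.0)


class TestUnwrapDespike:
    def test_isolated_aliased_pixel_restored(self):
        true = np.array([0.0, 0.1, 0.5, 3.5, 1.7, 1.2, 0.8])
        wrapped = wrap_phase(true)
        fixed = unwrap_despike(wrapped)
        np.testing.assert_allclose(fixed, true, atol=1e-12)

    def test_noise_untouched(self, rng):
        noisy = rng.normal(0, 0.3, 100)
        np.testing.assert_array_equal(unwrap_despike(noisy), noisy)


class TestIntegratePhase:
    def test_zero_alpha_zero_phase(self):
        phi = integrate_phase(np.zeros(50), 2e-6, 0.121,
                              wavenumber_from_energy(25.0), 8e-6, margin=5)
        np.testing.assert_array_equal(phi, 0.0)

    def test_constant_alpha_linear_ramp(self):
        k = wavenumber_from_energy(25.0)
        dphi = np.full(100, 0.2)
        pw = 8e-6
        phi = integrate_phase(dphi, 2e-6, 0.121, k, pw)
        alpha = -refraction_angle(0.2, 2e-6, 0.121)
        slope = np.diff(phi)
        np.testing.assert_allclose(slope, k * alpha * pw, rtol=1e-12)

    def test_both_margin_anchor_closes(self):
        k = wavenumber_from_energy(25.0)
        dphi = np.concatenate([np.zeros(10), np.full(30, 0.5),
                               np.full(30, -0.5), np.zeros(10)])
        phi = integrate_phase(dphi, 2e-6, 0.121, k, 8e-6, margin=8,
                              anchor="both")
        assert abs(phi[:8].mean()) < 1e-10
        assert abs(phi[-8:].mean()) < 1e-10


def test_wedge_contrast_separation():
    """End-to-end GI on a pure-phase wedge: T ~ 1 and D ~ 1 while the
    fringe shift matches the prism deviation delta * slope within 5%."""
    from xpci.transition import ComplexWavefront
    from xpci.waveoptics import (GratingSpec, SteppingConfig,
                                 apply_phase_grating, fresnel_propagate,
                                 lohmann_distance, phase_stepping_scan)
    from xpci.constants import wavelength_from_energy

    e = 25.0
    lam = wavelength_from_energy(e)
    k = wavenumber_from_energy(e)
    p1, dx = 4e-6, 0.25e-6
    p2 = p1 / 2
    d = lohmann_distance(2, p1, lam)
    n = 8192
    x = np.arange(n) * dx + dx / 2
    delta = compute_delta(get_material("water"), e)
    slope = 0.05
    t = np.clip(x - 0.2e-3, 0, None) * slope
    wf = ComplexWavefront(np.exp(-1j * k * delta * t), dx, 0.0, e)
    ref = ComplexWavefront(np.ones(n, complex), dx, 0.0, e)
    g1 = GratingSpec(p1, "phase")
    g2 = GratingSpec(p2, "absorption")
    cfg = SteppingConfig(5, 8e-6, n // 32)
    scan_s = phase_stepping_scan(
        fresnel_propagate(apply_phase_grating(wf, g1), d, guard=0.25), g2, cfg)
    scan_r = phase_stepping_scan(
        fresnel_propagate(apply_phase_grating(ref, g1), d, guard=0.25), g2, cfg)
    c = extract_contrasts(scan_s, scan_r)
    inside = slice(n // 64, n // 32 * 3 // 4)
    assert c.transmission[inside].mean() == pytest.approx(1.0, abs=0.02)
    assert c.darkfield[inside].mean() == pytest.approx(1.0, abs=0.05)
    assert np.abs(c.dphi[inside]).min() > 0
    alpha = refraction_angle(c.dphi[inside].mean(), p2, d)
    assert abs(alpha) == pytest.approx(delta * slope, rel=0.05)
    # integrated phase reproduces -k delta t(x)
    phi = integrate_phase(unwrap_despike(c.dphi), p2, d, k, 8e-6, margin=10)
    xp = (np.arange(n // 32) + 0.5) * 8e-6
    phi_true = -k * delta * np.clip(xp - 0.2e-3, 0, None) * slope
    sel = slice(40, 180)
    np.testing.assert_allclose(phi[sel], phi_true[sel],
                               rtol=0.05, atol=0.3)
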