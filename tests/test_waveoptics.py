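"""Wave optics: Fresnel propagation, gratings, Talbot physics, PA model."""

import numpy as np
import pytest

from xpci.constants import wavelength_from_energy, wavenumber_from_energy
from xpci.materials import compute_delta, compute_mu, get_material
from xpci.phantoms import build_hollow_cylinder_phantom
from xpci.sources import SourceSpec
from xpci.transition import ComplexWavefront, split_phase_space
from xpci.transport import TransportConfig, run_histories
from xpci.waveoptics import (
    GratingSpec,
    SteppingConfig,
    apply_absorption_grating,
    apply_phase_grating,
    fresnel_propagate,
    fringe_visibility,
    intensity,
    lohmann_distance,
    pa_transmission,
    phase_stepping_scan,
)

E = 25.0
LAM = wavelength_from_energy(E)


def plane_wave(n=4096, dx=0.25e-6):
    return ComplexWavefront(np.ones(n, complex), dx, 0.0, E)


class TestFresnel:
    def test_plane_wave_eigenfunction(self):
        w = fresnel_propagate(plane_wave(), 0.1)
        np.testing.assert_allclose(w.amplitude, 1.0, atol=1e-12)

    def test_unitarity(self, rng):
        w = plane_wave()
        w.amplitude *= np.exp(1j * rng.uniform(0, 2 * np.pi, w.n))
        w.amplitude *= rng.uniform(0.5, 1.5, w.n)
        out = fresnel_propagate(w, 0.05)
        assert np.sum(np.abs(out.amplitude) ** 2) == pytest.approx(
            np.sum(np.abs(w.amplitude) ** 2), rel=1e-12)

    def test_composition_law(self, rng):
        w = plane_wave(2048)
        w.amplitude = np.exp(-(w.x - w.x.mean()) ** 2 / (20e-6) ** 2).astype(complex)
        a = fresnel_propagate(fresnel_propagate(w, 0.03), 0.07)
        b = fresnel_propagate(w, 0.10)
        np.testing.assert_allclose(a.amplitude, b.amplitude, atol=1e-10)

    def test_identity_at_zero(self):
        w = plane_wave(64)
        out = fresnel_propagate(w, 0.0)
        np.testing.assert_array_equal(out.amplitude, w.amplitude)

    def test_gaussian_waist_growth(self):
        w0 = 10e-6
        n, dx = 8192, 0.25e-6
        x = (np.arange(n) - n / 2) * dx
        w = ComplexWavefront(np.exp(-(x / w0) ** 2).astype(complex), dx, 0.0, E)
        d = 3.0
        out = fresnel_propagate(w, d)
        inten = np.abs(out.amplitude) ** 2
        w_meas = 2 * np.sqrt(np.sum(x**2 * inten) / np.sum(inten))
        w_theory = w0 * np.sqrt(1 + (LAM * d / (np.pi * w0**2)) ** 2)
        assert w_meas == pytest.approx(w_theory, rel=1e-3)

    def test_aliasing_guard_names_limits(self):
        w = plane_wave(256, dx=0.1e-6)
        with pytest.raises(ValueError, match="samples"):
            fresnel_propagate(w, 1.0)
        with pytest.raises(ValueError):
            fresnel_propagate(w, -0.1)


class TestIntensity:
    def test_trivials(self):
        w = plane_wave(16)
        np.testing.assert_array_equal(intensity(w), np.ones(16))
        w.amplitude[:] = 0
        np.testing.assert_array_equal(intensity(w), np.zeros(16))

    def test_two_wave_interference(self):
        phi = 0.7
        w = plane_wave(16)
        w.amplitude = (1 + np.exp(1j * phi)) * np.ones(16)
        np.testing.assert_allclose(intensity(w), 2 + 2 * np.cos(phi), rtol=1e-12)


class TestLohmann:
    def test_first_distance(self):
        assert lohmann_distance(1, 4e-6, LAM) == pytest.approx(40.33e-3, rel=1e-3)

    def test_structure(self):
        d1 = lohmann_distance(1, 4e-6, LAM)
        assert lohmann_distance(2, 4e-6, LAM) == pytest.approx(3 * d1)
        assert lohmann_distance(1, 4e-6, LAM / 2) == pytest.approx(2 * d1)
        with pytest.raises(ValueError):
            lohmann_distance(0, 4e-6, LAM)


class TestGratings:
    def test_phase_grating_preserves_intensity(self):
        w = plane_wave()
        g = GratingSpec(4e-6, "phase", profile="binary")
        out = apply_phase_grating(w, g)
        np.testing.assert_allclose(np.abs(out.amplitude), 1.0, atol=1e-12)

    def test_zero_shift_is_identity(self):
        w = plane_wave()
        g = GratingSpec(4e-6, "phase", phase_shift=0.0, profile="binary")
        np.testing.assert_allclose(apply_phase_grating(w, g).amplitude,
                                   w.amplitude, atol=1e-15)

    def test_under_resolved_rejected(self):
        w = plane_wave(64, dx=1e-6)
        with pytest.raises(ValueError, match="under-resolved"):
            apply_phase_grating(w, GratingSpec(4e-6, "phase"))

    def test_opaque_half_duty_halves_power(self):
        w = plane_wave()
        g = GratingSpec(2e-6, "absorption", profile="binary")
        out = apply_absorption_grating(w, g, 0.0)
        total = np.sum(np.abs(out.amplitude) ** 2)
        assert total == pytest.approx(0.5 * w.n, rel=1e-3)

    def test_period_shift_invariance(self):
        w = plane_wave()
        w.amplitude *= np.exp(1j * 0.3)
        g = GratingSpec(2e-6, "absorption")
        a = apply_absorption_grating(w, g, 0.7e-6)
        b = apply_absorption_grating(w, g, 0.7e-6 + 2e-6)
        np.testing.assert_allclose(a.amplitude, b.amplitude, atol=1e-12)

    def test_transparent_bars_identity(self):
        w = plane_wave()
        g = GratingSpec(2e-6, "absorption", bar_transmission=1.0)
        np.testing.assert_allclose(apply_absorption_grating(w, g).amplitude,
                                   w.amplitude, atol=1e-12)


class TestTalbot:
    def setup_method(self):
        self.p1 = 4e-6
        self.w = plane_wave(4096, dx=0.25e-6)
        self.g1 = GratingSpec(self.p1, "phase", profile="binary")
        self.after = apply_phase_grating(self.w, self.g1)
        self.d1 = lohmann_distance(1, self.p1, LAM)

    def test_pattern_period_and_visibility_at_d1(self):
        inten = intensity(fresnel_propagate(self.after, self.d1))
        spec = np.abs(np.fft.rfft(inten - inten.mean()))
        freqs = np.fft.rfftfreq(len(inten), 0.25e-6)
        assert 1 / freqs[np.argmax(spec)] == pytest.approx(self.p1 / 2, rel=1e-6)
        assert fringe_visibility(inten) > 0.9

    def test_visibility_peaks_at_lohmann_distance(self):
        vis = {f: fringe_visibility(
            intensity(fresnel_propagate(self.after, f * self.d1)),
            0.25e-6, self.p1 / 2) for f in (0.5, 1.0, 1.5)}
        assert vis[1.0] > vis[0.5]
        assert vis[1.0] > vis[1.5]

    def test_talbot_revival(self):
        z_t = 2 * self.p1**2 / LAM
        revived = intensity(fresnel_propagate(self.after, z_t))
        np.testing.assert_allclose(revived, intensity(self.after), atol=1e-6)


class TestPhaseStepping:
    def test_uniform_wave_flat_curve(self):
        w = plane_wave(4096)
        g2 = GratingSpec(2e-6, "absorption", profile="binary")
        cfg = SteppingConfig(4, 8e-6, 100)
        scan = phase_stepping_scan(w, g2, cfg)
        # translating a square window over a uniform field: flat in m
        np.testing.assert_allclose(scan - scan[:, :1], 0.0, atol=1e-9 * scan.mean())

    def test_sinusoidal_fringe_gives_pure_first_harmonic(self):
        p2 = 2e-6
        w = plane_wave(4096)
        inten = 1 + 0.4 * np.cos(2 * np.pi * w.x / p2 + 0.9)
        w.amplitude = np.sqrt(inten).astype(complex)
        g2 = GratingSpec(p2, "absorption")
        cfg = SteppingConfig(5, 8e-6, 100)
        scan = phase_stepping_scan(w, g2, cfg)
        m = np.arange(5)
        basis = np.column_stack([np.ones(5), np.cos(2 * np.pi * m / 5),
                                 np.sin(2 * np.pi * m / 5)])
        for px in (10, 50, 90):
            resid = scan[px] - basis @ np.linalg.lstsq(basis, scan[px],
                                                       rcond=None)[0]
            assert np.max(np.abs(resid)) < 1e-9 * scan[px].mean()

    def test_pixel_grid_validation(self):
        w = plane_wave(4096)
        g2 = GratingSpec(2e-6, "absorption")
        with pytest.raises(ValueError, match="integer multiple"):
            phase_stepping_scan(w, g2, SteppingConfig(5, 8.1e-6, 10))
        with pytest.raises(ValueError, match="beyond"):
            phase_stepping_scan(w, g2, SteppingConfig(5, 8e-6, 1000))


class TestProjectionApproximation:
    def test_empty_phantom_unit_wavefront(self):
        from xpci.phantoms import Phantom

        ph = Phantom((), get_material("vacuum"), (-1e-3, 1e-3, -1e-3, 1e-3))
        wf = pa_transmission(ph, (64, 2e-5, -0.64e-3), E)
        np.testing.assert_allclose(wf.amplitude, 1.0, atol=1e-9)

    def test_hollow_cylinder_chords(self):
        ph = build_hollow_cylinder_phantom()
        grid = (500, 2e-5, -5e-3)
        wf = pa_transmission(ph, grid, 10.0)
        x = wf.x
        pp = get_material("polypropylene")
        mu = compute_mu(pp, 10.0)
        delta = compute_delta(pp, 10.0)
        r_o, r_i = 5.5e-3, 4.5e-3
        chord = (2 * np.sqrt(np.clip(r_o**2 - x**2, 0, None))
                 - 2 * np.sqrt(np.clip(r_i**2 - x**2, 0, None)))
        k = wavenumber_from_energy(10.0)
        sel = np.abs(np.abs(x) - r_i) > 1e-4  # clear of grazing bins
        sel &= np.abs(np.abs(x) - r_o) > 1e-4
        span = ph.bbox[3] - ph.bbox[2]
        mu_air = compute_mu(get_material("air"), 10.0)
        expected = mu * chord + mu_air * (span - chord)
        np.testing.assert_allclose(-2 * np.log(np.abs(wf.amplitude[sel])),
                                   expected[sel] * 100, rtol=2e-4, atol=5e-5)
        # phase: the full complex amplitude matches the closed-form chord
        # integrals (wrap-free comparison)
        d_air = compute_delta(get_material("air"), 10.0)
        delta_bar = delta * chord + d_air * (span - chord)
        ref = np.exp(-expected * 100 / 2) * np.exp(-1j * k * delta_bar)
        np.testing.assert_allclose(wf.amplitude[sel], ref[sel],
                                   rtol=0, atol=2e-3)


def test_gaussian_source_reduces_visibility():
    """Fringe visibility decreases monotonically with source size."""
    p1 = 4e-6
    d1 = lohmann_distance(1, p1, LAM)
    from xpci.phantoms import Phantom

    vis = []
    for sigma in (0.0, 40e-6, 90e-6):
        kind = "plane" if sigma == 0 else "partial-gaussian"
        src = SourceSpec(kind, E, width=sigma if sigma else 120e-6,
                         roi_width=120e-6, distance=25.0, z0=-1e-4, n=1)
        ph = Phantom((), get_material("vacuum"), (-2e-4, 2e-4, -2e-4, 2e-4))
        cfg = TransportConfig(cutoff_energy=10.0, scoring_z=2e-4 - 1e-9)
        ps = run_histories(src, ph, cfg, seed=21, n=400_000)
        wf, _ = split_phase_space(ps, (480, 0.25e-6, -60e-6))
        wg = apply_phase_grating(wf, GratingSpec(p1, "phase"))
        inten = intensity(fresnel_propagate(wg, d1, guard=0.3))
        vis.append(fringe_visibility(inten[100:380], 0.25e-6, p1 / 2))
    assert vis[0] > vis[1] > vis[2]
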