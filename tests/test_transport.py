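"""Monte Carlo transport: samplers, refraction, slab physics, accounting."""

import numpy as np
import pytest

from xpci.constants import wavenumber_from_energy
from xpci.materials import (
    ELEMENTS,
    MaterialSpec,
    compute_delta,
    compute_mu,
    default_cross_sections,
)
from xpci.phantoms import build_slab_phantom, build_wedge_phantom
from xpci.sources import SourceSpec
from xpci.transport import (
    PhaseSpace,
    TransportConfig,
    apply_refraction,
    run_histories,
    sample_compton,
    sample_free_path,
    sample_rayleigh,
    select_interaction,
    transport_photon,
)
from xpci.transport import _MaterialTables


class TestFreePath:
    def test_mean_and_median(self, rng):
        mu = np.full(200_000, 5.0)
        s = sample_free_path(mu, rng)
        n = len(s)
        assert np.mean(s) == pytest.approx(0.2e-2, rel=3.0 / np.sqrt(n) * 1.0)
        assert np.median(s) == pytest.approx(np.log(2) / 5.0 * 1e-2, rel=0.01)

    def test_vacuum_is_infinite(self, rng):
        assert np.isinf(sample_free_path(np.array([0.0]), rng))[0]

    def test_negative_mu_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_free_path(np.array([-1.0]), rng)


class TestInteractionSelection:
    def test_channel_frequencies_match_cross_sections(self, rng, water):
        xs = default_cross_sections()
        tab = _MaterialTables([water], xs)
        ppe, pco = tab.channel_probs(np.array([0]), np.array([25.0]))
        n = 100_000
        counts = {"photoelectric": 0, "compton": 0, "rayleigh": 0}
        for _ in range(n):
            counts[select_interaction(water, 25.0, rng, xs)] += 1
        probs = {"photoelectric": ppe[0], "compton": pco[0],
                 "rayleigh": 1 - ppe[0] - pco[0]}
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        for ch, p in probs.items():
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[ch] - n * p) < 3.5 * sd

    def test_photoelectric_only_material(self, rng):
        # a fake cross-section set with photoelectric-only tables
        xs = default_cross_sections()
        import copy

        xs2 = copy.deepcopy(xs)
        for sym in xs2.tables:
            pe, co, ra = xs2.tables[sym]
            xs2.tables[sym] = (pe + co + ra, np.zeros_like(co), np.zeros_like(ra))
        mat = MaterialSpec("absorber", 1.0, ((ELEMENTS["O"], 1.0),))
        assert all(select_interaction(mat, 25.0, rng, xs2) == "photoelectric"
                   for _ in range(50))


class TestCompton:
    def test_energy_angle_relation_exact(self, rng):
        e, theta = sample_compton(np.full(5000, 25.0), rng)
        k = 25.0 / 510.99895
        np.testing.assert_allclose(e, 25.0 / (1 + k * (1 - np.cos(theta))),
                                   rtol=1e-12)
        # backscatter limit of the Compton formula
        assert 25.0 / (1 + 2 * k) == pytest.approx(22.77, abs=0.01)

    def test_angular_distribution_matches_klein_nishina(self, rng):
        """Chi-squared of sampled cos(theta) against the numeric KN pdf."""
        n = 200_000
        _, theta = sample_compton(np.full(n, 25.0), rng)
        c = np.cos(theta)
        k = 25.0 / 510.99895
        grid = np.linspace(-1, 1, 2001)
        eps = 1.0 / (1 + k * (1 - grid))
        pdf = eps**2 * (eps + 1 / eps - (1 - grid**2))
        pdf /= np.trapezoid(pdf, grid)
        edges = np.linspace(-1, 1, 21)
        expected = np.array([
            np.trapezoid(pdf[(grid >= a) & (grid <= b)],
                         grid[(grid >= a) & (grid <= b)])
            for a, b in zip(edges[:-1], edges[1:])]) * n
        observed, _ = np.histogram(c, bins=edges)
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert chi2 < 43.8  # dof=19, p=0.001


class TestRayleigh:
    def test_thomson_mode_distribution(self, rng):
        n = 200_000
        theta = sample_rayleigh(ELEMENTS["O"], 25.0, rng, size=n, thomson=True)
        c = np.cos(theta)
        edges = np.linspace(-1, 1, 21)
        cdf = lambda x: (3 * x / 8 + x**3 / 8 + 0.5)  # noqa: E731
        expected = np.diff([cdf(e) for e in edges]) * n
        observed, _ = np.histogram(c, bins=edges)
        chi2 = np.sum((observed - expected) ** 2 / expected)
        assert chi2 < 43.8

    def test_forward_peaking_increases_with_energy(self, rng):
        th25 = sample_rayleigh(ELEMENTS["O"], 25.0, rng, size=20_000)
        th10 = sample_rayleigh(ELEMENTS["O"], 10.0, rng, size=20_000)
        assert np.median(th25) < np.median(th10)


class TestRefraction:
    def test_normal_incidence_unchanged(self):
        d = np.array([0.0, 0.0, 1.0])
        out = apply_refraction(d, np.array([0.0, 0.0, 1.0]), 1.0, 1 - 3.7e-7)
        np.testing.assert_allclose(out, d, atol=1e-15)

    @pytest.mark.parametrize("tilt", [0.01, 0.3, 1.0])
    def test_snell_reversibility(self, tilt):
        d = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        nrm = np.array([0.0, 0.0, 1.0])
        n1, n2 = 1.0, 1 - 2.1e-6
        mid = apply_refraction(d, nrm, n1, n2)
        back = apply_refraction(mid, -nrm, n2, n1)
        np.testing.assert_allclose(back, d, atol=1e-12)

    def test_total_external_reflection_at_grazing(self):
        delta = 3.687e-7
        theta_c = np.sqrt(2 * delta)  # critical grazing angle ~0.86 mrad
        graze = 0.5 * theta_c
        d = np.array([np.cos(graze), 0.0, np.sin(graze)])  # mostly along x
        nrm = np.array([0.0, 0.0, 1.0])  # surface normal along z
        out = apply_refraction(d, nrm, 1.0, 1.0 - delta)
        # reflected: z-component flips sign, x preserved
        assert out[2] == pytest.approx(-d[2], rel=1e-9)
        assert out[0] == pytest.approx(d[0], rel=1e-9)

    def test_non_unit_inputs_rejected(self):
        with pytest.raises(ValueError):
            apply_refraction(np.array([0.0, 0.0, 2.0]),
                             np.array([0.0, 0.0, 1.0]), 1.0, 1.0)


def _slab_run(material, thickness, energy, n, seed, cutoff=9.0):
    slab = build_slab_phantom(material, thickness, half_width=0.05)
    src = SourceSpec("plane", energy, width=0.01, z0=slab.bbox[2] + 1e-9)
    cfg = TransportConfig(cutoff_energy=cutoff, scoring_z=slab.bbox[3] - 1e-9)
    return run_histories(src, slab, cfg, seed=seed, n=n)


class TestSlabPhysics:
    @pytest.mark.parametrize("name, energy", [
        ("water", 25.0), ("water", 10.0),
        ("polystyrene", 25.0), ("polypropylene", 10.0), ("pmma", 25.0),
    ])
    def test_beer_lambert_unscattered_fraction(self, name, energy):
        from xpci.materials import get_material

        mat = get_material(name)
        t = 1e-3
        n = 50_000
        ps = _slab_run(mat, t, energy, n, seed=17, cutoff=5.0)
        unscattered = np.sum((ps.n_compton == 0) & (ps.n_rayleigh == 0))
        p = np.exp(-compute_mu(mat, energy) * t * 100)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(unscattered - n * p) < 3.5 * sd

    def test_optical_path_length_closed_form(self, water):
        """Straight transit of 1 mm water at 25 keV accumulates
        opl = k * delta * t (~46.7 rad)."""
        ps = _slab_run(water, 1e-3, 25.0, 2000, seed=5)
        unscattered = (ps.n_compton == 0) & (ps.n_rayleigh == 0)
        k = wavenumber_from_energy(25.0)
        expected = k * compute_delta(water, 25.0) * 1e-3
        assert expected == pytest.approx(46.7, abs=0.1)
        np.testing.assert_allclose(ps.opl[unscattered], expected, rtol=1e-6)

    def test_opl_additivity_of_stacked_slabs(self, water):
        ps1 = _slab_run(water, 2e-3, 25.0, 2000, seed=6)
        u1 = (ps1.n_compton == 0) & (ps1.n_rayleigh == 0)
        # two stacked slabs = one phantom with two adjacent regions; with
        # identical material the opl must equal the single 2 mm slab
        from xpci.phantoms import ConvexRegion, Phantom
        from xpci.materials import get_material

        vac = get_material("vacuum")
        regions = (
            ConvexRegion(((0.0, -1.0, 0.0), (0.0, 1.0, 1e-3)), water, 1),
            ConvexRegion(((0.0, -1.0, -1e-3), (0.0, 1.0, 2e-3)), water, 1),
        )
        ph = Phantom(regions, vac, (-0.05, 0.05, -5e-3, 7e-3))
        src = SourceSpec("plane", 25.0, width=0.01, z0=-4.9e-3)
        cfg = TransportConfig(cutoff_energy=9.0, scoring_z=6.9e-3)
        ps2 = run_histories(src, ph, cfg, seed=6, n=2000)
        u2 = (ps2.n_compton == 0) & (ps2.n_rayleigh == 0)
        assert np.median(ps2.opl[u2]) == pytest.approx(
            np.median(ps1.opl[u1]), rel=1e-6)

    def test_wedge_prism_deviation(self, water):
        """Unscattered deflection through a wedge matches the analytic
        prism deviation (n1 - n2) * tan(wedge angle)."""
        slope = 0.5
        ph = build_wedge_phantom(water, slope, extent=5e-3)
        src = SourceSpec("plane", 25.0, width=2e-3, center=2.5e-3,
                         z0=ph.bbox[2] + 1e-9)
        cfg = TransportConfig(cutoff_energy=9.0, scoring_z=ph.bbox[3] - 1e-9)
        ps = run_histories(src, ph, cfg, seed=8, n=2000)
        u = (ps.n_compton == 0) & (ps.n_rayleigh == 0) & (np.abs(ps.dx) > 0)
        expected = compute_delta(water, 25.0) * slope
        np.testing.assert_allclose(np.abs(ps.dx[u]), expected, rtol=1e-3)
        # deflection is toward the thin side (-x) for n < 1
        assert np.all(ps.dx[u] < 0)


class TestHistories:
    def test_accounting_identity(self, water):
        ps = _slab_run(water, 1e-3, 25.0, 5000, seed=11)
        assert len(ps) + ps.n_absorbed + ps.n_escaped + ps.n_flagged == 5000

    def test_fixed_seed_bitwise_reproducible(self, water):
        a = _slab_run(water, 1e-3, 25.0, 3000, seed=13)
        b = _slab_run(water, 1e-3, 25.0, 3000, seed=13)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.opl, b.opl)
        c = _slab_run(water, 1e-3, 25.0, 3000, seed=14)
        assert not np.array_equal(a.x, c.x)

    def test_sqrt_n_error_scaling(self, water):
        """Standard error of the scored fraction scales ~ 1/sqrt(N)."""
        slab = build_slab_phantom(water, 5e-3, half_width=0.05)
        src = SourceSpec("plane", 25.0, width=0.01, z0=slab.bbox[2] + 1e-9)
        cfg = TransportConfig(cutoff_energy=10.0, scoring_z=slab.bbox[3] - 1e-9)
        rng = np.random.default_rng(999)
        ns = [1000, 2000, 4000, 8000]
        stds = []
        for n in ns:
            fr = [len(run_histories(src, slab, cfg, rng=rng, n=n)) / n
                  for _ in range(24)]
            stds.append(np.std(fr, ddof=1))
        slope = np.polyfit(np.log(ns), np.log(stds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.12)

    def test_max_steps_flags_not_silent(self, water, caplog):
        slab = build_slab_phantom(water, 1e-3, half_width=0.05)
        src = SourceSpec("plane", 25.0, width=0.01, z0=slab.bbox[2] + 1e-9)
        cfg = TransportConfig(cutoff_energy=10.0,
                              scoring_z=slab.bbox[3] - 1e-9, max_steps=1)
        import logging

        with caplog.at_level(logging.WARNING, logger="xpci.transport"):
            ps = run_histories(src, slab, cfg, seed=1, n=500)
        assert ps.n_flagged > 0
        assert any("flagged" in r.message for r in caplog.records)

    def test_transport_photon_single(self, water, rng):
        from xpci.sources import sample_photon

        slab = build_slab_phantom(water, 1e-4, half_width=0.05)
        init = sample_photon(SourceSpec("plane", 25.0, width=1e-3,
                                        z0=slab.bbox[2] + 1e-9), rng)
        cfg = TransportConfig(cutoff_energy=10.0, scoring_z=slab.bbox[3] - 1e-9)
        status, ps = transport_photon(init, slab, cfg, rng)
        assert len(ps) + ps.n_absorbed + ps.n_escaped + ps.n_flagged == 1


def test_phase_space_csv_roundtrip(tmp_path, water):
    ps = _slab_run(water, 1e-3, 25.0, 500, seed=3)
    path = tmp_path / "ps.csv"
    ps.to_csv(path)
    back = PhaseSpace.from_csv(path)
    for col in PhaseSpace._COLS:
        np.testing.assert_array_equal(getattr(ps, col), getattr(back, col))
    assert back.n_emitted == ps.n_emitted
    assert back.config_digest == ps.config_digest
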