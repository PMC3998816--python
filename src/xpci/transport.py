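"""Photon Monte Carlo through a phantom, carrying phase and refraction.

Analog transport: exponential free paths from the local attenuation
coefficient, interaction channels (photoelectric / Compton / Rayleigh)
drawn from their cross-section ratios, Klein-Nishina Compton sampling
(free electron), form-factor Rayleigh sampling, and two extensions that
make the particle stage phase-aware:

* every geometric step adds k * delta(material) * step to the photon's
  optical path length (the phase it would accumulate relative to vacuum);
* at every material boundary Snell's law is applied to the tiny refractive
  index difference, including total external reflection past the critical
  angle (~ sqrt(2*delta) at grazing incidence).

Photons are terminated by photoelectric absorption, by falling below the
cut-off energy (deposited locally), by leaving the bounding box, or scored
when they cross the scoring plane.  The engine is vectorized over photons;
a fixed seed gives bitwise-identical results.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass

import numpy as np

from .constants import M_E_C2_KEV, R_ELECTRON_M, wavelength_from_energy
from .materials import (
    CrossSectionSet,
    MaterialSpec,
    default_cross_sections,
    electron_density,
)
from .phantoms import GeometryEngine, Phantom
from .sources import PhotonInit, SourceSpec, sample_photons

logger = logging.getLogger(__name__)

__all__ = [
    "TransportConfig", "PhaseSpace", "run_histories", "transport_photon",
    "sample_free_path", "select_interaction", "sample_compton",
    "sample_rayleigh", "apply_refraction",
    "ALIVE", "SCORED", "ABSORBED", "ESCAPED", "FLAGGED",
]

ALIVE, SCORED, ABSORBED, ESCAPED, FLAGGED = 0, 1, 2, 3, 4

#: nudge past a boundary after refraction (m); far below any geometric
#: feature size but far above the intersection acceptance epsilon.
BOUNDARY_EPS = 1e-9


@dataclass(frozen=True)
class TransportConfig:
    """Cut-off energy (keV), scoring plane z (m), iteration guard."""

    cutoff_energy: float = 10.0
    scoring_z: float = 0.0
    max_steps: int = 2000

    def __post_init__(self):
        if self.cutoff_energy < 1.0:
            raise ValueError("cutoff below 1 keV is outside cross-section validity")


@dataclass
class PhaseSpace:
    """Exit-plane photon records: the MC -> wave-optics handoff artifact."""

    x: np.ndarray
    y: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    energy: np.ndarray  # keV
    weight: np.ndarray
    opl: np.ndarray  # accumulated optical path length (rad)
    n_compton: np.ndarray
    n_rayleigh: np.ndarray
    # provenance / accounting
    n_emitted: int = 0
    n_absorbed: int = 0
    n_escaped: int = 0
    n_flagged: int = 0
    source_width: float = 0.0
    scoring_z: float = 0.0
    energy0: float = 0.0
    seed: int | None = None
    config_digest: str = ""

    def __len__(self):
        return len(self.x)

    _COLS = ("x", "y", "dx", "dy", "dz", "energy", "weight", "opl",
             "n_compton", "n_rayleigh")
    _META = ("n_emitted", "n_absorbed", "n_escaped", "n_flagged",
             "source_width", "scoring_z", "energy0", "seed", "config_digest")

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("# xpci phase space v1\n")
            for m in self._META:
                fh.write(f"# {m}={getattr(self, m)}\n")
            fh.write(",".join(self._COLS) + "\n")
            data = np.column_stack([getattr(self, c) for c in self._COLS])
            np.savetxt(fh, data, delimiter=",", fmt="%.17e")

    @classmethod
    def from_csv(cls, path):
        meta = {}
        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("# ") and "=" in line:
                k, v = line[2:].split("=", 1)
                meta[k] = v
        body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
        data = np.loadtxt(io.StringIO(body), delimiter=",", skiprows=1, ndmin=2)
        if data.size == 0:
            data = np.empty((0, len(cls._COLS)))
        cols = {c: data[:, i] for i, c in enumerate(cls._COLS)}
        cols["n_compton"] = cols["n_compton"].astype(int)
        cols["n_rayleigh"] = cols["n_rayleigh"].astype(int)
        return cls(
            **cols,
            n_emitted=int(meta["n_emitted"]), n_absorbed=int(meta["n_absorbed"]),
            n_escaped=int(meta["n_escaped"]), n_flagged=int(meta["n_flagged"]),
            source_width=float(meta["source_width"]),
            scoring_z=float(meta["scoring_z"]), energy0=float(meta["energy0"]),
            seed=None if meta["seed"] == "None" else int(meta["seed"]),
            config_digest=meta["config_digest"],
        )


# ---------------------------------------------------------------------------
# Elementary samplers (unit-testable in isolation)
# ---------------------------------------------------------------------------

def sample_free_path(mu_per_cm, rng, size=None):
    """Exponential free path (m) for attenuation coefficient mu (1/cm)."""
    mu = np.asarray(mu_per_cm, dtype=float)
    if np.any(mu < 0):
        raise ValueError("mu must be >= 0")
    u = rng.random(size if size is not None else mu.shape or None)
    with np.errstate(divide="ignore"):
        s = -np.log1p(-u) / (mu * 100.0)  # 1/cm -> 1/m
    return s


def sample_compton(energy_kev, rng):
    """Klein-Nishina (free-electron) Compton sample.

    Returns (scattered energy keV, polar angle rad) for each input energy;
    rejection sampling of cos(theta) against the KN differential cross
    section, azimuth handled by the caller.
    """
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    k = e / M_E_C2_KEV
    n = e.shape[0]
    cost = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        c = rng.uniform(-1.0, 1.0, todo.size)
        u = rng.random(todo.size)
        eps = 1.0 / (1.0 + k[todo] * (1.0 - c))
        f = eps * eps * (eps + 1.0 / eps - (1.0 - c * c))
        acc = u * 2.0 <= f
        cost[todo[acc]] = c[acc]
        todo = todo[~acc]
    e_out = e / (1.0 + k * (1.0 - cost))
    theta = np.arccos(np.clip(cost, -1.0, 1.0))
    if np.ndim(energy_kev) == 0:
        return float(e_out[0]), float(theta[0])
    return e_out, theta


def sample_rayleigh(element, energy_kev, rng, size=None, thomson=False):
    """Rayleigh polar angles (rad) from Thomson x form-factor^2.

    ``thomson=True`` ignores the form factor (pure 1 + cos^2 sampling),
    which is the analytic reference mode used in tests.
    """
    e = float(energy_kev)
    n = int(size) if size is not None else 1
    lam_a = wavelength_from_energy(e) * 1e10
    f0 = 1.0 if thomson else float(element.form_factor(np.array([0.0]))[0])
    out = np.empty(n)
    todo = n
    filled = 0
    while todo:
        m = max(todo * 8, 64)
        c = rng.uniform(-1.0, 1.0, m)
        u = rng.random(m)
        if thomson:
            f = (1.0 + c * c) / 2.0
        else:
            s = np.sqrt((1.0 - c) / 2.0) / lam_a
            f = (1.0 + c * c) / 2.0 * (element.form_factor(s) / f0) ** 2
        acc = np.nonzero(u <= f)[0][:todo]
        out[filled:filled + acc.size] = c[acc]
        filled += acc.size
        todo -= acc.size
    theta = np.arccos(out)
    if size is None:
        return float(theta[0])
    return theta


def apply_refraction(direction, normal, n_from, n_to):
    """Snell refraction of unit ``direction`` at a surface with unit
    ``normal``; total external reflection if sin(theta_r) would exceed 1.

    Works on arrays with the vector components in the last axis.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.asarray(normal, dtype=float)
    if np.any(np.abs(np.linalg.norm(d, axis=-1) - 1.0) > 1e-9) or \
       np.any(np.abs(np.linalg.norm(nrm, axis=-1) - 1.0) > 1e-9):
        raise ValueError("direction and normal must be unit vectors")
    # orient normal against the direction of travel (incidence side)
    cos_i = np.sum(d * nrm, axis=-1, keepdims=True)
    nrm = np.where(cos_i > 0, -nrm, nrm)
    cos_i = np.abs(cos_i)
    ratio = np.asarray(n_from / n_to)[..., None]
    sin2_t = ratio**2 * (1.0 - cos_i**2)
    tir = sin2_t > 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    refracted = ratio * d + (ratio * cos_i - cos_t) * nrm
    reflected = d + 2.0 * cos_i * nrm
    out = np.where(tir, reflected, refracted)
    out /= np.linalg.norm(out, axis=-1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Per-material property tables
# ---------------------------------------------------------------------------

class _MaterialTables:
    """mu(E), channel fractions and Rayleigh element weights per material."""

    def __init__(self, materials, xs: CrossSectionSet):
        self.materials = materials
        self.xs = xs
        self.log_e = np.log(xs.energies)
        n_m, n_e = len(materials), len(xs.energies)
        self.mu = np.zeros((n_m, n_e))          # 1/cm
        self.p_pe = np.zeros((n_m, n_e))
        self.p_co = np.zeros((n_m, n_e))
        self.n_e = np.zeros(n_m)                # electrons / m^3
        self.elements = []                      # per material: list of ElementSpec
        self.ray_w = []                         # per material: (n_el, n_e) weights
        for i, mat in enumerate(materials):
            if getattr(mat, "name", "") == "escaped" or mat.density == 0.0:
                self.elements.append([])
                self.ray_w.append(np.zeros((0, n_e)))
                continue
            self.n_e[i] = electron_density(mat)
            pe = np.zeros(n_e)
            co = np.zeros(n_e)
            ra = np.zeros(n_e)
            ray_w = []
            els = []
            for el, w in mat.composition:
                cpe, cco, cra = xs.tables[el.symbol]
                pe += w * cpe
                co += w * cco
                ra += w * cra
                els.append(el)
                ray_w.append(w * cra)
            tot = pe + co + ra
            self.mu[i] = mat.density * tot
            self.p_pe[i] = pe / tot
            self.p_co[i] = co / tot
            self.elements.append(els)
            rw = np.asarray(ray_w)
            self.ray_w.append(rw / np.maximum(rw.sum(axis=0), 1e-300))

    def mu_at(self, mid, energy):
        """Linear attenuation (1/cm) per photon (mid, energy arrays)."""
        idx = np.searchsorted(self.log_e, np.log(energy)) - 1
        idx = np.clip(idx, 0, len(self.log_e) - 2)
        t = (np.log(energy) - self.log_e[idx]) / (self.log_e[idx + 1] - self.log_e[idx])
        a = self.mu[mid, idx]
        b = self.mu[mid, idx + 1]
        with np.errstate(divide="ignore"):
            out = np.where((a > 0) & (b > 0),
                           np.exp((1 - t) * np.log(np.maximum(a, 1e-300))
                                  + t * np.log(np.maximum(b, 1e-300))),
                           (1 - t) * a + t * b)
        return out

    def channel_probs(self, mid, energy):
        idx = np.searchsorted(self.log_e, np.log(energy)) - 1
        idx = np.clip(idx, 0, len(self.log_e) - 2)
        t = (np.log(energy) - self.log_e[idx]) / (self.log_e[idx + 1] - self.log_e[idx])
        ppe = (1 - t) * self.p_pe[mid, idx] + t * self.p_pe[mid, idx + 1]
        pco = (1 - t) * self.p_co[mid, idx] + t * self.p_co[mid, idx + 1]
        return ppe, pco

    def delta_at(self, mid, energy):
        lam = wavelength_from_energy(energy)
        return R_ELECTRON_M * lam**2 * self.n_e[mid] / (2.0 * np.pi)


def select_interaction(material: MaterialSpec, energy, rng,
                       xs: CrossSectionSet | None = None):
    """Draw an interaction channel name for one material/energy."""
    xs = xs or default_cross_sections()
    tab = _MaterialTables([material], xs)
    ppe, pco = tab.channel_probs(np.array([0]), np.atleast_1d(float(energy)))
    u = rng.random()
    if u < ppe[0]:
        return "photoelectric"
    if u < ppe[0] + pco[0]:
        return "compton"
    return "rayleigh"


def _rotate_direction(dx, dy, dz, theta, phi):
    """Deflect unit vectors by polar angle theta (azimuth phi about the axis)."""
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    # orthonormal frame (u, v, d): cross d with x-hat near the z axis,
    # with z-hat otherwise, to avoid a degenerate frame
    near_z = np.abs(dz) > 0.99999
    u1 = np.stack([np.zeros_like(dx), -dz, dy])   # (1,0,0) x d
    u2 = np.stack([-dy, dx, np.zeros_like(dx)])   # (0,0,1) x d
    u = np.where(near_z, u1, u2)
    u /= np.linalg.norm(u, axis=0)
    d = np.stack([dx, dy, dz])
    v = np.cross(d, u, axis=0)
    out = ct * d + st * (cp * u + sp * v)
    out /= np.linalg.norm(out, axis=0)
    return out[0], out[1], out[2]


# ---------------------------------------------------------------------------
# The transport loop
# ---------------------------------------------------------------------------

def run_histories(source: SourceSpec, phantom: Phantom, config: TransportConfig,
                  seed=None, rng=None, n: int | None = None,
                  xs: CrossSectionSet | None = None,
                  init: PhotonInit | None = None) -> PhaseSpace:
    """Simulate ``n`` photon histories and return the scored phase space.

    Accounting identity: scored + absorbed + escaped + flagged == emitted.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(n if n is not None else source.n)
    xs = xs or default_cross_sections()
    engine = GeometryEngine(phantom)
    tables = _MaterialTables(engine.materials, xs)
    ph = init if init is not None else sample_photons(source, n, rng)
    x, y, z = ph.x.copy(), ph.y.copy(), ph.z.copy()
    dx, dy, dz = ph.dx.copy(), ph.dy.copy(), ph.dz.copy()
    energy, weight, opl = ph.energy.copy(), ph.weight.copy(), ph.opl.copy()
    n_co = np.zeros(n, dtype=int)
    n_ra = np.zeros(n, dtype=int)
    status = np.full(n, ALIVE, dtype=np.int8)
    two_pi_over_hc = 2.0 * np.pi / (1.23984198e-9)  # k = this * E_keV (1/m)

    alive = np.nonzero(status == ALIVE)[0]
    for _ in range(config.max_steps):
        if alive.size == 0:
            break
        ax, az = x[alive], z[alive]
        adx, ady, adz = dx[alive], dy[alive], dz[alive]
        ae = energy[alive]
        mids = engine.locate_ids(ax, az)
        # photons travelling (numerically) parallel to y leave the slice
        esc = (mids < 0) | (adx * adx + adz * adz < 1e-20)
        if np.any(esc):
            status[alive[esc]] = ESCAPED
            keep = ~esc
            alive = alive[keep]
            ax, az, adx, ady, adz, ae, mids = (
                a[keep] for a in (ax, az, adx, ady, adz, ae, mids))
            if alive.size == 0:
                break
        mu = tables.mu_at(mids, ae)
        s_free = sample_free_path(mu, rng)
        t_bnd, nx_b, nz_b = engine.next_boundary_arrays(ax, az, adx, adz)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_score = np.where(adz > 0, (config.scoring_z - z[alive]) / adz, np.inf)
        t_score = np.where(t_score > 0, t_score, np.inf)
        step = np.minimum(np.minimum(s_free, t_bnd), t_score)
        # accumulate phase over the step
        k_ph = two_pi_over_hc * ae
        delta = tables.delta_at(mids, ae)
        opl[alive] += k_ph * delta * step
        x[alive] += step * adx
        y[alive] += step * ady
        z[alive] += step * adz

        is_score = t_score <= np.minimum(s_free, t_bnd)
        is_bnd = (~is_score) & (t_bnd <= s_free)
        is_int = (~is_score) & (~is_bnd)

        if np.any(is_score):
            status[alive[is_score]] = SCORED
        # -- boundary: refract or totally reflect --------------------------
        if np.any(is_bnd):
            sel = np.nonzero(is_bnd)[0]
            gsel = alive[sel]
            d3 = np.stack([dx[gsel], dy[gsel], dz[gsel]], axis=-1)
            n3 = np.stack([nx_b[sel], np.zeros(sel.size), nz_b[sel]], axis=-1)
            # far-side material: probe a nudge past the boundary
            px = x[gsel] + BOUNDARY_EPS * dx[gsel]
            pz = z[gsel] + BOUNDARY_EPS * dz[gsel]
            mid_to = engine.locate_ids(px, pz)
            mid_from = mids[sel]
            esc2 = mid_to < 0
            n1 = 1.0 - tables.delta_at(np.maximum(mid_from, 0), energy[gsel])
            n2 = 1.0 - tables.delta_at(np.maximum(mid_to, 0), energy[gsel])
            nrm_len = np.linalg.norm(n3, axis=-1)
            ok = nrm_len > 0.5
            d3[ok] = apply_refraction(d3[ok], n3[ok], n1[ok], n2[ok])
            dx[gsel], dy[gsel], dz[gsel] = d3[:, 0], d3[:, 1], d3[:, 2]
            x[gsel] += BOUNDARY_EPS * d3[:, 0]
            y[gsel] += BOUNDARY_EPS * d3[:, 1]
            z[gsel] += BOUNDARY_EPS * d3[:, 2]
            status[gsel[esc2]] = ESCAPED
        # -- interaction ---------------------------------------------------
        if np.any(is_int):
            sel = np.nonzero(is_int)[0]
            gsel = alive[sel]
            ppe, pco = tables.channel_probs(mids[sel], energy[gsel])
            u = rng.random(sel.size)
            pe_m = u < ppe
            co_m = (~pe_m) & (u < ppe + pco)
            ra_m = ~(pe_m | co_m)
            status[gsel[pe_m]] = ABSORBED
            if np.any(co_m):
                g = gsel[co_m]
                e_new, theta = sample_compton(energy[g], rng)
                phi = rng.uniform(0, 2 * np.pi, g.size)
                dx[g], dy[g], dz[g] = _rotate_direction(
                    dx[g], dy[g], dz[g], theta, phi)
                energy[g] = e_new
                n_co[g] += 1
                below = energy[g] < config.cutoff_energy
                status[g[below]] = ABSORBED
            if np.any(ra_m):
                g = gsel[ra_m]
                lmids = mids[sel][ra_m]
                theta = np.empty(g.size)
                # element choice weighted by each element's coherent share
                for m in np.unique(lmids):
                    mm = lmids == m
                    els = tables.elements[m]
                    if not els:
                        theta[mm] = 0.0
                        continue
                    w = tables.ray_w[m]
                    # nearest grid point is accurate enough for a choice prob
                    gi = np.clip(np.searchsorted(
                        tables.log_e, np.log(energy[g[mm]])), 0, w.shape[1] - 1)
                    probs = w[:, gi]  # (n_el, n_sel)
                    cum = np.cumsum(probs, axis=0)
                    if len(els) > 1:
                        pick = (rng.random(int(mm.sum()))[:, None]
                                < cum.T).argmax(axis=1)
                    else:
                        pick = np.zeros(int(mm.sum()), int)
                    th = np.empty(mm.sum())
                    for ei, el in enumerate(els):
                        emask = pick == ei
                        if np.any(emask):
                            # one energy per draw; use the mean (narrow spread)
                            th[emask] = sample_rayleigh(
                                el, float(np.mean(energy[g[mm]])), rng,
                                size=int(emask.sum()))
                    theta[mm] = th
                phi = rng.uniform(0, 2 * np.pi, g.size)
                dx[g], dy[g], dz[g] = _rotate_direction(
                    dx[g], dy[g], dz[g], theta, phi)
                n_ra[g] += 1
        alive = np.nonzero(status == ALIVE)[0]
    if alive.size:
        status[alive] = FLAGGED
        logger.warning("%d photons exceeded max_steps=%d and were flagged",
                       alive.size, config.max_steps)

    scored = status == SCORED
    digest = hashlib.sha256(
        f"{source}{config}{phantom.bbox}{n}".encode()).hexdigest()[:12]
    ps = PhaseSpace(
        x=x[scored], y=y[scored], dx=dx[scored], dy=dy[scored], dz=dz[scored],
        energy=energy[scored], weight=weight[scored], opl=opl[scored],
        n_compton=n_co[scored], n_rayleigh=n_ra[scored],
        n_emitted=n, n_absorbed=int(np.sum(status == ABSORBED)),
        n_escaped=int(np.sum(status == ESCAPED)),
        n_flagged=int(np.sum(status == FLAGGED)),
        source_width=source.width if source.width > 0 else source.roi_width,
        scoring_z=config.scoring_z, energy0=source.energy,
        seed=seed, config_digest=digest,
    )
    logger.info("transport: emitted=%d scored=%d absorbed=%d escaped=%d flagged=%d",
                n, len(ps), ps.n_absorbed, ps.n_escaped, ps.n_flagged)
    return ps


def transport_photon(init: PhotonInit, phantom: Phantom, config: TransportConfig,
                     rng) -> tuple:
    """Transport a single photon; returns (status, PhaseSpace-of-one)."""
    src = SourceSpec("plane", float(init.energy[0]), roi_width=1.0)
    ps = run_histories(src, phantom, config, rng=rng, n=1, init=init)
    if len(ps):
        return SCORED, ps
    if ps.n_absorbed:
        return ABSORBED, ps
    if ps.n_flagged:
        return FLAGGED, ps
    return ESCAPED, ps
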