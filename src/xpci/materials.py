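"""Optical constants of X-ray materials from elemental composition.

For hard X-rays the refractive index is written n = 1 - delta + i*beta.
``delta`` follows from the electron density (with the atomic scattering
factor f1 approximated by Z, valid away from absorption edges):

    delta = (r_e * lambda^2 / 2pi) * sum_i n_i * Z_i ,

and the linear attenuation coefficient is the density-weighted sum of
per-element mass attenuation coefficients, each the sum of the
photoelectric, Compton (incoherent) and Rayleigh (coherent) channels:

    mu = rho * sum_i w_i * (N_A / A_i) * (sigma_pe + sigma_C + sigma_R).

Channel construction
--------------------
The Compton channel is the analytic Klein-Nishina total cross section per
electron times Z (free-electron approximation, no binding/Doppler).  The
Rayleigh channel is the Thomson cross section modulated by the squared
atomic form factor (Cromer-Mann analytic fits), integrated numerically.
The photoelectric channel is anchored so that the three channels sum to
standard reference total mass-attenuation values on the NIST energy grid;
between anchors it is interpolated log-log, which is accurate because the
photoelectric cross section is very nearly a power law in energy.  Valid
range 1-100 keV; no absorption-edge structure (all supported elements have
edges below 1 keV except none in range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    HC_KEV_NM,
    M_E_C2_KEV,
    N_AVOGADRO,
    R_ELECTRON_CM,
    R_ELECTRON_M,
    wavelength_from_energy,
)

__all__ = [
    "ElementSpec",
    "MaterialSpec",
    "OpticalConstants",
    "CrossSectionSet",
    "ELEMENTS",
    "MATERIALS",
    "get_material",
    "material_from_dict",
    "mix_materials",
    "parse_formula",
    "compute_delta",
    "compute_beta",
    "compute_mu",
    "electron_density",
    "optical_constants",
    "klein_nishina_total",
    "rayleigh_cross_section",
    "default_cross_sections",
]

ENERGY_RANGE_KEV = (1.0, 100.0)


@dataclass(frozen=True)
class ElementSpec:
    """A chemical element: symbol, atomic number Z, atomic mass A (g/mol)."""

    symbol: str
    Z: int
    A: float
    #: Cromer-Mann coefficients (a[4], b[4], c) for the atomic form factor
    #: F(s) = sum a_i exp(-b_i s^2) + c with s = sin(theta/2)/lambda in 1/A.
    cm_a: tuple = ()
    cm_b: tuple = ()
    cm_c: float = 0.0

    def __post_init__(self):
        if self.Z < 1:
            raise ValueError(f"Z must be >= 1, got {self.Z}")
        if self.A <= 0 or self.A < self.Z:
            raise ValueError(f"unphysical atomic mass A={self.A} for Z={self.Z}")

    def form_factor(self, s_inv_angstrom):
        """Atomic form factor F(s), s = sin(theta/2)/lambda in 1/Angstrom.

        The analytic fit is used up to s = 2/A; beyond that it is continued
        with a 1/s^2 tail (the fit itself diverges out of range, while the
        true form factor decays -- the tail region carries negligible
        Rayleigh probability anyway).
        """
        s = np.asarray(s_inv_angstrom, dtype=float)
        a = np.asarray(self.cm_a)
        b = np.asarray(self.cm_b)
        s_fit = np.minimum(s, 2.0)
        f = np.sum(a * np.exp(-b * s_fit[..., None] ** 2), axis=-1) + self.cm_c
        tail = np.where(s > 2.0, (2.0 / np.maximum(s, 2.0)) ** 2, 1.0)
        return f * tail


# Cromer-Mann form-factor fits (International Tables convention).
ELEMENTS: dict[str, ElementSpec] = {
    "H": ElementSpec(
        "H", 1, 1.008,
        (0.489918, 0.262003, 0.196767, 0.049879),
        (20.6593, 7.74039, 49.5519, 2.20159), 0.001305,
    ),
    "C": ElementSpec(
        "C", 6, 12.011,
        (2.31000, 1.02000, 1.58860, 0.865000),
        (20.8439, 10.2075, 0.568700, 51.6512), 0.215600,
    ),
    "N": ElementSpec(
        "N", 7, 14.007,
        (12.2126, 3.13220, 2.01250, 1.16630),
        (0.005700, 9.89330, 28.9975, 0.582600), -11.5290,
    ),
    "O": ElementSpec(
        "O", 8, 15.999,
        (3.04850, 2.28680, 1.54630, 0.867000),
        (13.2771, 5.70110, 0.323900, 32.9089), 0.250800,
    ),
}

# Standard-reference total mass attenuation anchors (cm^2/g) on the common
# reference energy grid; photoelectric values are derived from these (see
# module docstring).
_ANCHOR_KEV = np.array([5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0])
_ANCHOR_MU_RHO = {
    "H": [0.4193, 0.4042, 0.3914, 0.3854, 0.3764, 0.3695, 0.3570, 0.3458,
          0.3355, 0.3260, 0.3091, 0.2944],
    "C": [19.07, 10.91, 4.576, 2.373, 0.8063, 0.4420, 0.2562, 0.2076,
          0.1871, 0.1753, 0.1610, 0.1514],
    "N": [31.33, 17.21, 7.562, 3.879, 1.236, 0.6178, 0.3066, 0.2288,
          0.1980, 0.1817, 0.1639, 0.1529],
    "O": [48.18, 24.85, 11.63, 5.952, 1.836, 0.8651, 0.3779, 0.2585,
          0.2132, 0.1907, 0.1678, 0.1551],
}


@dataclass(frozen=True)
class MaterialSpec:
    """A material: mass density (g/cm^3) and element mass fractions."""

    name: str
    density: float
    composition: tuple  # of (ElementSpec, mass fraction)

    def __post_init__(self):
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        if not self.composition:
            raise ValueError(f"material {self.name!r} has empty composition")
        w = np.array([wi for _, wi in self.composition], dtype=float)
        if np.any(w <= 0):
            raise ValueError(f"mass fractions must be positive in {self.name!r}")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {w.sum()!r}, not 1"
            )

    def with_density(self, density: float, name: str | None = None) -> "MaterialSpec":
        return MaterialSpec(name or self.name, density, self.composition)


@dataclass(frozen=True)
class OpticalConstants:
    """delta, beta (dimensionless) and mu (1/cm) at one photon energy (keV)."""

    delta: float
    beta: float
    mu: float
    energy: float


def parse_formula(formula: str) -> tuple:
    """Parse a chemical formula like ``C8H8`` into mass fractions.

    Returns a composition tuple of (ElementSpec, w_i) suitable for
    :class:`MaterialSpec`.
    """
    import re

    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    counts: dict[str, float] = {}
    parsed = ""
    for sym, num in tokens:
        if not sym:
            continue
        if sym not in ELEMENTS:
            raise ValueError(f"unsupported element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0.0) + (float(num) if num else 1.0)
        parsed += sym + num
    if parsed != formula.replace(" ", ""):
        raise ValueError(f"could not parse formula {formula!r}")
    if not counts:
        raise ValueError(f"empty formula {formula!r}")
    masses = {s: n * ELEMENTS[s].A for s, n in counts.items()}
    total = sum(masses.values())
    return tuple((ELEMENTS[s], m / total) for s, m in sorted(masses.items()))


def mix_materials(parts, density: float, name: str) -> MaterialSpec:
    """Mix materials by mass fraction; density must be supplied (measured)."""
    acc: dict[str, float] = {}
    wsum = 0.0
    for mat, w in parts:
        wsum += w
        for el, wi in mat.composition:
            acc[el.symbol] = acc.get(el.symbol, 0.0) + w * wi
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions sum to {wsum}, not 1")
    comp = tuple((ELEMENTS[s], w) for s, w in sorted(acc.items()))
    return MaterialSpec(name, density, comp)


def _water():
    return MaterialSpec("water", 0.9982, parse_formula("H2O"))


def _ethanol():
    return MaterialSpec("ethanol", 0.7893, parse_formula("C2H6O"))


def _build_library() -> dict[str, MaterialSpec]:
    water = _water()
    ethanol = _ethanol()
    lib = {
        "water": water,
        "ethanol": ethanol,
        # water-ethanol mixtures by mass; densities are the measured Table
        # values of the phantom liquids, not volume-additive estimates.
        "ethanol33": mix_materials(
            [(ethanol, 1.0 / 3.0), (water, 2.0 / 3.0)], 0.9487, "ethanol33"),
        "ethanol50": mix_materials(
            [(ethanol, 0.5), (water, 0.5)], 0.9143, "ethanol50"),
        "ethanol66": mix_materials(
            [(ethanol, 2.0 / 3.0), (water, 1.0 / 3.0)], 0.8749, "ethanol66"),
        "polystyrene": MaterialSpec("polystyrene", 1.04, parse_formula("C8H8")),
        "polypropylene": MaterialSpec("polypropylene", 0.905, parse_formula("C3H6")),
        "pmma": MaterialSpec("pmma", 1.19, parse_formula("C5H8O2")),
        # dry air without the trace argon (no Ar data embedded); background
        # medium only, where its attenuation/refraction are negligible.
        "air": MaterialSpec("air", 1.205e-3,
                            ((ELEMENTS["N"], 0.765), (ELEMENTS["O"], 0.235))),
    }
    return lib


MATERIALS: dict[str, MaterialSpec] = _build_library()

#: Sentinel for empty space: zero density (delta = beta = mu = 0 by linearity).
VACUUM = MaterialSpec("vacuum", 0.0, ((ELEMENTS["H"], 1.0),))
# MaterialSpec forbids density<0 only; density==0 is the vacuum limit.
MATERIALS["vacuum"] = VACUUM


def get_material(name: str) -> MaterialSpec:
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(MATERIALS)}") from None


def material_from_dict(d: dict) -> MaterialSpec:
    """Build a material from a config mapping.

    Either ``{"name": ..., "density": ..., "formula": "C8H8"}`` or an
    explicit ``"composition": {"C": 0.92, "H": 0.08}``.
    """
    name = d["name"]
    density = float(d["density"])
    if "formula" in d:
        comp = parse_formula(d["formula"])
    else:
        comp = tuple((ELEMENTS[s], float(w)) for s, w in sorted(d["composition"].items()))
    return MaterialSpec(name, density, comp)


# ---------------------------------------------------------------------------
# Cross sections
# ---------------------------------------------------------------------------

def klein_nishina_total(energy_kev) -> np.ndarray:
    """Total Klein-Nishina cross section per free electron (cm^2)."""
    k = np.asarray(energy_kev, dtype=float) / M_E_C2_KEV
    t = 1.0 + 2.0 * k
    lg = np.log(t)
    sigma = (2.0 * np.pi * R_ELECTRON_CM**2) * (
        (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - lg / k)
        + lg / (2.0 * k)
        - (1.0 + 3.0 * k) / t**2
    )
    return sigma


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)


def rayleigh_cross_section(element: ElementSpec, energy_kev) -> np.ndarray:
    """Coherent (Rayleigh) cross section per atom (cm^2), form-factor model.

    sigma_R = pi r_e^2 * integral (1 + mu^2) F(q)^2 dmu over mu = cos(theta).
    """
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    lam_a = HC_KEV_NM * 10.0 / e  # wavelength in Angstrom
    mu = _GL_NODES
    s = np.sqrt((1.0 - mu) / 2.0)[None, :] / lam_a[:, None]
    f2 = element.form_factor(s) ** 2
    integ = np.sum(_GL_WEIGHTS[None, :] * (1.0 + mu**2)[None, :] * f2, axis=1)
    out = np.pi * R_ELECTRON_CM**2 * integ
    return out if np.ndim(energy_kev) else float(out[0])


def _loglog_interp(x, xp, fp):
    """Piecewise log-log linear interpolation with slope extrapolation."""
    lx, lxp, lfp = np.log(x), np.log(xp), np.log(fp)
    out = np.interp(lx, lxp, lfp)
    lo = lx < lxp[0]
    hi = lx > lxp[-1]
    if np.any(lo):
        s = (lfp[1] - lfp[0]) / (lxp[1] - lxp[0])
        out = np.where(lo, lfp[0] + s * (lx - lxp[0]), out)
    if np.any(hi):
        s = (lfp[-1] - lfp[-2]) / (lxp[-1] - lxp[-2])
        out = np.where(hi, lfp[-1] + s * (lx - lxp[-1]), out)
    return np.exp(out)


@dataclass
class CrossSectionSet:
    """Per-element photoelectric/Compton/Rayleigh mass coefficients (cm^2/g).

    Tabulated on a dense log-spaced energy grid over 1-100 keV (>= 20 points
    per decade); queries interpolate each channel log-log.
    """

    energies: np.ndarray
    tables: dict = field(default_factory=dict)  # symbol -> (pe, compton, rayleigh)

    def channels(self, symbol: str, energy_kev):
        """(photoelectric, compton, rayleigh) mass coefficients at energy."""
        e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
        if np.any(e < ENERGY_RANGE_KEV[0]) or np.any(e > ENERGY_RANGE_KEV[1]):
            raise ValueError(
                f"energy {energy_kev} keV outside supported range {ENERGY_RANGE_KEV}")
        pe, co, ra = self.tables[symbol]
        out = tuple(_loglog_interp(e, self.energies, t) for t in (pe, co, ra))
        if np.ndim(energy_kev) == 0:
            return tuple(float(o[0]) for o in out)
        return out

    def total(self, symbol: str, energy_kev):
        pe, co, ra = self.channels(symbol, energy_kev)
        return pe + co + ra


def build_cross_sections(n_per_decade: int = 40) -> CrossSectionSet:
    """Construct the default cross-section set (see module docstring)."""
    grid = np.geomspace(ENERGY_RANGE_KEV[0], ENERGY_RANGE_KEV[1],
                        int(2 * n_per_decade) + 1)
    tables = {}
    for sym, el in ELEMENTS.items():
        per_gram = N_AVOGADRO / el.A
        # channels at the anchor energies
        co_anchor = per_gram * el.Z * klein_nishina_total(_ANCHOR_KEV)
        ra_anchor = per_gram * rayleigh_cross_section(el, _ANCHOR_KEV)
        total_anchor = np.asarray(_ANCHOR_MU_RHO[sym])
        pe_anchor = np.clip(total_anchor - co_anchor - ra_anchor, 1e-8, None)
        # dense grid: photoelectric interpolated (near power law), the
        # scattering channels evaluated directly
        pe = _loglog_interp(grid, _ANCHOR_KEV, pe_anchor)
        co = per_gram * el.Z * klein_nishina_total(grid)
        ra = per_gram * rayleigh_cross_section(el, grid)
        tables[sym] = (pe, co, ra)
    return CrossSectionSet(grid, tables)


_DEFAULT_XS: CrossSectionSet | None = None


def default_cross_sections() -> CrossSectionSet:
    global _DEFAULT_XS
    if _DEFAULT_XS is None:
        _DEFAULT_XS = build_cross_sections()
    return _DEFAULT_XS


# ---------------------------------------------------------------------------
# Optical constants
# ---------------------------------------------------------------------------

def electron_density(material: MaterialSpec) -> float:
    """Electron density in 1/m^3: rho * N_A * sum w_i Z_i / A_i."""
    z_over_a = sum(w * el.Z / el.A for el, w in material.composition)
    return material.density * N_AVOGADRO * z_over_a * 1e6  # 1/cm^3 -> 1/m^3


def compute_delta(material: MaterialSpec, energy_kev: float) -> float:
    """Refractive index decrement delta at ``energy_kev`` (f1 ~ Z).

    Equals r_e lambda^2 n_e / (2 pi); exact linear in density and lambda^2.
    Not valid near absorption edges (none in 1-100 keV for H/C/N/O).
    """
    lam = wavelength_from_energy(energy_kev)
    return R_ELECTRON_M * lam**2 * electron_density(material) / (2.0 * np.pi)


def compute_mu(material: MaterialSpec, energy_kev: float,
               xs: CrossSectionSet | None = None) -> float:
    """Linear attenuation coefficient (1/cm) at ``energy_kev`` in 1-100 keV."""
    if xs is None:
        xs = default_cross_sections()
    if material.density == 0.0:
        # still validate the energy
        xs.channels("H", energy_kev)
        return 0.0
    mu_rho = sum(w * xs.total(el.symbol, energy_kev)
                 for el, w in material.composition)
    return material.density * mu_rho


def compute_beta(mu_per_cm: float, energy_kev: float) -> float:
    """beta = mu * lambda / (4 pi); mu in 1/cm."""
    mu = np.asarray(mu_per_cm, dtype=float)
    if np.any(mu < 0):
        raise ValueError(f"mu must be >= 0, got {mu_per_cm}")
    lam_cm = wavelength_from_energy(energy_kev) * 100.0
    out = mu * lam_cm / (4.0 * np.pi)
    return float(out) if np.isscalar(mu_per_cm) else out


def mu_from_beta(beta: float, energy_kev: float) -> float:
    """Inverse of :func:`compute_beta`: mu = 4 pi beta / lambda (1/cm)."""
    lam_cm = wavelength_from_energy(energy_kev) * 100.0
    return 4.0 * np.pi * beta / lam_cm


def optical_constants(material: MaterialSpec, energy_kev: float,
                      xs: CrossSectionSet | None = None) -> OpticalConstants:
    mu = compute_mu(material, energy_kev, xs)
    return OpticalConstants(
        delta=compute_delta(material, energy_kev),
        beta=compute_beta(mu, energy_kev),
        mu=mu,
        energy=float(energy_kev),
    )
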