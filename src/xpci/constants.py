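"""Physical constants (CODATA 2018 values, in the units used package-wide).

Energies are keV, lengths metres unless a name says otherwise; attenuation
coefficients are 1/cm because that is how the imaging literature tabulates
them.
"""

#: hc in keV*nm; divide by energy in keV to get wavelength in nm.
HC_KEV_NM = 1.23984198

#: Classical electron radius (m).
R_ELECTRON_M = 2.8179403e-15

#: Classical electron radius (cm), for cross sections in cm^2.
R_ELECTRON_CM = 2.8179403e-13

#: Avogadro's number (1/mol).
N_AVOGADRO = 6.02214076e23

#: Electron rest energy (keV).
M_E_C2_KEV = 510.99895


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in metres for an energy in keV.

    lambda = hc/E.  Raises ``ValueError`` for non-positive energies.
    """
    import numpy as np

    e = np.asarray(energy_kev, dtype=float)
    if np.any(e <= 0):
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    out = HC_KEV_NM / e * 1e-9
    return float(out) if np.isscalar(energy_kev) else out


def wavenumber_from_energy(energy_kev: float) -> float:
    """k = 2*pi/lambda in 1/m."""
    import numpy as np

    return 2.0 * np.pi / wavelength_from_energy(energy_kev)
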