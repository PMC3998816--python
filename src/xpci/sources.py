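"""Photon source models: coherence encoded in initial position/direction/phase.

A perfectly coherent plane wave is a set of photons sharing direction and
initial phase; a point source is a fan of directions from one point; partial
spatial coherence arises when photons that arrive at the same place may have
started from different source points, so their optical path lengths differ.

Photons are initialized on the sample entrance plane.  For divergent
sources the geometric path difference from the source point x_s over the
source-to-sample distance R is carried as an initial phase
-k (x - x_s)^2 / (2R) (paraxial), which is the "assign an initial phase"
coherence option: the transport stage itself only accumulates the
material-induced phase k*delta*ds, so source-geometry phase must enter at
initialization.  Only horizontal (x) coherence is modelled; y is passive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import wavenumber_from_energy

__all__ = ["SourceSpec", "PhotonInit", "sample_photons", "sample_photon",
           "sample_source_positions", "effective_source_width"]

KINDS = ("plane", "point", "partial-uniform", "partial-gaussian")


@dataclass(frozen=True)
class SourceSpec:
    """Monochromatic source description.

    width: transverse extent for plane/partial-uniform (full width, m) or
        the Gaussian second moment (standard deviation, m) for
        partial-gaussian.
    divergence: full angular fan (rad) for a point source.
    distance: source-to-sample distance R (m) for divergent kinds.
    roi_width: transverse extent illuminated at the entrance plane (m); for
        the plane kind this doubles as the beam width if ``width`` is 0.
    center: transverse offset of the illuminated region (m).
    z0: entrance-plane z (m).
    """

    kind: str
    energy: float  # keV
    width: float = 0.0
    divergence: float = 0.0
    distance: float = 25.0
    roi_width: float = 1e-3
    center: float = 0.0
    z0: float = 0.0
    n: int = 1

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}; known {KINDS}")
        if self.width < 0 or self.divergence < 0 or self.n < 1:
            raise ValueError("width/divergence must be >= 0 and n >= 1")


@dataclass
class PhotonInit:
    """Arrays of initial photon states (positions m, unit directions, keV)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    energy: np.ndarray
    weight: np.ndarray
    opl: np.ndarray  # initial optical path length / phase (rad)

    def __len__(self):
        return len(self.x)


def sample_source_positions(spec: SourceSpec, n: int, rng) -> np.ndarray:
    """Draw source-plane transverse positions x_s (m)."""
    if spec.kind == "partial-gaussian":
        return rng.normal(0.0, spec.width, n)
    if spec.kind == "partial-uniform":
        return rng.uniform(-spec.width / 2, spec.width / 2, n)
    if spec.kind == "point":
        return np.zeros(n)
    return spec.center + rng.uniform(-self_width(spec) / 2, self_width(spec) / 2, n)


def self_width(spec: SourceSpec) -> float:
    return spec.width if spec.width > 0 else spec.roi_width


def sample_photons(spec: SourceSpec, n: int, rng) -> PhotonInit:
    """Sample ``n`` initial photon states on the entrance plane z = z0."""
    k = wavenumber_from_energy(spec.energy)
    y = np.zeros(n)
    z = np.full(n, spec.z0)
    energy = np.full(n, float(spec.energy))
    weight = np.ones(n)
    if spec.kind == "plane":
        x = spec.center + rng.uniform(-self_width(spec) / 2, self_width(spec) / 2, n)
        theta = np.zeros(n)
        opl = np.zeros(n)
    elif spec.kind == "point":
        if spec.divergence > 0:
            theta = rng.uniform(-spec.divergence / 2, spec.divergence / 2, n)
            x = spec.center + spec.distance * np.tan(theta)
        else:
            theta = (spec.center
                     + rng.uniform(-spec.roi_width / 2, spec.roi_width / 2, n)
                     ) / spec.distance
            x = spec.center + spec.distance * theta
        opl = -k * (x - spec.center) ** 2 / (2.0 * spec.distance)
    else:  # partial coherence
        xs = sample_source_positions(spec, n, rng)
        x = spec.center + rng.uniform(-spec.roi_width / 2, spec.roi_width / 2, n)
        theta = (x - xs) / spec.distance
        opl = -k * (x - xs) ** 2 / (2.0 * spec.distance)
    dx = np.sin(np.arctan(theta)) if spec.kind != "plane" else np.zeros(n)
    dz = np.sqrt(1.0 - dx**2)
    return PhotonInit(x, y, z, dx, np.zeros(n), dz, energy, weight, opl)


def sample_photon(spec: SourceSpec, rng) -> PhotonInit:
    """A single initial photon state (batch of one)."""
    return sample_photons(spec, 1, rng)


def effective_source_width(spec: SourceSpec, roi_width: float,
                           sample_depth: float = 0.0,
                           max_scatter_angle: float = 0.2,
                           margin: float | None = None) -> float:
    """Beam width needed so in-scatter into the scored slice is captured.

    Pads the region of interest by the maximum transverse displacement a
    scattered photon can acquire (sample depth times the tangent of the
    largest scattering angle considered), on both sides.
    """
    if roi_width <= 0:
        raise ValueError("roi_width must be positive")
    if margin is None:
        margin = sample_depth * math.tan(max_scatter_angle)
    return max(spec.width, roi_width + 2.0 * margin)
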