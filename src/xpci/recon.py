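"""Sinograms and parallel-beam filtered back-projection.

Projections of the three contrast modalities become sinograms of line
integrals: -ln T for mu, the integrated wavefront phase over -k for the
projected delta, and -ln D for the dark-field extinction.  Reconstruction
is textbook parallel-beam FBP (ramp filter, Hann option) scaled so that
reconstructed values come out in physical units (e.g. 1/cm when the
sinogram holds -ln T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import iradon

from .retrieval import integrate_phase, unwrap_despike

logger = logging.getLogger(__name__)

__all__ = ["Sinogram", "SliceImage", "fbp_reconstruct", "reconstruct_mu",
           "reconstruct_delta", "reconstruct_darkfield", "affine_calibrate",
           "disc_mean"]

_FILTERS = {"ram-lak": "ramp", "ramp": "ramp", "hann": "hann"}


@dataclass
class Sinogram:
    """values[angle, pixel] of line integrals; angles in degrees over [0, 180)."""

    values: np.ndarray
    angles_deg: np.ndarray
    pixel_size: float  # m
    modality: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.angles_deg = np.asarray(self.angles_deg, float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.angles_deg):
            raise ValueError("sinogram must be (n_angles, n_pixels)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")
        d = np.diff(self.angles_deg)
        if len(d) and not np.allclose(d, d[0]):
            raise ValueError("angles must be uniformly spaced")


@dataclass
class SliceImage:
    """Reconstructed 2D coefficient map with its pixel size (m)."""

    values: np.ndarray
    pixel_size: float
    modality: str = ""


def fbp_reconstruct(s: Sinogram, filter_name: str = "ram-lak") -> SliceImage:
    """Filtered back-projection of a parallel-beam sinogram.

    Output units: sinogram units per cm of path (line integrals taken in
    units consistent with a path measured in cm; -ln T sinograms therefore
    reconstruct mu in 1/cm).
    """
    if len(s.angles_deg) < 2:
        raise ValueError("need at least 2 projection angles")
    recon = iradon(s.values.T, theta=s.angles_deg,
                   filter_name=_FILTERS[filter_name], circle=False,
                   output_size=s.values.shape[1])
    # iradon treats the path variable in pixel units; convert to 1/cm
    recon = recon / (s.pixel_size * 100.0)
    return SliceImage(recon, s.pixel_size, s.modality)


def reconstruct_mu(transmission, angles_deg, pixel_size,
                   filter_name="ram-lak") -> SliceImage:
    """mu map (1/cm) from transmission projections T[angle, pixel]."""
    t = np.asarray(transmission, float)
    bad = t <= 0
    if np.any(bad):
        logger.info("masking %d nonpositive transmission pixels", bad.sum())
        t = np.where(bad, 1.0, t)
    sino = Sinogram(-np.log(t), angles_deg, pixel_size, "mu")
    return fbp_reconstruct(sino, filter_name)


def reconstruct_delta(dphi, angles_deg, pixel_size, p2, d, k,
                      margin: int = 0, filter_name="ram-lak") -> SliceImage:
    """delta map from fringe-shift projections dphi[angle, pixel].

    Per angle: resolve 2*pi-aliased pixels, integrate to the wavefront
    phase Phi (closure-anchored in both sample-free margins), and form the
    line-integral sinogram -Phi/k = integral(delta dz); FBP then returns
    delta (dimensionless).
    """
    dphi = unwrap_despike(np.asarray(dphi, float))
    phi = integrate_phase(dphi, p2, d, k, pixel_size, margin=margin,
                          anchor="both")
    delta_bar = -phi / k  # m of projected delta
    # fbp scales by path-in-cm; delta_bar is per metre of path
    sino = Sinogram(delta_bar * 100.0, angles_deg, pixel_size, "delta")
    return fbp_reconstruct(sino, filter_name)


def reconstruct_darkfield(darkfield, angles_deg, pixel_size,
                          filter_name="ram-lak") -> SliceImage:
    """Dark-field extinction map (1/cm of -ln D) from visibility ratios."""
    dfield = np.asarray(darkfield, float)
    bad = dfield <= 0
    if np.any(bad):
        logger.info("masking %d nonpositive dark-field pixels", bad.sum())
        dfield = np.where(bad, 1.0, dfield)
    sino = Sinogram(-np.log(dfield), angles_deg, pixel_size, "darkfield")
    return fbp_reconstruct(sino, filter_name)


def affine_calibrate(img: SliceImage, pair1, pair2) -> SliceImage:
    """Two-point affine calibration (measured, true) -> calibrated copy.

    Optional postprocess mirroring calibration against two known materials;
    raw values are never modified in place.
    """
    (m1, t1), (m2, t2) = pair1, pair2
    if m1 == m2:
        raise ValueError("calibration points must differ")
    a = (t2 - t1) / (m2 - m1)
    b = t1 - a * m1
    return SliceImage(a * img.values + b, img.pixel_size,
                      img.modality + "+calibrated")


def disc_mean(img: SliceImage, center_xy=(0.0, 0.0), radius=None,
              fraction: float = 0.7) -> float:
    """Mean of a slice inside a centred disc (physical coordinates, m).

    ``radius=None`` uses ``fraction`` of the half field of view; used for
    region statistics (interior plateau means).
    """
    n = img.values.shape[0]
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:img.values.shape[1]]
    x = (xx - c) * img.pixel_size
    y = (yy - (img.values.shape[0] - 1) / 2.0) * img.pixel_size
    if radius is None:
        radius = fraction * c * img.pixel_size
    m = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius**2
    return float(img.values[m].mean())
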