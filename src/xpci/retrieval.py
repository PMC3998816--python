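"""Fourier retrieval of transmission, differential phase and dark-field.

A phase-stepping scan gives, per pixel, M intensities over one analyzer
period: a sinusoid-like curve with mean a0, first-harmonic amplitude a1 and
phase phi.  Comparing a sample scan to a reference scan yields the three
contrast modalities:

    T    = a0_s / a0_r              (transmission)
    dphi = wrap(phi_s - phi_r)      (fringe phase shift)
    D    = (a1_s/a0_s)/(a1_r/a0_r)  (visibility ratio = dark-field)

The fringe shift is proportional to the refraction angle,
alpha = dphi * p2 / (2 pi d), and the wavefront phase Phi follows by
integration of d(Phi)/dx = k * alpha.  Package-wide sign convention:
Phi = -k * integral(delta dz), so the projected decrement delta_bar is
recovered as -Phi/k; in this geometry a positive fringe phase shift
corresponds to a deflection toward -x, which the integration step absorbs
(verified against the analytic wedge deviation in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ContrastTriplet", "fourier_coefficients", "extract_contrasts",
           "refraction_angle", "integrate_phase", "wrap_phase"]


@dataclass
class ContrastTriplet:
    """Per-pixel transmission, fringe phase shift (rad) and dark-field."""

    transmission: np.ndarray
    dphi: np.ndarray
    darkfield: np.ndarray
    valid: np.ndarray  # False where the reference carried no signal


def wrap_phase(phi):
    """Wrap to (-pi, pi]."""
    return -np.mod(-np.asarray(phi) + np.pi, 2 * np.pi) + np.pi


def fourier_coefficients(curve, steps=None):
    """(a0, a1, phi) of stepping curves (last axis = the M steps).

    a0 is the mean, a1 the first-harmonic amplitude, phi its phase from the
    discrete Fourier transform; exact to machine precision for any curve
    containing only harmonics 0 and 1.  ``steps``, if given, must be
    equidistant over one period.
    """
    curve = np.asarray(curve, dtype=float)
    m = curve.shape[-1]
    if m < 3:
        raise ValueError("need at least 3 phase steps")
    if steps is not None:
        steps = np.asarray(steps, float)
        d = np.diff(steps)
        if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise ValueError("phase steps must be equidistant")
    phase = np.exp(-2j * np.pi * np.arange(m) / m)
    c1 = (2.0 / m) * np.sum(curve * phase, axis=-1)
    a0 = curve.mean(axis=-1)
    return a0, np.abs(c1), np.angle(c1)


def extract_contrasts(sample, reference) -> ContrastTriplet:
    """Contrast triplet from sample and reference stepping curves.

    Both arrays share the step axis (last).  Pixels whose reference has
    zero mean or zero modulation are flagged invalid (values set to the
    neutral 1/0/1, not NaN).
    """
    sample = np.asarray(sample, float)
    reference = np.asarray(reference, float)
    if sample.shape != reference.shape:
        raise ValueError("sample and reference scans must share a step grid")
    a0s, a1s, ps = fourier_coefficients(sample)
    a0r, a1r, pr = fourier_coefficients(reference)
    valid = (a0r > 0) & (a1r > 0) & (a0s > 0)
    n_bad = int(np.sum(~valid))
    if n_bad:
        logger.info("%d pixels flagged invalid in contrast extraction", n_bad)
    a0r_s = np.where(valid, a0r, 1.0)
    a1r_s = np.where(a1r > 0, a1r, 1.0)
    t = np.where(valid, a0s / a0r_s, 1.0)
    dphi = np.where(valid, wrap_phase(ps - pr), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vis_s = np.where(a0s > 0, a1s / np.where(a0s > 0, a0s, 1.0), 0.0)
        vis_r = a1r_s / a0r_s
    d = np.where(valid, vis_s / vis_r, 1.0)
    return ContrastTriplet(t, dphi, d, valid)


def unwrap_despike(dphi):
    """Resolve isolated 2*pi-aliased pixels in fringe-shift profiles.

    At a strong edge the true fringe shift can sweep past pi inside a
    single detector pixel; the reported pixel value is then aliased by a
    multiple of 2*pi, which a greedy running unwrap cannot repair (the
    jump in and out of the pixel are both below threshold after wrapping).
    Each pixel is compared with the average of its neighbours and shifted
    by the nearest multiple of 2*pi; noise (<< pi) never triggers a shift.
    Works along the last axis.  Profiles that genuinely exceed pi over
    many consecutive pixels are outside this scheme (documented limit for
    smooth phantoms).
    """
    out = np.array(dphi, dtype=float, copy=True)
    n = out.shape[-1]
    for j in range(1, n - 1):
        pred = 0.5 * (out[..., j - 1] + dphi[..., j + 1])
        m = np.round((out[..., j] - pred) / (2 * np.pi))
        out[..., j] -= 2 * np.pi * m
    return out


def refraction_angle(dphi, p2: float, d: float):
    """Refraction angle magnitude relation alpha = dphi * p2 / (2 pi d)."""
    if d <= 0:
        raise ValueError("inter-grating distance must be positive")
    return np.asarray(dphi) * p2 / (2.0 * np.pi * d)


def integrate_phase(dphi, p2: float, d: float, k: float, pixel_width: float,
                    margin: int = 0, anchor: str = "left"):
    """Wavefront phase Phi(x) (rad) from a fringe-shift profile.

    ``dphi`` must be free of wrap artifacts along x (see
    :func:`unwrap_despike`).  d(Phi)/dx = k * alpha with the sign
    convention stated in the module docstring; the cumulative integral is
    anchored to Phi = 0 in the first ``margin`` (sample-free) pixels.
    ``anchor="both"`` additionally removes the linear ramp between the two
    sample-free margins, enforcing the physical closure Phi = 0 on either
    side of the sample (suppresses drift from noise and residual edge
    aliasing).  With ``margin=0`` the anchor is the left edge (warned:
    absolute phase is then only defined up to the edge value).
    """
    alpha = -refraction_angle(np.asarray(dphi, float), p2, d)
    phi = k * np.cumsum(alpha, axis=-1) * pixel_width
    if margin > 0:
        left = phi[..., :margin].mean(axis=-1, keepdims=True)
        if anchor == "both":
            n = phi.shape[-1]
            right = phi[..., -margin:].mean(axis=-1, keepdims=True)
            il = (margin - 1) / 2.0
            ir = n - 1 - (margin - 1) / 2.0
            ramp = (np.arange(n) - il) / (ir - il)
            phi = phi - left - (right - left) * ramp
        else:
            phi = phi - left
    else:
        logger.warning("no sample-free margin given; phase anchored at left edge")
    return phi
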