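"""Monogenic-signal analysis.

The monogenic signal extends the 1-D analytic signal to images: a
band-passed input ``I`` together with its two Riesz-transform components
``(Re RI, Im RI)`` forms a 3-valued vector from which local amplitude,
local phase and local orientation follow:

* ``amplitude = sqrt(I^2 + (Re RI)^2 + (Im RI)^2)`` — phase-invariant
  local contrast;
* ``phase`` classifies the local contour type: values near 0 mark bright
  lines (ridges), near +/-pi dark lines, near +/-pi/2 edges;
* ``orientation`` is the local axis of variation, folded to [-90, 90).

The band-pass is an isotropic log-Gabor filter (two-octave bandwidth)
centred at the requested spatial scale; it removes DC, so the Riesz
components are mean-free and the phase model is well defined at a single,
explicitly chosen scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .image import RasterImage


@dataclass(frozen=True)
class MonogenicField:
    """Band-passed signal, Riesz pair, and derived amplitude/phase/orientation."""

    i_bp: np.ndarray
    r_re: np.ndarray
    r_im: np.ndarray
    amplitude: np.ndarray
    phase_rad: np.ndarray
    orientation_deg: np.ndarray
    scale_px: float


# two-octave bandwidth for the log-Gabor radial profile: the ratio
# sigma/f0 giving FWHM of 2 octaves is ~0.55 (standard value)
_SIGMA_ON_F = 0.55


def _log_gabor(shape: tuple[int, int], scale_px: float) -> np.ndarray:
    ny, nx = shape
    u = scipy.fft.fftfreq(nx)[None, :]
    v = scipy.fft.fftfreq(ny)[:, None]
    radius = np.hypot(u, v)
    radius[0, 0] = 1.0
    f0 = 1.0 / scale_px
    lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(_SIGMA_ON_F) ** 2))
    lg[0, 0] = 0.0  # no DC
    return lg


def monogenic_transform(img: RasterImage | np.ndarray, scale_px: float = 8.0) -> MonogenicField:
    """Single-scale monogenic decomposition of an image.

    ``scale_px`` is the centre wavelength of the isotropic log-Gabor
    band-pass in pixels (must satisfy ``1 <= scale_px <= min(shape)/2``).
    """
    px = img.as_float() if isinstance(img, RasterImage) else np.asarray(img, dtype=float)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    if scale_px < 1:
        raise ValueError("scale_px must be >= 1")
    if scale_px > min(px.shape) / 2:
        raise ValueError("scale_px exceeds half the image size")

    pad = min(64, min(px.shape) // 2)
    padded = np.pad(px, pad, mode="reflect")
    F = scipy.fft.fft2(padded)
    lg = _log_gabor(padded.shape, scale_px)

    ny, nx = padded.shape
    u = scipy.fft.fftfreq(nx)[None, :]
    v = scipy.fft.fftfreq(ny)[:, None]
    norm = np.hypot(u, v)
    norm[0, 0] = 1.0
    hx = -1j * u / norm
    hy = -1j * v / norm
    hx[0, 0] = 0.0
    hy[0, 0] = 0.0

    Fbp = F * lg
    i_bp = scipy.fft.ifft2(Fbp).real
    r_re = scipy.fft.ifft2(Fbp * hx).real
    r_im = scipy.fft.ifft2(Fbp * hy).real
    sl = (slice(pad, -pad), slice(pad, -pad)) if pad else (slice(None), slice(None))
    i_bp, r_re, r_im = i_bp[sl], r_re[sl], r_im[sl]

    riesz_mag = np.hypot(r_re, r_im)
    amplitude = np.sqrt(i_bp * i_bp + r_re * r_re + r_im * r_im)
    # unsigned phase in [0, pi]; signed by the Riesz y-component so the
    # full range [-pi, pi] distinguishes the two edge polarities
    phase = np.arctan2(riesz_mag, i_bp)
    sign = np.where(r_im < 0, -1.0, 1.0)
    phase_rad = phase * sign
    # local orientation: axis of the Riesz vector, y-up convention,
    # rotated 90 deg from the gradient-like direction to the structure axis
    orientation = np.degrees(np.arctan2(-r_im, r_re)) + 90.0
    orientation_deg = ((orientation + 90.0) % 180.0) - 90.0
    return MonogenicField(
        i_bp=i_bp,
        r_re=r_re,
        r_im=r_im,
        amplitude=amplitude,
        phase_rad=phase_rad,
        orientation_deg=orientation_deg,
        scale_px=float(scale_px),
    )


def enhance_modulus(
    amplitude: np.ndarray,
    clip_percentiles: tuple[float, float] = (0.5, 99.5),
    gamma: float = 0.5,
) -> np.ndarray:
    """Contrast-enhance a monogenic modulus map for display.

    Percentile-clips the (typically very low-contrast) amplitude map and
    applies a gamma < 1 compression; the mapping is monotone, so ordering
    of amplitudes (in particular the argmax) is preserved.  All-zero input
    yields all-zero output.
    """
    amp = np.asarray(amplitude, dtype=float)
    if np.any(amp < 0):
        raise ValueError("amplitude must be non-negative")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if amp.max() == 0:
        return np.zeros_like(amp)
    lo, hi = np.percentile(amp, clip_percentiles)
    if hi <= lo:
        lo, hi = amp.min(), amp.max()
    out = np.clip((amp - lo) / (hi - lo), 0.0, 1.0)
    # strictly monotone tie-break within the clipped ranges
    out = out ** gamma
    eps = 1e-12 / max(amp.max(), 1.0)
    return out + eps * amp
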