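"""Gradient structure-tensor analysis with a Riesz-filter gradient.

Per-pixel local orientation, energy and coherency of a grey-level image:

* the gradient is obtained with the Riesz filter pair, a translation-,
  rotation- and scale-invariant frequency-domain operator (transfer
  functions ``-i*u/|w|`` and ``-i*v/|w|``, zero at DC);
* the structure tensor is the Gaussian-windowed outer product of the
  gradient: ``J = W * (g g^T)``;
* energy ``E = Jxx + Jyy`` is the trace of the tensor (magnitude of local
  gradient activity), and coherency
  ``C = sqrt((Jxx - Jyy)^2 + 4 Jxy^2) / (Jxx + Jyy)`` is the normalized
  eigenvalue difference: C = 1 for a strongly elongated (oriented) local
  structure, C = 0 for local isotropy.

Angle convention: orientation of the *structure* (the line direction,
perpendicular to the dominant gradient), in degrees, counterclockwise
positive with 0 deg along the image horizontal axis, folded to [-90, 90).
Coherency is undefined (NaN) where the energy vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy import ndimage

from .image import RasterImage


@dataclass(frozen=True)
class TensorField:
    """Smoothed structure-tensor components and derived maps."""

    jxx: np.ndarray
    jxy: np.ndarray
    jyy: np.ndarray
    orientation_deg: np.ndarray
    energy: np.ndarray
    coherency: np.ndarray  # NaN where energy ~ 0
    window_sigma_px: float
    pixel_size_um: float = 1.0

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of pixels where coherency is defined."""
        return np.isfinite(self.coherency)

    def interior(self, margin_px: int | None = None) -> tuple[slice, slice]:
        """Slices excluding a boundary margin (default 2*sigma window)."""
        if margin_px is None:
            margin_px = int(np.ceil(2 * self.window_sigma_px)) + 2
        return (slice(margin_px, -margin_px or None), slice(margin_px, -margin_px or None))


@dataclass(frozen=True)
class HSBComposite:
    """Hue-saturation-brightness orientation composite as RGB in [0, 1].

    Hue encodes orientation, saturation encodes coherency, brightness the
    source fluorescence intensity.
    """

    rgb: np.ndarray


def _riesz_fft(img: np.ndarray, pad: int) -> tuple[np.ndarray, np.ndarray]:
    padded = np.pad(img, pad, mode="reflect") if pad else img
    F = scipy.fft.fft2(padded)
    ny, nx = padded.shape
    u = scipy.fft.fftfreq(nx)[None, :]
    v = scipy.fft.fftfreq(ny)[:, None]
    norm = np.hypot(u, v)
    norm[0, 0] = 1.0  # avoid 0/0; DC response forced to zero below
    hx = -1j * u / norm
    hy = -1j * v / norm
    hx[0, 0] = 0.0
    hy[0, 0] = 0.0
    gx = scipy.fft.ifft2(F * hx).real
    gy = scipy.fft.ifft2(F * hy).real
    if pad:
        gx = gx[pad:-pad, pad:-pad]
        gy = gy[pad:-pad, pad:-pad]
    return gx, gy


def riesz_gradient(img: RasterImage | np.ndarray, pad: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """First-order Riesz filter pair of an image.

    Returns ``(gx, gy)``, the responses to the transfer functions
    ``-i*u/||(u,v)||`` and ``-i*v/||(u,v)||`` (zero at DC), computed by FFT
    with mirror padding.  A constant image yields exact zeros.
    """
    px = img.as_float() if isinstance(img, RasterImage) else np.asarray(img, dtype=float)
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    if np.ptp(px) == 0:
        z = np.zeros_like(px)
        return z, z.copy()
    if pad is None:
        pad = min(64, min(px.shape) // 2)
    return _riesz_fft(px, pad)


def finite_difference_gradient(img: RasterImage | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradient; cross-check alternative to the Riesz pair."""
    px = img.as_float() if isinstance(img, RasterImage) else np.asarray(img, dtype=float)
    gy, gx = np.gradient(px)
    return gx, gy


def structure_tensor(
    gx: np.ndarray,
    gy: np.ndarray,
    window_sigma_px: float = 2.0,
    pixel_size_um: float = 1.0,
) -> TensorField:
    """Gaussian-windowed structure tensor of a gradient field.

    ``Jxx = W*(gx*gx)``, ``Jxy = W*(gx*gy)``, ``Jyy = W*(gy*gy)`` with W a
    normalized Gaussian of the given sigma (mirror-padded convolution).
    """
    if window_sigma_px <= 0:
        raise ValueError("window_sigma_px must be positive")
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    if gx.shape != gy.shape:
        raise ValueError("gradient components must share a shape")
    smooth = lambda a: ndimage.gaussian_filter(a, window_sigma_px, mode="mirror")
    jxx = smooth(gx * gx)
    jxy = smooth(gx * gy)
    jyy = smooth(gy * gy)
    energy = jxx + jyy
    np.maximum(energy, 0.0, out=energy)  # clip tiny negative round-off
    eps = 1e-12 * float(energy.max()) if energy.max() > 0 else np.inf
    defined = energy > eps
    coherency = np.full_like(energy, np.nan)
    np.divide(
        np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy * jxy),
        energy,
        out=coherency,
        where=defined,
    )
    coherency[defined] = np.clip(coherency[defined], 0.0, 1.0)
    # Line orientation, y-axis-up sign convention: the array row axis points
    # down, so flip the sign of the mixed term; +90 deg turns the dominant
    # gradient direction into the structure direction.
    orientation = 0.5 * np.arctan2(-2.0 * jxy, jxx - jyy) + np.pi / 2.0
    orientation_deg = np.degrees(orientation)
    orientation_deg = ((orientation_deg + 90.0) % 180.0) - 90.0
    return TensorField(
        jxx=jxx,
        jxy=jxy,
        jyy=jyy,
        orientation_deg=orientation_deg,
        energy=energy,
        coherency=coherency,
        window_sigma_px=float(window_sigma_px),
        pixel_size_um=pixel_size_um,
    )


def analyze_orientation(
    img: RasterImage,
    window_sigma_px: float = 2.0,
    gradient: str = "riesz",
) -> TensorField:
    """Full structure-tensor analysis of an image (gradient + windowing)."""
    if gradient == "riesz":
        gx, gy = riesz_gradient(img)
    elif gradient == "finite_difference":
        gx, gy = finite_difference_gradient(img)
    else:
        raise ValueError(f"unknown gradient operator {gradient!r}")
    return structure_tensor(gx, gy, window_sigma_px, pixel_size_um=img.pixel_size_um)


def hsb_composite(tf: TensorField, source: RasterImage | np.ndarray) -> HSBComposite:
    """Hue = orientation, saturation = coherency, brightness = source image."""
    import matplotlib.colors as mcolors

    src = source.as_float() if isinstance(source, RasterImage) else np.asarray(source, dtype=float)
    if src.shape != tf.orientation_deg.shape:
        raise ValueError("source shape does not match tensor field")
    hue = (tf.orientation_deg + 90.0) / 180.0
    sat = np.nan_to_num(tf.coherency, nan=0.0)
    lo, hi = src.min(), src.max()
    val = (src - lo) / (hi - lo) if hi > lo else np.zeros_like(src)
    hsv = np.stack([hue, sat, val], axis=-1)
    return HSBComposite(rgb=mcolors.hsv_to_rgb(hsv))


def energy_weighted_circular_mean(tf: TensorField, mask: np.ndarray | None = None) -> float:
    """Energy-weighted circular mean orientation (degrees, axial data)."""
    from .polar import circular_summary

    sel = tf.defined if mask is None else (tf.defined & mask)
    return circular_summary(
        tf.orientation_deg[sel], weights=tf.energy[sel]
    ).circular_mean_deg
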