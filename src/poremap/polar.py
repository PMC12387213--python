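"""Polar statistics of orientation fields.

Quantifies preferential alignment of actin-filament textures: polar
histograms of (a) the per-pixel orientation distribution of an image and
(b) the orientations of thresholded high-energy anisotropy features of the
structure-tensor energy map, with optional ROI restriction, energy
weighting and display scaling.  Orientations are axial (pi-periodic) data;
all circular summaries double the angles first, so a resultant length of 1
means perfect alignment and 0 means an isotropic orientation field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .orientation import TensorField


@dataclass(frozen=True)
class CircularSummary:
    """Axial circular summary statistics (computed on angle-doubled data)."""

    circular_mean_deg: float
    resultant_length: float

    @property
    def circular_variance(self) -> float:
        return 1.0 - self.resultant_length


def circular_summary(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> CircularSummary:
    """Mean orientation and resultant length of axial data in degrees.

    Angles are doubled (orientations, not directions), averaged as unit
    vectors, and the mean is halved back into [-90, 90).
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    if a.size == 0:
        return CircularSummary(circular_mean_deg=np.nan, resultant_length=0.0)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        return CircularSummary(circular_mean_deg=np.nan, resultant_length=0.0)
    z = np.sum(w * np.exp(2j * np.radians(a))) / total
    mean = np.degrees(np.angle(z)) / 2.0
    mean = ((mean + 90.0) % 180.0) - 90.0
    return CircularSummary(circular_mean_deg=float(mean), resultant_length=float(np.abs(z)))


@dataclass(frozen=True)
class OrientationHistogram:
    """Binned pi-periodic orientation distribution over [-90, 90)."""

    bin_edges_deg: np.ndarray
    weights: np.ndarray
    weighting: str = "none"  # {"none", "energy"}
    source: str = "image_orientations"  # or "energy_feature_orientations"
    roi: tuple[int, int, int, int] | None = None  # (row, col, height, width) px
    display_scale: float = 1.0
    summary: CircularSummary | None = None

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])

    @property
    def normalized(self) -> np.ndarray:
        t = self.weights.sum()
        return self.weights / t if t > 0 else self.weights.copy()

    def polar_angles_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Duplicate the half-turn histogram to [90, 270) for polar rendering."""
        c = self.bin_centers_deg
        return np.concatenate([c, c + 180.0]), np.tile(self.weights * self.display_scale, 2)


def high_energy_mask(
    tf: TensorField,
    method: str = "quantile",
    quantile: float = 0.95,
) -> tuple[np.ndarray, dict]:
    """Mask of high-energy anisotropy features (the "white" energy pixels).

    ``method='quantile'`` keeps the top ``1 - quantile`` fraction of energy
    values (default top 5%); ``method='otsu'`` uses Otsu's threshold on the
    energy map.  Returns the boolean mask and a provenance dict recording
    the method and threshold actually applied.
    """
    e = tf.energy
    if e.max() == 0:
        warnings.warn("energy map is identically zero; high-energy mask is empty")
        return np.zeros_like(e, dtype=bool), {"method": method, "threshold": np.inf}
    if method == "quantile":
        if not (0 < quantile < 1):
            raise ValueError("quantile must lie in (0, 1)")
        thr = float(np.quantile(e, quantile))
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(e))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return e > thr, {"method": method, "threshold": thr, "quantile": quantile}


def _roi_slices(roi: tuple[int, int, int, int], shape: tuple[int, int]) -> tuple[slice, slice]:
    r, c, h, w = roi
    if r < 0 or c < 0 or r + h > shape[0] or c + w > shape[1]:
        raise ValueError(f"ROI {roi} exceeds frame {shape}")
    return slice(r, r + h), slice(c, c + w)


def orientation_polar(
    tf: TensorField,
    mask: np.ndarray | None = None,
    roi: tuple[int, int, int, int] | None = None,
    weighting: str = "energy",
    n_bins: int = 72,
    source: str = "image_orientations",
) -> OrientationHistogram:
    """Polar histogram of orientations over selected pixels.

    ``mask`` restricts to feature pixels (e.g. the high-energy mask),
    ``roi`` to a rectangle ``(row, col, height, width)`` in pixels, and
    ``weighting='energy'`` weights each pixel by its tensor energy.
    Binning is wrap-aware over the axial range [-90, 90).
    """
    if weighting not in {"none", "energy"}:
        raise ValueError("weighting must be 'none' or 'energy'")
    sel = tf.defined.copy()
    if mask is not None:
        if mask.shape != sel.shape:
            raise ValueError("mask shape mismatch")
        sel &= mask.astype(bool)
    if roi is not None:
        keep = np.zeros_like(sel)
        keep[_roi_slices(roi, sel.shape)] = True
        sel &= keep
    angles = tf.orientation_deg[sel]
    w = tf.energy[sel] if weighting == "energy" else None
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    if angles.size == 0:
        warnings.warn("empty pixel selection; returning an empty histogram")
        weights = np.zeros(n_bins)
        summ = CircularSummary(np.nan, 0.0)
    else:
        folded = ((angles + 90.0) % 180.0) - 90.0
        weights, _ = np.histogram(folded, bins=edges, weights=w)
        summ = circular_summary(folded, weights=w)
    return OrientationHistogram(
        bin_edges_deg=edges,
        weights=weights.astype(float),
        weighting=weighting,
        source=source,
        roi=roi,
        summary=summ,
    )


def scale_for_display(h: OrientationHistogram, factor: float) -> OrientationHistogram:
    """Multiply histogram weights by ``factor`` for side-by-side polar plots.

    Only the displayed curve changes: the normalized view and the circular
    summary are invariant.  ``display_scale`` records the cumulative factor.
    """
    if factor <= 0:
        raise ValueError("display scale factor must be positive")
    return replace(
        h,
        weights=h.weights * factor,
        display_scale=h.display_scale * factor,
    )


@dataclass(frozen=True)
class HistogramComparison:
    """Divergence report between two orientation histograms."""

    circular_mean_difference_deg: float
    resultant_length_difference: float
    p_value: float
    n_permutations: int


def _axial_samples(h: OrientationHistogram, n_total: int = 2000) -> np.ndarray:
    """Expand a histogram into a pseudo-sample of bin-centre angles."""
    w = h.normalized
    counts = np.round(w * n_total).astype(int)
    return np.repeat(h.bin_centers_deg, counts)


def compare_histograms(
    a: OrientationHistogram,
    b: OrientationHistogram,
    n_perm: int = 999,
    seed: int = 0,
    n_pseudo: int = 500,
) -> HistogramComparison:
    """Permutation test for equality of two axial orientation distributions.

    The test statistic is the distance between the mean resultant vectors
    of the two samples on angle-doubled data; the null distribution is
    built by permuting pooled pseudo-samples drawn from the histograms
    (``n_pseudo`` angles per histogram, bin-centre resolution).
    """
    if a.bin_edges_deg.shape != b.bin_edges_deg.shape or not np.allclose(
        a.bin_edges_deg, b.bin_edges_deg
    ):
        raise ValueError("histograms must share identical binning")
    sa, sb = a.summary, b.summary
    if sa is None:
        sa = circular_summary(a.bin_centers_deg, weights=a.weights)
    if sb is None:
        sb = circular_summary(b.bin_centers_deg, weights=b.weights)
    d = abs(sa.circular_mean_deg - sb.circular_mean_deg)
    mean_diff = min(d, 180.0 - d)  # axial wrap

    rng = np.random.default_rng(seed)
    xa = _axial_samples(a, n_pseudo)
    xb = _axial_samples(b, n_pseudo)
    pooled = np.exp(2j * np.radians(np.concatenate([xa, xb])))
    na = xa.size

    def stat(z1: np.ndarray, z2: np.ndarray) -> float:
        return abs(z1.mean() - z2.mean())

    observed = stat(pooled[:na], pooled[na:])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stat(perm[:na], perm[na:]) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return HistogramComparison(
        circular_mean_difference_deg=float(mean_diff),
        resultant_length_difference=float(sa.resultant_length - sb.resultant_length),
        p_value=float(p),
        n_permutations=n_perm,
    )


def plot_polar(histograms, labels=None, path=None, ax=None):
    """Render one or more orientation histograms as polar curves (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    else:
        fig = ax.figure
    if isinstance(histograms, OrientationHistogram):
        histograms = [histograms]
    for i, h in enumerate(histograms):
        ang, wt = h.polar_angles_weights()
        order = np.argsort(ang)
        theta = np.radians(ang[order])
        radius = wt[order]
        theta = np.append(theta, theta[0])
        radius = np.append(radius, radius[0])
        label = labels[i] if labels else None
        ax.plot(theta, radius, label=label)
    if labels:
        ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1))
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
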