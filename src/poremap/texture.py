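"""Grey-level co-occurrence texture descriptors and PCA classification.

Workflow: quantize an image to G grey levels, accumulate co-occurrence
matrices at angles {0, 45, 90} degrees and pixel distances (d = 0 is the
degenerate diagonal self-co-occurrence, kept for completeness; d = 2 the
informative offset), compute 23 named Haralick-family descriptors per
matrix, z-score the resulting feature table, and project it onto principal
components for texture comparison across images.

Angle-to-offset convention (image-processing standard, row index
increasing downward): 0 deg -> (d, 0), 45 deg -> (d, -d), 90 deg ->
(0, -d) as (column, row) steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import RasterImage

#: fixed descriptor order; Haralick's classic fourteen plus the
#: Soh/Tsatsoulis- and Clausi-style extensions, 23 in total
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_correlation_1",
    "info_measure_correlation_2",
    "autocorrelation",
    "dissimilarity",
    "cluster_shade",
    "cluster_prominence",
    "maximum_probability",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
    "sum_of_squares_intensity",
    "maximal_correlation_coefficient",
)

ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    # angle -> (dcol, drow) per unit distance
    0: (1, 0),
    45: (1, -1),
    90: (0, -1),
}


@dataclass(frozen=True)
class GLCM:
    matrix: np.ndarray
    levels: int
    distance_px: int
    angle_deg: int
    symmetric: bool
    normalized: bool


def quantize(img: RasterImage | np.ndarray, levels: int = 32) -> np.ndarray:
    """Equal-width quantization of [min, max] into integer labels 0..levels-1."""
    if not (2 <= levels <= 256):
        raise ValueError("levels must lie in [2, 256]")
    px = img.as_float() if isinstance(img, RasterImage) else np.asarray(img, dtype=float)
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros(px.shape, dtype=np.int64)
    q = np.floor((px - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm(
    q: np.ndarray,
    distance_px: int,
    angle_deg: int,
    levels: int | None = None,
    symmetric: bool = True,
    normalized: bool = True,
) -> GLCM:
    """Co-occurrence matrix of quantized labels at one (distance, angle).

    Counts ordered pairs ``(q[p], q[p + d*offset])`` over all pixels whose
    offset partner lies inside the image; ``d = 0`` pairs every pixel with
    itself (diagonal matrix).  Optionally symmetrized (add transpose) and
    normalized to unit sum.
    """
    q = np.asarray(q)
    if not np.issubdtype(q.dtype, np.integer):
        raise ValueError("quantized input must be integer labels")
    if angle_deg not in ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(ANGLE_OFFSETS)}")
    if distance_px < 0:
        raise ValueError("distance must be non-negative")
    G = int(levels) if levels is not None else int(q.max()) + 1
    if q.max() >= G:
        raise ValueError("labels exceed the declared number of levels")
    dc, dr = ANGLE_OFFSETS[angle_deg]
    dc, dr = dc * distance_px, dr * distance_px
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("offset leaves no valid pixel pairs")
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    m = np.zeros((G, G), dtype=float)
    np.add.at(m, (a, b), 1.0)
    if symmetric and distance_px > 0:
        m = m + m.T
    if normalized:
        m = m / m.sum()
    return GLCM(
        matrix=m,
        levels=G,
        distance_px=distance_px,
        angle_deg=angle_deg,
        symmetric=symmetric,
        normalized=normalized,
    )


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def haralick_features(m: GLCM) -> pd.Series:
    """The 23 named texture descriptors of a normalized co-occurrence matrix.

    Definitions follow the Haralick conventions: marginals ``px, py``,
    sum/difference distributions ``p_{x+y}, p_{x-y}``, entropies in bits.
    The maximal correlation coefficient is the square root of the
    second-largest eigenvalue of ``Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))``.
    """
    if not m.normalized:
        raise ValueError("haralick_features requires a normalized GLCM")
    p = m.matrix
    G = m.levels
    i = np.arange(G, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    var_x = float(np.sum((i - mu_x) ** 2 * px))
    var_y = float(np.sum((i - mu_y) ** 2 * py))
    mu = float(np.sum(ii * p))  # overall mean level under p

    # sum (k = i+j in 0..2G-2) and difference (k = |i-j| in 0..G-1) dists
    k_sum = np.arange(2 * G - 1, dtype=float)
    p_sum = np.zeros(2 * G - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    k_diff = np.arange(G, dtype=float)
    p_diff = np.zeros(G)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    asm = float(np.sum(p * p))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    sxsy = np.sqrt(var_x * var_y)
    correlation = (
        float(np.sum((ii - mu_x) * (jj - mu_y) * p) / sxsy) if sxsy > 0 else 1.0
    )
    sum_sq_variance = float(np.sum((ii - mu) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    sum_average = float(np.sum(k_sum * p_sum))
    sum_entropy = _entropy(p_sum)
    sum_variance = float(np.sum((k_sum - sum_average) ** 2 * p_sum))
    entropy = _entropy(p)
    diff_average = float(np.sum(k_diff * p_diff))
    difference_variance = float(np.sum((k_diff - diff_average) ** 2 * p_diff))
    difference_entropy = _entropy(p_diff)

    hx = _entropy(px)
    hy = _entropy(py)
    pxy_outer = np.outer(px, py)
    mask = (p > 0) & (pxy_outer > 0)
    hxy1 = float(-np.sum(p[mask] * np.log2(pxy_outer[mask])))
    mask2 = pxy_outer > 0
    hxy2 = float(-np.sum(pxy_outer[mask2] * np.log2(pxy_outer[mask2])))
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * np.log(2.0) * (hxy2 - entropy)))))

    autocorrelation = float(np.sum(ii * jj * p))
    dissimilarity = float(np.sum(np.abs(ii - jj) * p))
    cluster_shade = float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p))
    cluster_prominence = float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p))
    maximum_probability = float(p.max())
    inverse_difference = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    idn = float(np.sum(p / (1.0 + np.abs(ii - jj) / G)))
    idmn = float(np.sum(p / (1.0 + (ii - jj) ** 2 / G**2)))
    sum_sq_intensity = float(np.sum(ii * ii * p))

    # maximal correlation coefficient
    with np.errstate(divide="ignore", invalid="ignore"):
        denom_q = px[:, None] * py[None, :]
        ratio = np.where(denom_q > 0, p / np.where(denom_q > 0, denom_q, 1.0), 0.0)
    Q = ratio @ p.T  # Q[i,j] = sum_k p(i,k)/(px(i)py(k)) * p(j,k)
    try:
        eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(0.0, eig[1]))) if eig.size > 1 else 0.0
    except np.linalg.LinAlgError:  # pragma: no cover
        mcc = float("nan")

    values = [
        asm,
        contrast,
        correlation,
        sum_sq_variance,
        idm,
        sum_average,
        sum_variance,
        sum_entropy,
        entropy,
        difference_variance,
        difference_entropy,
        imc1,
        imc2,
        autocorrelation,
        dissimilarity,
        cluster_shade,
        cluster_prominence,
        maximum_probability,
        inverse_difference,
        idn,
        idmn,
        sum_sq_intensity,
        mcc,
    ]
    return pd.Series(values, index=list(DESCRIPTOR_NAMES))


def feature_table(
    images: dict[str, RasterImage | np.ndarray],
    levels: int = 32,
    distances: tuple[int, ...] = (0, 2),
    angles: tuple[int, ...] = (0, 45, 90),
) -> pd.DataFrame:
    """Per-(image, distance, angle) table of the 23 descriptors.

    Index is a MultiIndex (image, distance_px, angle_deg); columns are
    :data:`DESCRIPTOR_NAMES`.
    """
    rows = {}
    for name, img in images.items():
        q = quantize(img, levels)
        for d in distances:
            for a in angles:
                g = glcm(q, d, a, levels=levels)
                rows[(name, d, a)] = haralick_features(g)
    table = pd.DataFrame(rows).T
    table.index.names = ["image", "distance_px", "angle_deg"]
    return table


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (population variance convention: ddof = 0).

    Constant columns map to 0 (with a warning) since they carry no
    between-sample information.
    """
    if len(table) < 2:
        raise ValueError("standardization requires at least 2 rows")
    mean = table.mean(axis=0)
    std = table.std(axis=0, ddof=0)
    constant = std == 0
    if constant.any():
        warnings.warn(
            f"constant feature columns mapped to 0: {list(table.columns[constant])}"
        )
    std = std.replace(0.0, 1.0)
    return (table - mean) / std


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_pct: np.ndarray


def pca(table: pd.DataFrame, k: int = 2) -> PCAResult:
    """Principal components of a (standardized) feature table.

    ``k`` may exceed the matrix rank; components beyond the rank carry 0%
    explained variance.  Scores are the centred data projected on the
    loadings; explained variance percentages are sorted descending and sum
    to 100 at full rank.
    """
    from sklearn.decomposition import PCA as SkPCA

    n = len(table)
    if k > min(n - 1, table.shape[1]):
        raise ValueError("k exceeds min(n - 1, n_features)")
    x = table.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    fit_k = min(k, rank) if rank > 0 else 1
    sk = SkPCA(n_components=fit_k)
    scores = sk.fit_transform(x)
    evr = sk.explained_variance_ratio_ * 100.0
    if fit_k < k:  # pad rank-deficient trailing components with zeros
        scores = np.hstack([scores, np.zeros((n, k - fit_k))])
        evr = np.concatenate([evr, np.zeros(k - fit_k)])
        loadings = np.vstack([sk.components_, np.zeros((k - fit_k, x.shape[1]))])
    else:
        loadings = sk.components_
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=cols),
        loadings=pd.DataFrame(loadings.T, index=table.columns, columns=cols),
        explained_variance_pct=evr,
    )


@dataclass(frozen=True)
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def feature_boxplot_summary(values: np.ndarray) -> BoxplotSummary:
    """Five-number box-plot summary with Tukey 1.5*IQR outlier flagging.

    Quantiles use linear interpolation (type 7, the numpy default); the
    whiskers sit at the most extreme points within Q1 - 1.5 IQR and
    Q3 + 1.5 IQR, and points beyond are reported as outliers.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
    )
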