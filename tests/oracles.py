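"""Independent brute-force oracles used by the test suite.

These are deliberately naive (loop-based, definition-level)
implementations, kept separate from the package so that agreement between
the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np

ANGLE_STEPS = {0: (1, 0), 45: (1, -1), 90: (0, -1)}  # (dcol, drow)


def brute_force_glcm(q: np.ndarray, d: int, angle: int, symmetric: bool, normalized: bool, levels: int) -> np.ndarray:
    """Pair counting by explicit iteration over every pixel."""
    dc, dr = ANGLE_STEPS[angle]
    dc, dr = dc * d, dr * d
    h, w = q.shape
    m = np.zeros((levels, levels), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1
    if symmetric and d > 0:
        m = m + m.T
    if normalized:
        m = m / m.sum()
    return m


def brute_force_haralick(p: np.ndarray) -> dict[str, float]:
    """All 23 descriptors computed with explicit loops from a normalized GLCM."""
    G = p.shape[0]
    px = [sum(p[i, j] for j in range(G)) for i in range(G)]
    py = [sum(p[i, j] for i in range(G)) for j in range(G)]
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(G))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(G))
    mu = sum(i * p[i, j] for i in range(G) for j in range(G))

    p_sum = [0.0] * (2 * G - 1)
    p_diff = [0.0] * G
    for i in range(G):
        for j in range(G):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def ent(vals):
        return -sum(v * np.log2(v) for v in vals if v > 0)

    asm = sum(p[i, j] ** 2 for i in range(G) for j in range(G))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(G) for j in range(G))
    sxsy = np.sqrt(var_x * var_y)
    correlation = (
        sum((i - mu_x) * (j - mu_y) * p[i, j] for i in range(G) for j in range(G)) / sxsy
        if sxsy > 0
        else 1.0
    )
    sum_sq_var = sum((i - mu) ** 2 * p[i, j] for i in range(G) for j in range(G))
    idm = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(G) for j in range(G))
    sum_average = sum(k * p_sum[k] for k in range(2 * G - 1))
    sum_entropy = ent(p_sum)
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * G - 1))
    entropy = ent(p.ravel())
    diff_avg = sum(k * p_diff[k] for k in range(G))
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(G))
    diff_entropy = ent(p_diff)
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(G)
        for j in range(G)
        if px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - entropy))))
    autocorr = sum(i * j * p[i, j] for i in range(G) for j in range(G))
    dissim = sum(abs(i - j) * p[i, j] for i in range(G) for j in range(G))
    shade = sum((i + j - mu_x - mu_y) ** 3 * p[i, j] for i in range(G) for j in range(G))
    prom = sum((i + j - mu_x - mu_y) ** 4 * p[i, j] for i in range(G) for j in range(G))
    max_prob = max(p[i, j] for i in range(G) for j in range(G))
    inv_diff = sum(p[i, j] / (1 + abs(i - j)) for i in range(G) for j in range(G))
    idn = sum(p[i, j] / (1 + abs(i - j) / G) for i in range(G) for j in range(G))
    idmn = sum(p[i, j] / (1 + (i - j) ** 2 / G**2) for i in range(G) for j in range(G))
    sum_sq_int = sum(i * i * p[i, j] for i in range(G) for j in range(G))

    Q = np.zeros((G, G))
    for i in range(G):
        for j in range(G):
            s = 0.0
            for k in range(G):
                if px[i] > 0 and py[k] > 0:
                    s += p[i, k] * p[j, k] / (px[i] * py[k])
            Q[i, j] = s
    eig = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
    mcc = float(np.sqrt(max(0.0, eig[1]))) if G > 1 else 0.0

    return {
        "angular_second_moment": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares_variance": sum_sq_var,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": diff_var,
        "difference_entropy": diff_entropy,
        "info_measure_correlation_1": imc1,
        "info_measure_correlation_2": imc2,
        "autocorrelation": autocorr,
        "dissimilarity": dissim,
        "cluster_shade": shade,
        "cluster_prominence": prom,
        "maximum_probability": max_prob,
        "inverse_difference": inv_diff,
        "inverse_difference_normalized": idn,
        "inverse_difference_moment_normalized": idmn,
        "sum_of_squares_intensity": sum_sq_int,
        "maximal_correlation_coefficient": mcc,
    }


def gaussian_window_convolution(field: np.ndarray, sigma: float) -> np.ndarray:
    """Direct spatial-domain Gaussian convolution with mirror padding."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    kern = np.exp(-(x**2) / (2 * sigma * sigma))
    kern /= kern.sum()
    padded = np.pad(field, radius, mode="reflect")
    h, w = field.shape
    out = np.zeros_like(field, dtype=float)
    # separable convolution via explicit loops over the kernel
    tmp = np.zeros((h + 2 * radius, w), dtype=float)
    for k, kv in enumerate(kern):
        tmp += kv * padded[:, k : k + w]
    for k, kv in enumerate(kern):
        out += kv * tmp[k : k + h, :]
    return out
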