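"""Ground-truthed synthetic micrograph generator.

Emulates the three classes of scene the analysis pipeline consumes, so
every stage can be validated against known ground truth without any
external data:

* actin-filament textures — anti-aliased line segments with a Gaussian
  cross-profile whose orientations follow a von Mises distribution
  (axial: angles are doubled before sampling and halved after), with an
  optional partition of the frame into sub-domains each with its own mean
  orientation and concentration;
* nuclei fields — smooth-edged blobs with known count, radius range,
  minimum separation and optional clustering;
* pore scenes — a filament texture silenced inside pores (regular lattice
  or random low-density discs) with an optional depletion halo.

Identical (seed, spec) inputs yield bit-identical outputs; with
``noise_model='none'`` the image is a deterministic function of the
scene parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .design import PoreLattice, rasterize_pores
from .image import ChannelRole, RasterImage


@dataclass(frozen=True)
class SceneConfig:
    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.5
    seed: int = 0
    noise_model: str = "none"  # {"none", "gaussian", "poisson"}
    snr: float = 10.0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("frame must be at least 64x64 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_model not in {"none", "gaussian", "poisson"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass(frozen=True)
class Domain:
    """Axis-aligned sub-domain in fractional frame coordinates."""

    x0: float
    y0: float
    width: float
    height: float
    mu_deg: float
    kappa: float


@dataclass(frozen=True)
class FilamentTextureSpec:
    """Filament texture parameters.

    ``length_um`` defaults to 3x the spatial period; set it much larger
    than the frame to obtain frame-spanning straight fibres (the cleanest
    texture for orientation-recovery tests, free of end-cap artefacts).
    ``width_um`` (Gaussian cross-profile sigma) defaults to period / 6.
    """

    mu_deg: float = 0.0
    kappa: float = 10.0
    spatial_period_um: float = 8.0
    n_filaments: int = 500
    domain_map: tuple[Domain, ...] | None = None
    length_um: float | None = None
    width_um: float | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.mu_deg < 90.0):
            raise ValueError("mu_deg must lie in [-90, 90)")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.spatial_period_um <= 0 or self.n_filaments <= 0:
            raise ValueError("spatial_period_um and n_filaments must be positive")
        if self.length_um is not None and self.length_um <= 0:
            raise ValueError("length_um must be positive")
        if self.width_um is not None and self.width_um <= 0:
            raise ValueError("width_um must be positive")

    def domains(self) -> tuple[Domain, ...]:
        if self.domain_map is None:
            return (Domain(0.0, 0.0, 1.0, 1.0, self.mu_deg, self.kappa),)
        return tuple(self.domain_map)


@dataclass(frozen=True)
class NucleiFieldSpec:
    n_nuclei: int = 100
    radius_um_range: tuple[float, float] = (2.5, 4.5)
    min_separation_um: float = 0.0
    clustering: float = 0.0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        lo, hi = self.radius_um_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid radius range")
        if not (0.0 <= self.clustering <= 1.0):
            raise ValueError("clustering must lie in [0, 1]")


@dataclass(frozen=True)
class RandomPoreSpec:
    """Randomly placed circular pores at a target fractional porosity."""

    pore_diameter_um: float = 8.0
    porosity: float = 0.034


@dataclass(frozen=True)
class GroundTruth:
    label_mask: np.ndarray
    orientation_map_deg: np.ndarray | None
    pore_mask: np.ndarray | None
    params_used: dict


class PlacementError(RuntimeError):
    """Requested object packing is infeasible."""


def _validate_domains(domains: tuple[Domain, ...], shape: tuple[int, int]) -> list[tuple[slice, slice]]:
    h, w = shape
    cover = np.zeros(shape, dtype=np.int16)
    boxes = []
    for d in domains:
        r0, r1 = int(round(d.y0 * h)), int(round((d.y0 + d.height) * h))
        c0, c1 = int(round(d.x0 * w)), int(round((d.x0 + d.width) * w))
        cover[r0:r1, c0:c1] += 1
        boxes.append((slice(r0, r1), slice(c0, c1)))
    if cover.min() < 1 or cover.max() > 1:
        raise ValueError("domain partition must be disjoint and cover the frame")
    return boxes


def sample_orientations(rng: np.random.Generator, mu_deg: float, kappa: float, n: int) -> np.ndarray:
    """Sample axial orientations (degrees in [-90, 90)) from von Mises(mu, kappa).

    Orientations are pi-periodic, so sampling doubles the angle, draws from
    a von Mises on the full circle, and halves back; kappa = 0 gives the
    isotropic (uniform) case.
    """
    if kappa == 0:
        return rng.uniform(-90.0, 90.0, size=n)
    doubled = rng.vonmises(np.radians(2.0 * mu_deg), kappa, size=n)
    out = np.degrees(doubled) / 2.0
    return ((out + 90.0) % 180.0) - 90.0


def _render_segment(img, best, orient_map, cx, cy, angle_deg, half_len, sigma_w, amp):
    """Additively draw one anti-aliased filament segment; track the strongest
    contributor's orientation per pixel."""
    h, w = img.shape
    theta = np.radians(angle_deg)
    dx, dy = np.cos(theta), -np.sin(theta)  # y-up angle in array coords
    sigma_l = 4.0 * sigma_w  # soft ends: weak along-axis gradients
    reach = half_len + 3.0 * sigma_l
    x0 = max(0, int(np.floor(cx - reach)))
    x1 = min(w, int(np.ceil(cx + reach)) + 1)
    y0 = max(0, int(np.floor(cy - reach)))
    y1 = min(h, int(np.ceil(cy + reach)) + 1)
    if x1 <= x0 or y1 <= y0:
        return
    xs = np.arange(x0, x1)[None, :] - cx
    ys = np.arange(y0, y1)[:, None] - cy
    t = xs * dx + ys * dy  # along-axis coordinate
    p = -xs * dy + ys * dx  # cross-axis coordinate
    over = np.maximum(np.abs(t) - half_len, 0.0)
    val = amp * np.exp(
        -p * p / (2.0 * sigma_w * sigma_w) - over * over / (2.0 * sigma_l * sigma_l)
    )
    img[y0:y1, x0:x1] += val
    sub_best = best[y0:y1, x0:x1]
    stronger = val > sub_best
    sub_best[stronger] = val[stronger]
    orient_map[y0:y1, x0:x1][stronger] = angle_deg


def apply_noise(img: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Apply the configured noise model at the configured SNR."""
    if cfg.noise_model == "none":
        return img
    # SNR is referenced to the foreground signal level (mean over pixels
    # above 10% of max), not the frame mean, so sparse scenes are not
    # trivially noise-free
    fg = img[img > 0.1 * img.max()] if img.max() > 0 else img
    level = float(fg.mean()) if fg.size else 1.0
    if level <= 0:
        level = 1.0
    if cfg.noise_model == "gaussian":
        return img + rng.normal(0.0, level / cfg.snr, size=img.shape)
    # Poisson: scale so the foreground level maps to snr^2 expected
    # photons, giving SNR = sqrt(counts) = snr at that level.
    scale = cfg.snr**2 / level
    return rng.poisson(np.maximum(img, 0.0) * scale).astype(float) / scale


def make_filament_texture(
    cfg: SceneConfig, spec: FilamentTextureSpec
) -> tuple[RasterImage, GroundTruth]:
    """Render an actin-like filament texture with known orientation statistics.

    Filaments are line segments of length ~3x the spatial period with a
    Gaussian cross-profile, orientations drawn von Mises per domain.  The
    ground-truth orientation map records, per pixel, the orientation of the
    strongest contributing filament (the domain mean where no filament
    reaches).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape
    domains = spec.domains()
    boxes = _validate_domains(domains, shape)
    img = np.zeros(shape, dtype=float)
    best = np.zeros(shape, dtype=float)
    orient = np.zeros(shape, dtype=float)
    for d, (rows, cols) in zip(domains, boxes):
        orient[rows, cols] = d.mu_deg

    period_px = spec.spatial_period_um / cfg.pixel_size_um
    length_px = (
        spec.length_um / cfg.pixel_size_um
        if spec.length_um is not None
        else 3.0 * period_px
    )
    half_len = length_px / 2.0
    sigma_w = (
        spec.width_um / cfg.pixel_size_um
        if spec.width_um is not None
        else max(0.8, period_px / 6.0)
    )
    frame_area = shape[0] * shape[1]
    sampled = []
    for d, (rows, cols) in zip(domains, boxes):
        area = (rows.stop - rows.start) * (cols.stop - cols.start)
        n_d = max(1, int(round(spec.n_filaments * area / frame_area)))
        angles = sample_orientations(rng, d.mu_deg, d.kappa, n_d)
        cxs = rng.uniform(cols.start, cols.stop, size=n_d)
        cys = rng.uniform(rows.start, rows.stop, size=n_d)
        amps = rng.uniform(0.5, 1.0, size=n_d)
        sampled.append(angles)
        for a, cx, cy, amp in zip(angles, cxs, cys, amps):
            _render_segment(img, best, orient, cx, cy, a, half_len, sigma_w, amp)
    img = apply_noise(img, cfg, rng)
    gt = GroundTruth(
        label_mask=np.zeros(shape, dtype=np.int32),
        orientation_map_deg=orient,
        pore_mask=None,
        params_used={
            "scene": asdict(cfg),
            "texture": _spec_dict(spec),
            "sampled_orientations_deg": np.concatenate(sampled).tolist(),
        },
    )
    return RasterImage(img, cfg.pixel_size_um, ChannelRole.ACTIN), gt


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    return d


def _place_centers(
    rng: np.random.Generator,
    cfg: SceneConfig,
    spec: NucleiFieldSpec,
    max_attempts: int = 20000,
) -> np.ndarray:
    """Rejection-sample nucleus centres (px) honouring the minimum separation."""
    h, w = cfg.shape
    r_max_px = spec.radius_um_range[1] / cfg.pixel_size_um
    sep_px = spec.min_separation_um / cfg.pixel_size_um
    margin = r_max_px + 1
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise PlacementError("frame too small for the requested nuclei")
    centers: list[tuple[float, float]] = []
    parents: list[tuple[float, float]] = []
    cluster_sigma = 6.0 * r_max_px
    attempts = 0
    while len(centers) < spec.n_nuclei:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {spec.n_nuclei} nuclei at separation "
                f"{spec.min_separation_um} um after {max_attempts} attempts"
            )
        if spec.clustering > 0 and parents and rng.random() < spec.clustering:
            px, py = parents[rng.integers(len(parents))]
            cx = px + rng.normal(0, cluster_sigma)
            cy = py + rng.normal(0, cluster_sigma)
        else:
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
        if not (margin <= cx <= w - margin and margin <= cy <= h - margin):
            continue
        if sep_px > 0 and centers:
            arr = np.asarray(centers)
            if np.min(np.hypot(arr[:, 0] - cx, arr[:, 1] - cy)) < sep_px:
                continue
        centers.append((cx, cy))
        parents.append((cx, cy))
    return np.asarray(centers).reshape(-1, 2)


def make_nuclei_image(
    cfg: SceneConfig, spec: NucleiFieldSpec
) -> tuple[RasterImage, GroundTruth]:
    """Render a nuclei (DAPI-like) blob field with an exact ground-truth mask.

    Each nucleus is a soft-edged disc; the label mask marks pixels within
    the nominal radius of each centre, labelled 1..n in placement order.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape
    img = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    if spec.n_nuclei > 0:
        centers = _place_centers(rng, cfg, spec)
        radii_px = (
            rng.uniform(*spec.radius_um_range, size=spec.n_nuclei) / cfg.pixel_size_um
        )
        edge = 1.0  # soft-edge width in px
        for i, ((cx, cy), r) in enumerate(zip(centers, radii_px), start=1):
            reach = r + 4 * edge
            x0 = max(0, int(cx - reach))
            x1 = min(shape[1], int(cx + reach) + 1)
            y0 = max(0, int(cy - reach))
            y1 = min(shape[0], int(cy + reach) + 1)
            xs = np.arange(x0, x1)[None, :] - cx
            ys = np.arange(y0, y1)[:, None] - cy
            dist = np.hypot(xs, ys)
            img[y0:y1, x0:x1] += 1.0 / (1.0 + np.exp((dist - r) / edge))
            labels[y0:y1, x0:x1][dist <= r] = i
        centers_list = centers.tolist()
        radii_list = (radii_px * cfg.pixel_size_um).tolist()
    else:
        centers_list, radii_list = [], []
    img = apply_noise(img, cfg, rng)
    gt = GroundTruth(
        label_mask=labels,
        orientation_map_deg=None,
        pore_mask=None,
        params_used={
            "scene": asdict(cfg),
            "nuclei": asdict(spec),
            "centers_px": centers_list,
            "radii_um": radii_list,
        },
    )
    return RasterImage(img, cfg.pixel_size_um, ChannelRole.NUCLEI), gt


def _random_pore_mask(
    rng: np.random.Generator, cfg: SceneConfig, spec: RandomPoreSpec
) -> np.ndarray:
    h, w = cfg.shape
    r_px = spec.pore_diameter_um / 2.0 / cfg.pixel_size_um
    area_um2 = h * w * cfg.pixel_size_um**2
    pore_area = np.pi * (spec.pore_diameter_um / 2.0) ** 2
    n = int(round(spec.porosity * area_um2 / pore_area))
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(n):
        cx = rng.uniform(0, w)
        cy = rng.uniform(0, h)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px * r_px
    return mask


def make_pore_scene(
    cfg: SceneConfig,
    pores: PoreLattice | RandomPoreSpec,
    texture: FilamentTextureSpec,
    depletion_halo_um: float = 0.0,
) -> tuple[RasterImage, GroundTruth]:
    """Filament texture on a porous membrane: pores silence the texture.

    The texture is multiplied by 0 inside pores and ramps linearly back to
    full intensity across the depletion halo (distance-transform based), so
    pore rims carry a sharp intensity transition like the cell-depleted
    regions around real membrane pores.
    """
    if depletion_halo_um < 0:
        raise ValueError("depletion halo must be non-negative")
    base_cfg = dataclasses.replace(cfg, noise_model="none")
    tex_img, tex_gt = make_filament_texture(base_cfg, texture)
    if isinstance(pores, PoreLattice):
        lat = pores
        if lat.frame_um is None:
            lat = dataclasses.replace(
                lat, frame_um=(cfg.width_px * cfg.pixel_size_um, cfg.height_px * cfg.pixel_size_um)
            )
        pore_mask = rasterize_pores(lat, cfg.pixel_size_um) >= 0.5
        pore_params = asdict(lat)
    else:
        rng = np.random.default_rng(cfg.seed + 1)
        pore_mask = _random_pore_mask(rng, cfg, pores)
        pore_params = asdict(pores)
    if depletion_halo_um > 0:
        dist_um = ndimage.distance_transform_edt(~pore_mask) * cfg.pixel_size_um
        atten = np.clip(dist_um / depletion_halo_um, 0.0, 1.0)
    else:
        atten = (~pore_mask).astype(float)
    img = tex_img.as_float() * atten
    img[pore_mask] = 0.0
    rng_noise = np.random.default_rng(cfg.seed)
    img = apply_noise(img, cfg, rng_noise)
    gt = GroundTruth(
        label_mask=np.zeros(cfg.shape, dtype=np.int32),
        orientation_map_deg=tex_gt.orientation_map_deg,
        pore_mask=pore_mask,
        params_used={
            "scene": asdict(cfg),
            "texture": _spec_dict(texture),
            "pores": pore_params,
            "depletion_halo_um": depletion_halo_um,
        },
    )
    return RasterImage(img, cfg.pixel_size_um, ChannelRole.ACTIN), gt


def save_scene(
    img: RasterImage, gt: GroundTruth, out_dir: str | Path, stem: str = "scene"
) -> dict[str, Path]:
    """Write a scene as TIFF (image, masks) plus JSON (ground truth + spec)."""
    from .image import write_raster

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"image": write_raster(img.pixels, out / f"{stem}.tif")}
    if gt.label_mask is not None and gt.label_mask.max() > 0:
        paths["labels"] = write_raster(gt.label_mask.astype(np.uint16), out / f"{stem}_labels.tif")
    if gt.pore_mask is not None:
        paths["pore_mask"] = write_raster(
            gt.pore_mask.astype(np.uint8), out / f"{stem}_pores.tif"
        )
    if gt.orientation_map_deg is not None:
        paths["orientation"] = write_raster(
            gt.orientation_map_deg, out / f"{stem}_orientation.tif"
        )
    meta = {k: v for k, v in gt.params_used.items() if k != "sampled_orientations_deg"}
    meta["pixel_size_um"] = img.pixel_size_um
    meta["channel_role"] = img.channel_role.value
    gt_path = out / f"{stem}_groundtruth.json"
    gt_path.write_text(json.dumps(meta, indent=2))
    paths["groundtruth"] = gt_path
    return paths
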