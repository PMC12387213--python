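"""End-to-end pipeline runner.

Reproduces the comparative per-substrate workflow in one call: for each
input image set (actin, nuclei, optional bright-field per sample) it runs
structure-tensor orientation analysis and the polar anisotropy statistics
on the actin channel, monogenic analysis on the actin channel, nuclei
statistics on the nuclei channel, and GLCM texture + PCA across the actin
channels of all samples, writing every figure-type artefact (HSB
composite, energy/coherency maps, monogenic phase map, polar histogram
CSVs and plots, feature tables, PCA scores, nuclei histograms) plus one
machine-readable JSON report.

All stochastic stages derive their sub-seeds deterministically from the
run seed, so a rerun with the same config is bit-identical (timestamps
excluded by design: the report carries none).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import monogenic as mg
from . import nuclei as nc
from . import orientation as ori
from . import polar as pol
from . import texture as tx
from .image import ChannelRole, RasterImage, read_image, write_raster

log = logging.getLogger("poremap")


@dataclass
class SampleConfig:
    """One sample (substrate): paths per channel role."""

    name: str
    actin: str | None = None
    nuclei: str | None = None
    brightfield: str | None = None


@dataclass
class RunConfig:
    samples: list[SampleConfig]
    pixel_size_um: float = 0.5
    out_dir: str = "poremap_out"
    seed: int = 0
    # stage parameters (all logged at startup)
    window_sigma_px: float = 2.0
    monogenic_scale_px: float = 8.0
    glcm_levels: int = 32
    glcm_distances: tuple[int, ...] = (0, 2)
    glcm_angles: tuple[int, ...] = (0, 45, 90)
    pca_components: int = 2
    energy_mask_quantile: float = 0.95
    polar_bins: int = 72
    nuclei_min_area_um2: float = 20.0
    nuclei_max_area_um2: float = 500.0
    roi_um: float = 350.0
    n_rois: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        samples = [SampleConfig(**s) for s in raw.pop("samples")]
        return cls(samples=samples, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(
    cfg: RunConfig,
    images: dict[str, dict[str, RasterImage]] | None = None,
) -> dict:
    """Execute every analysis stage and write all artefacts.

    ``images`` may supply in-memory images keyed ``{sample: {role: img}}``;
    otherwise the paths in the config are read from disk.  A missing
    channel skips its stage with a logged warning; the pipeline still
    completes.  Returns the report dict (also written as JSON).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run config: %s", json.dumps(cfg.to_dict(), default=str))
    report: dict = {
        "provenance": {"config": cfg.to_dict(), "config_hash": _config_hash(cfg), "seed": cfg.seed},
        "samples": {},
    }
    actin_images: dict[str, RasterImage] = {}
    for sample in cfg.samples:
        s_out = out / sample.name
        s_out.mkdir(parents=True, exist_ok=True)
        s_rep: dict = {}

        def _load(role: str) -> RasterImage | None:
            if images is not None and sample.name in images:
                return images[sample.name].get(role)
            path = getattr(sample, role)
            if path is None:
                return None
            return read_image(path, channel_role=role, pixel_size_um=cfg.pixel_size_um)

        actin = _load("actin")
        dapi = _load("nuclei")

        if actin is not None:
            actin_images[sample.name] = actin
            tf = ori.analyze_orientation(actin, cfg.window_sigma_px)
            write_raster(tf.orientation_deg, s_out / "orientation_deg.tif")
            write_raster(tf.energy, s_out / "energy.tif")
            write_raster(np.nan_to_num(tf.coherency), s_out / "coherency.tif")
            hsb = ori.hsb_composite(tf, actin)
            write_raster((hsb.rgb * 255).astype(np.uint8), s_out / "hsb_composite.png", dtype="uint8")

            mask, mask_prov = pol.high_energy_mask(tf, quantile=cfg.energy_mask_quantile)
            h_img = pol.orientation_polar(tf, weighting="energy", n_bins=cfg.polar_bins)
            h_feat = pol.orientation_polar(
                tf, mask=mask, weighting="none", n_bins=cfg.polar_bins,
                source="energy_feature_orientations",
            )
            for tag, h in (("image", h_img), ("energy_features", h_feat)):
                pd.DataFrame(
                    {
                        "bin_center_deg": h.bin_centers_deg,
                        "weight": h.weights,
                        "normalized_weight": h.normalized,
                    }
                ).to_csv(s_out / f"polar_{tag}.csv", index=False)
            pol.plot_polar([h_img, h_feat], labels=["image", "energy features"],
                           path=s_out / "polar.png")
            s_rep["orientation"] = {
                "window_sigma_px": cfg.window_sigma_px,
                "circular_mean_deg": h_img.summary.circular_mean_deg,
                "resultant_length": h_img.summary.resultant_length,
                "energy_mask": {k: (float(v) if isinstance(v, (int, float)) else v)
                                 for k, v in mask_prov.items()},
                "feature_circular_mean_deg": h_feat.summary.circular_mean_deg,
                "feature_resultant_length": h_feat.summary.resultant_length,
            }

            mf = mg.monogenic_transform(actin, cfg.monogenic_scale_px)
            write_raster(mf.amplitude, s_out / "monogenic_amplitude.tif")
            write_raster(mf.phase_rad, s_out / "monogenic_phase.tif")
            write_raster(mf.orientation_deg, s_out / "monogenic_orientation.tif")
            write_raster(
                (mg.enhance_modulus(mf.amplitude) * 255).astype(np.uint8),
                s_out / "monogenic_modulus_display.png",
                dtype="uint8",
            )
            s_rep["monogenic"] = {"scale_px": cfg.monogenic_scale_px}
        else:
            log.warning("sample %s: no actin channel, orientation/monogenic stages skipped", sample.name)

        if dapi is not None:
            labels = nc.segment_nuclei(
                dapi, cfg.nuclei_min_area_um2, cfg.nuclei_max_area_um2
            )
            roi_px = int(round(cfg.roi_um / cfg.pixel_size_um))
            roi_px = min(roi_px, min(labels.shape))
            stable = int.from_bytes(
                hashlib.sha256(sample.name.encode()).digest()[:2], "big"
            )  # process-independent per-sample sub-seed
            rois = nc.roi_sampler(
                labels.shape, roi_px, cfg.n_rois, seed=cfg.seed + stable
            )
            stats_full = nc.nuclei_stats(labels, dapi.pixel_size_um)
            counts, edges = nc.area_histogram(stats_full)
            pd.DataFrame({"area_um2_low": edges[:-1], "count": counts}).to_csv(
                s_out / "nuclei_area_histogram.csv", index=False
            )
            write_raster(labels.astype(np.uint16), s_out / "nuclei_labels.tif")
            s_rep["nuclei"] = {
                "n_obj": stats_full.n_obj,
                "coverage_pct": stats_full.coverage_pct,
                "mean_area_um2": float(stats_full.areas_um2.mean())
                if stats_full.n_obj
                else None,
                "rois": [
                    {
                        "roi": list(roi),
                        "n_obj": (st := nc.nuclei_stats(labels, dapi.pixel_size_um, roi)).n_obj,
                        "coverage_pct": st.coverage_pct,
                    }
                    for roi in rois
                ],
            }
        else:
            log.warning("sample %s: no nuclei channel, nuclei stage skipped", sample.name)

        report["samples"][sample.name] = s_rep

    if len(actin_images) >= 2:
        table = tx.feature_table(
            actin_images,
            levels=cfg.glcm_levels,
            distances=tuple(cfg.glcm_distances),
            angles=tuple(cfg.glcm_angles),
        )
        table.to_csv(out / "glcm_features.csv")
        std = tx.standardize(table)
        std.to_csv(out / "glcm_features_standardized.csv")
        k = min(cfg.pca_components, len(std) - 1, std.shape[1])
        res = tx.pca(std, k=k)
        res.scores.to_csv(out / "pca_scores.csv")
        res.loadings.to_csv(out / "pca_loadings.csv")
        box = {
            name: dataclasses.asdict(
                tx.feature_boxplot_summary(std.xs(name, level="image").to_numpy().ravel())
            )
            for name in actin_images
        }
        report["texture"] = {
            "n_rows": len(table),
            "n_descriptors": table.shape[1],
            "explained_variance_pct": [float(v) for v in res.explained_variance_pct],
            "boxplot": {
                k2: {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv) for kk, vv in v.items()}
                for k2, v in box.items()
            },
        }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    log.info("report written to %s", report_path)
    return report
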