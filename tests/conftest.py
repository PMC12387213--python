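import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from poremap.image import ChannelRole, RasterImage
from poremap.synth import FilamentTextureSpec, SceneConfig, make_filament_texture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grating(mu_deg: float, n: int = 128, period_px: float = 8.0) -> RasterImage:
    """Pure sinusoidal grating whose stripes run along ``mu_deg`` (y-up, CCW)."""
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    th = np.radians(mu_deg)
    phase = (xx * np.sin(th) + yy * np.cos(th)) * 2 * np.pi / period_px
    return RasterImage(np.cos(phase), 1.0, ChannelRole.ACTIN)


def clean_fibre_texture(mu_deg: float, seed: int = 0, n: int = 256) -> RasterImage:
    """Frame-spanning straight fibres at a single orientation (no end caps)."""
    cfg = SceneConfig(width_px=n, height_px=n, seed=seed)
    spec = FilamentTextureSpec(
        mu_deg=mu_deg, kappa=1e6, n_filaments=80, length_um=1e5, width_um=1.3
    )
    img, _ = make_filament_texture(cfg, spec)
    return img


@pytest.fixture
def grating30():
    return make_grating(30.0)
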