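"""Pore-pattern design calculators.

Analytic geometry for micro-drilled membrane patterns: regular pore
lattices (circular through-pores on a rectangular pitch), fractional-area
porosity, pore-centre coordinate export for stage-controlled direct
writing, and the charge-fluence to ion-density conversion used to plan
proton-beam doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: elementary charge in coulombs (CODATA exact value)
ELEMENTARY_CHARGE_C = 1.602176634e-19


@dataclass(frozen=True)
class PoreLattice:
    """Rectangular lattice of circular pores.

    ``arrangement='custom'`` ignores the pitches and uses ``centers_um``
    (explicit pore-centre list) instead.
    """

    pore_diameter_um: float
    pitch_x_um: float
    pitch_y_um: float | None = None
    arrangement: str = "square"
    frame_um: tuple[float, float] | None = None
    centers_um: tuple[tuple[float, float], ...] | None = None
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.pore_diameter_um < 0:
            raise ValueError("pore diameter must be non-negative")
        if self.pitch_y_um is None:
            object.__setattr__(self, "pitch_y_um", self.pitch_x_um)
        if self.arrangement not in {"square", "rectangular", "custom"}:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.arrangement != "custom":
            if self.pitch_x_um <= 0 or self.pitch_y_um <= 0:
                raise ValueError("pitches must be positive")
            if not self.allow_overlap and self.pore_diameter_um > min(
                self.pitch_x_um, self.pitch_y_um
            ):
                raise ValueError(
                    "pores overlap: diameter exceeds pitch "
                    "(pass allow_overlap=True to override)"
                )


@dataclass(frozen=True)
class BeamParameters:
    """Proton-microbeam write parameters (singly charged ions)."""

    energy_MeV: float
    current_pA: float
    fluence_pC_per_mm2: float
    spot_diameter_um: float

    def __post_init__(self) -> None:
        for name in ("energy_MeV", "current_pA", "fluence_pC_per_mm2", "spot_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ion_density_per_mm2(self) -> float:
        return fluence_to_ion_density(self.fluence_pC_per_mm2)


def porosity(lattice: PoreLattice) -> float:
    """Fractional-area porosity of the pattern.

    For a periodic lattice this is the area of one pore over the area of
    one unit cell, pi*(d/2)^2 / (pitch_x * pitch_y).  For cylindrical
    through-pores of uniform membrane thickness the area fraction equals
    the volume fraction, so this is also the fractional-volume porosity.
    Custom pore lists use total pore area over frame area.
    """
    r = lattice.pore_diameter_um / 2.0
    if lattice.arrangement == "custom":
        if lattice.centers_um is None or lattice.frame_um is None:
            raise ValueError("custom arrangement requires centers_um and frame_um")
        frame_area = lattice.frame_um[0] * lattice.frame_um[1]
        return len(lattice.centers_um) * np.pi * r * r / frame_area
    return float(np.pi * r * r / (lattice.pitch_x_um * lattice.pitch_y_um))


def fluence_to_ion_density(fluence_pC_per_mm2: float) -> float:
    """Convert a charge fluence (pC/mm^2) to an ion areal density (ions/mm^2).

    Assumes singly charged ions (protons): density = fluence[C/mm^2] / e.
    """
    if fluence_pC_per_mm2 < 0:
        raise ValueError("fluence must be non-negative")
    return fluence_pC_per_mm2 * 1e-12 / ELEMENTARY_CHARGE_C


def lattice_coordinates(lattice: PoreLattice) -> np.ndarray:
    """Centres (x_um, y_um) of all pores whose disc lies fully inside the frame.

    Deterministic row-major order (increasing y, then increasing x).  The
    lattice is anchored so that the first pore centre sits one pitch-aligned
    position with the pore tangent to the frame origin corner when possible.
    """
    if lattice.frame_um is None:
        raise ValueError("frame_um must be set to enumerate pore centres")
    if lattice.arrangement == "custom":
        return np.asarray(lattice.centers_um, dtype=float).reshape(-1, 2)
    w, h = lattice.frame_um
    r = lattice.pore_diameter_um / 2.0
    px, py = lattice.pitch_x_um, lattice.pitch_y_um
    # grid anchored at half-pitch offsets, keep discs fully inside the frame
    xs = np.arange(px / 2.0, w, px)
    ys = np.arange(py / 2.0, h, py)
    xs = xs[(xs - r >= 0) & (xs + r <= w)]
    ys = ys[(ys - r >= 0) & (ys + r <= h)]
    if xs.size == 0 or ys.size == 0:
        return np.empty((0, 2))
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def rasterize_pores(
    lattice: PoreLattice,
    pixel_size_um: float,
    supersample: int = 1,
) -> np.ndarray:
    """Rasterize the pore pattern as a coverage mask on the lattice frame.

    Returns a float array in [0, 1]: with ``supersample=1`` a hard
    pixel-centre membership test, with ``supersample=s`` the fraction of
    s*s subsamples inside a pore (sub-pixel accurate area estimates).
    """
    if lattice.frame_um is None:
        raise ValueError("frame_um must be set to rasterize")
    w_um, h_um = lattice.frame_um
    nx = int(round(w_um / pixel_size_um))
    ny = int(round(h_um / pixel_size_um))
    centers = lattice_coordinates(lattice)
    out = np.zeros((ny, nx), dtype=float)
    r = lattice.pore_diameter_um / 2.0
    s = max(1, int(supersample))
    offs = (np.arange(s) + 0.5) / s  # subsample positions within a pixel
    for cx, cy in centers:
        # bounding box in pixels
        x0 = max(0, int((cx - r) / pixel_size_um) - 1)
        x1 = min(nx, int((cx + r) / pixel_size_um) + 2)
        y0 = max(0, int((cy - r) / pixel_size_um) - 1)
        y1 = min(ny, int((cy + r) / pixel_size_um) + 2)
        if x1 <= x0 or y1 <= y0:
            continue
        xs = (np.arange(x0, x1)[:, None] + offs[None, :]).ravel() * pixel_size_um
        ys = (np.arange(y0, y1)[:, None] + offs[None, :]).ravel() * pixel_size_um
        dx2 = (xs - cx) ** 2
        dy2 = (ys - cy) ** 2
        inside = (dy2[:, None] + dx2[None, :]) <= r * r
        cov = inside.reshape(y1 - y0, s, x1 - x0, s).mean(axis=(1, 3))
        np.maximum(out[y0:y1, x0:x1], cov, out=out[y0:y1, x0:x1])
    return out
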