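"""Beer-Lambert density transform and two-stain unmixing.

Brightfield chromogens obey the Beer-Lambert law: the measured intensity of
channel *ch* is ``I_ch = I0_ch * exp(-D_ch)`` where ``D_ch`` is the optical
density contributed by all absorbers. Stain amount is therefore linear in
density, not in RGB intensity, which is the premise of density-based colour
models for transmitted-light microscopy. This module converts 8-bit RGB to
per-channel density and decomposes each density vector onto two reference
absorbance axes - DAB ("brown") and hematoxylin ("blue") - by per-pixel
least squares. A third raster, brown-minus-blue ("Brown+ve"), is positive
where DAB dominates and drives the downstream brown classification.

Densities are natural-log optical densities, reported in arbitrary units
(au). Reference vectors default to widely used DAB/hematoxylin absorbance
directions and are configurable for per-lab calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io import RGBSlide

__all__ = [
    "StainReference",
    "StainMaps",
    "rgb_to_density",
    "slide_density",
    "unmix_stains",
    "DEFAULT_DAB_OD",
    "DEFAULT_HEMATOXYLIN_OD",
]

# Per-channel absorbance directions (R, G, B); normalised on construction.
DEFAULT_DAB_OD = (0.269, 0.568, 0.778)
DEFAULT_HEMATOXYLIN_OD = (0.650, 0.704, 0.286)


@dataclass(frozen=True)
class StainReference:
    """Unit absorbance vectors for the brown (DAB) and blue (hematoxylin) stains."""

    brown_od: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_DAB_OD))
    blue_od: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_HEMATOXYLIN_OD))

    def __post_init__(self) -> None:
        for name in ("brown_od", "blue_od"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or np.any(v < 0):
                raise ConfigError(f"{name} must be a non-negative 3-vector")
            norm = float(np.linalg.norm(v))
            if norm == 0:
                raise ConfigError(f"{name} must be nonzero")
            object.__setattr__(self, name, v / norm)
        cosang = float(np.dot(self.brown_od, self.blue_od))
        if abs(cosang) > 1 - 1e-6:
            raise ConfigError("stain reference vectors are (near-)parallel")

    @classmethod
    def from_config(cls, section: dict) -> "StainReference":
        kwargs = {}
        if "brown_od" in section:
            kwargs["brown_od"] = np.asarray(section["brown_od"], dtype=float)
        if "blue_od" in section:
            kwargs["blue_od"] = np.asarray(section["blue_od"], dtype=float)
        return cls(**kwargs)


@dataclass
class StainMaps:
    """Per-pixel stain densities on a common grid.

    ``brown_pos_au`` is brown minus blue, computed after the non-negativity
    clamp, so it never exceeds ``brown_au`` and equals it exactly where the
    blue coefficient is zero. ``mpp`` is the microns-per-pixel of *this*
    grid (the slide's mpp times any downsampling factor applied upstream).
    """

    brown_au: np.ndarray
    blue_au: np.ndarray
    brown_pos_au: np.ndarray
    mpp: float

    def __post_init__(self) -> None:
        if not (self.brown_au.shape == self.blue_au.shape == self.brown_pos_au.shape):
            raise ValueError("stain rasters must share a shape")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")


def rgb_to_density(
    pixels: np.ndarray,
    i0: tuple[float, float, float] = (255.0, 255.0, 255.0),
) -> np.ndarray:
    """Per-channel optical density ``D = -ln(I / I0)``.

    Intensities are clipped to ``[1, I0]`` per channel before the log, so
    the transform is total: 8-bit zeros map to a large finite density and
    glass-bright pixels map to exactly zero. Accepts uint8 or float input
    (float input supports continuous, quantisation-free round trips) and
    returns float32.
    """
    i0_arr = np.asarray(i0, dtype=np.float32).reshape(1, 1, 3)
    img = np.asarray(pixels, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) raster, got {img.shape}")
    clipped = np.clip(img, 1.0, i0_arr)
    return -np.log(clipped / i0_arr)


def slide_density(slide: RGBSlide) -> np.ndarray:
    """Density raster of a slide at its native resolution."""
    return rgb_to_density(slide.pixels, slide.i0)


def unmix_stains(
    density: np.ndarray,
    ref: StainReference | None = None,
    mpp: float = 1.0,
) -> StainMaps:
    """Decompose a 3-channel density raster onto the two stain axes.

    Solves, per pixel, the least-squares problem ``D ~ b * brown_od +
    h * blue_od`` in closed form via the 2x3 pseudoinverse of the reference
    matrix; negative coefficients are clamped to zero (stain loads are
    physically non-negative). The clamp is applied independently per
    coefficient, which matches the downstream use of the maps as
    classification features.
    """
    ref = ref or StainReference()
    density = np.asarray(density, dtype=np.float32)
    if density.ndim != 3 or density.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) density raster, got {density.shape}")
    m = np.stack([ref.brown_od, ref.blue_od], axis=1)  # 3 x 2
    pinv = np.linalg.inv(m.T @ m) @ m.T  # 2 x 3
    coeffs = density @ pinv.T.astype(np.float32)  # (H, W, 2)
    coeffs = np.maximum(coeffs, 0.0)
    brown = np.ascontiguousarray(coeffs[..., 0])
    blue = np.ascontiguousarray(coeffs[..., 1])
    return StainMaps(brown_au=brown, blue_au=blue, brown_pos_au=brown - blue, mpp=mpp)
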