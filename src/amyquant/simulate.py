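"""Synthetic inputs with known ground truth: rendered histology slides,
immunoassay plates and grouped measurement tables.

Slides are rendered by inverting the Beer-Lambert relation the analysis
uses: plaque cores, halos and artifacts are painted as stain *densities*
(DAB load plus a hematoxylin tissue background), converted to RGB
intensity per channel as ``I = I0 * exp(-D)`` and quantised to 8 bits.
Noise, when requested, is additive Gaussian in density space so that
thresholds in au translate directly into detection margins. Object
geometry is laid out on the x20-equivalent analysis grid (one cell per
2x2 block of full-resolution pixels) and replicated up to full resolution,
so block-mean downsampling in the pipeline recovers the planted densities
exactly up to 8-bit quantisation.

Artifact objects are constructed to violate exactly one of the five
plaque-removal rules each, which lets end-to-end tests assert not just
rejection but the specific rule that fired. All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from .assay import Well
from .geometry import polygon_pixel_mask
from .io import RGBSlide
from .segmentation import (
    RULE_DARK_FRACTION,
    RULE_MIN_AREA,
    RULE_MIN_DARK_AREA,
    RULE_NON_ELLIPTICAL,
    RULE_UNIFORM_INTENSITY,
)
from .stains import StainReference

__all__ = [
    "PlaqueSpec",
    "ArtifactSpec",
    "SyntheticSlideSpec",
    "ObjectTruth",
    "SlideGroundTruth",
    "SyntheticPlateSpec",
    "render_slide",
    "render_plate",
    "render_groups",
    "clean_section_spec",
    "null_section_spec",
    "boundary_section_spec",
    "ARTIFACT_RULES",
]


@dataclass(frozen=True)
class PlaqueSpec:
    """A dark disc core inside a light halo disc; positions/radii in microns.

    ``wobble_amp``/``wobble_order`` perturb the halo radius with a low-order
    radial cosine, to exercise the elliptic-fit rule with non-circular but
    still compact shapes.
    """

    center_um: tuple[float, float]
    core_radius_um: float
    halo_radius_um: float
    core_brown_au: float = 0.8
    halo_brown_au: float = 0.3
    wobble_amp: float = 0.0
    wobble_order: int = 0

    def __post_init__(self) -> None:
        if self.halo_radius_um < self.core_radius_um:
            raise ValueError("halo radius must be >= core radius")
        if self.core_brown_au < 0 or self.halo_brown_au < 0:
            raise ValueError("densities must be >= 0")


# kind -> the removal rule the artifact is designed to violate (and only that)
ARTIFACT_RULES = {
    "speck": RULE_MIN_AREA,
    "faint_halo": RULE_MIN_DARK_AREA,
    "uniform_blob": RULE_UNIFORM_INTENSITY,
    "line": RULE_NON_ELLIPTICAL,
    "dense_blob": RULE_DARK_FRACTION,
}

# kind -> the rules it must also be accepted by (i.e. exactly one violation).
_BOUNDARY_KINDS = ("edge_area_10", "edge_area_40", "edge_dark_70")


@dataclass(frozen=True)
class ArtifactSpec:
    """A rule-violating object anchored at ``origin_um`` (top-left, microns).

    Designs (sizes quoted on a 1 um analysis grid):

    - ``speck``: 3x3 um square with a 2x2 dark corner - area below 10 um^2
      but mixed enough to dodge the uniform-intensity rule.
    - ``faint_halo``: single dark pixel inside a light disc - dark area
      below 1.5 um^2.
    - ``uniform_blob``: 6x6 um uniformly dark square - high mean with
      near-zero SD.
    - ``line``: 1x20 um line with a short dark run - non-elliptical at
      under 40 um^2.
    - ``dense_blob``: 8x8 um square, 81 % dark - dark fraction above 0.70
      at over 40 um^2.
    """

    kind: str
    origin_um: tuple[float, float]

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_RULES and self.kind not in _BOUNDARY_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")

    @property
    def intended_flag(self) -> str | None:
        return ARTIFACT_RULES.get(self.kind)


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Full description of a rendered section.

    ``width_px``/``height_px`` are the full-resolution raster size (must be
    even); ``tissue_polygon`` is in full-resolution pixel coordinates.
    ``hematoxylin_au`` is the uniform blue counterstain density inside
    tissue; ``noise_sd_au`` is the density-space noise SD applied per
    full-resolution pixel (0 renders a noiseless slide).
    """

    width_px: int
    height_px: int
    mpp: float
    tissue_polygon: tuple[tuple[float, float], ...]
    plaques: tuple[PlaqueSpec, ...] = ()
    artifacts: tuple[ArtifactSpec, ...] = ()
    hematoxylin_au: float = 0.12
    noise_sd_au: float = 0.0
    seed: int = 0
    i0: tuple[float, float, float] = (255.0, 255.0, 255.0)
    scan_magnification: int = 40


@dataclass
class ObjectTruth:
    """Planted footprint of one object on the analysis (stain) grid."""

    index: int
    kind: str  # "plaque" or an artifact kind
    intended_flag: str | None
    pixels: np.ndarray  # (n, 2) (row, col) on the stain grid
    area_um2: float
    centroid: tuple[float, float]  # (x, y), stain grid


@dataclass
class SlideGroundTruth:
    objects: list[ObjectTruth]
    tissue_mask_stain: np.ndarray
    plaque_count: int
    plaque_area_um2: float

    @property
    def plaques(self) -> list[ObjectTruth]:
        return [o for o in self.objects if o.kind == "plaque"]

    @property
    def artifacts(self) -> list[ObjectTruth]:
        return [o for o in self.objects if o.kind != "plaque"]


def _paint_rect(brown: np.ndarray, dark: np.ndarray, x0: int, y0: int,
                w: int, h: int, au: float, is_dark: bool) -> None:
    brown[y0:y0 + h, x0:x0 + w] = au
    dark[y0:y0 + h, x0:x0 + w] = is_dark


def _disc_mask(shape: tuple[int, int], cx: float, cy: float, r: float,
               wobble_amp: float = 0.0, wobble_order: int = 0) -> np.ndarray:
    rmax = r * (1.0 + abs(wobble_amp))
    y0 = max(0, int(cy - rmax - 2))
    y1 = min(shape[0], int(cy + rmax + 3))
    x0 = max(0, int(cx - rmax - 2))
    x1 = min(shape[1], int(cx + rmax + 3))
    gy, gx = np.mgrid[y0:y1, x0:x1]
    dx = gx + 0.5 - cx
    dy = gy + 0.5 - cy
    dist = np.hypot(dx, dy)
    if wobble_amp and wobble_order:
        theta = np.arctan2(dy, dx)
        r_eff = r * (1.0 + wobble_amp * np.cos(wobble_order * theta))
    else:
        r_eff = r
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = dist <= r_eff
    return mask


def _paint_artifact(kind: str, brown: np.ndarray, dark: np.ndarray,
                    origin: tuple[int, int], pitch: float) -> None:
    """Paint one artifact; all quoted sizes are microns, converted to the
    analysis grid via ``pitch`` (um per grid pixel)."""
    x0, y0 = origin

    def px(um: float) -> int:
        return max(1, int(round(um / pitch)))

    if kind == "speck":
        _paint_rect(brown, dark, x0, y0, px(3), px(3), 0.30, False)
        _paint_rect(brown, dark, x0, y0, px(2), px(2), 0.60, True)
    elif kind == "faint_halo":
        r = 3.0 / pitch
        mask = _disc_mask(brown.shape, x0 + r + 0.5, y0 + r + 0.5, r)
        brown[mask] = 0.32
        dark[mask] = False
        cy, cx = y0 + int(r), x0 + int(r)
        brown[cy, cx] = 0.60
        dark[cy, cx] = True
    elif kind == "uniform_blob":
        _paint_rect(brown, dark, x0, y0, px(6), px(6), 0.80, True)
    elif kind == "line":
        _paint_rect(brown, dark, x0, y0, px(20), px(1), 0.30, False)
        _paint_rect(brown, dark, x0, y0, px(3), px(1), 0.60, True)
    elif kind == "dense_blob":
        _paint_rect(brown, dark, x0, y0, px(8), px(8), 0.52, True)
        # light corner -> dark fraction 52/64 = 0.8125
        _paint_rect(brown, dark, x0, y0, px(4), px(3), 0.28, False)
    # Boundary-threshold objects: each sits exactly ON a printed threshold
    # and must be accepted.
    elif kind == "edge_area_10":
        # area exactly 10 um^2 (2x5 um rect): "smaller than 10" is strict
        _paint_rect(brown, dark, x0, y0, px(5), px(2), 0.30, False)
        _paint_rect(brown, dark, x0, y0, px(2), px(2), 0.60, True)
    elif kind == "edge_area_40":
        # area exactly 40 um^2, non-elliptical and 75 % dark: at exactly 40
        # neither the under-40 shape rule nor the over-40 fraction rule fires
        _paint_rect(brown, dark, x0, y0, px(40), px(1), 0.30, False)
        _paint_rect(brown, dark, x0, y0, px(30), px(1), 0.55, True)
    elif kind == "edge_dark_70":
        # dark fraction exactly 0.70 at 100 um^2: "greater than 70 %" is strict
        _paint_rect(brown, dark, x0, y0, px(10), px(10), 0.30, False)
        _paint_rect(brown, dark, x0, y0, px(10), px(7), 0.52, True)
    else:  # pragma: no cover - guarded by ArtifactSpec
        raise ValueError(kind)


def render_slide(spec: SyntheticSlideSpec) -> tuple[RGBSlide, SlideGroundTruth]:
    """Render a synthetic section and its ground truth.

    Deterministic for a fixed ``spec.seed``. Raises if any planted object
    extends outside the tissue polygon or overlaps another object (either
    would break the exactness of the ground truth).
    """
    if spec.width_px % 2 or spec.height_px % 2:
        raise ValueError("raster dimensions must be even")
    rng = np.random.default_rng(spec.seed)
    gw, gh = spec.width_px // 2, spec.height_px // 2  # stain grid
    pitch = spec.mpp * 2.0  # um per stain-grid pixel

    brown = np.zeros((gh, gw), dtype=np.float32)
    dark = np.zeros((gh, gw), dtype=bool)
    painted = np.zeros((gh, gw), dtype=np.int32)  # object index + 1

    tissue_poly_full = np.asarray(spec.tissue_polygon, dtype=float)
    tissue_full = polygon_pixel_mask((spec.height_px, spec.width_px), tissue_poly_full)
    tissue_stain = polygon_pixel_mask((gh, gw), (tissue_poly_full + 0.5) / 2.0 - 0.5)

    objects: list[ObjectTruth] = []

    def record(index: int, kind: str, flag: str | None, mask: np.ndarray) -> None:
        if not np.all(tissue_stain[mask]):
            raise ValueError(f"object {index} ({kind}) extends outside the tissue polygon")
        if np.any(painted[mask]):
            raise ValueError(f"object {index} ({kind}) overlaps a previous object")
        painted[mask] = index + 1
        rr, cc = np.nonzero(mask)
        objects.append(ObjectTruth(
            index=index,
            kind=kind,
            intended_flag=flag,
            pixels=np.column_stack([rr, cc]),
            area_um2=int(mask.sum()) * pitch * pitch,
            centroid=(float(cc.mean()), float(rr.mean())),
        ))

    idx = 0
    for pl in spec.plaques:
        cx = pl.center_um[0] / pitch
        cy = pl.center_um[1] / pitch
        halo = _disc_mask((gh, gw), cx, cy, pl.halo_radius_um / pitch,
                          pl.wobble_amp, pl.wobble_order)
        core = _disc_mask((gh, gw), cx, cy, pl.core_radius_um / pitch) & halo
        brown[halo] = pl.halo_brown_au
        brown[core] = pl.core_brown_au
        dark[halo] = False
        dark[core] = True
        record(idx, "plaque", None, halo)
        idx += 1
    for art in spec.artifacts:
        x0 = int(round(art.origin_um[0] / pitch))
        y0 = int(round(art.origin_um[1] / pitch))
        before = brown.copy()
        _paint_artifact(art.kind, brown, dark, (x0, y0), pitch)
        record(idx, art.kind, art.intended_flag, brown != before)
        idx += 1

    # Stain density -> full resolution, plus tissue-wide hematoxylin.
    ref = StainReference()
    brown_full = np.repeat(np.repeat(brown, 2, axis=0), 2, axis=1)
    density = brown_full[:, :, None] * ref.brown_od.astype(np.float32)
    density += (tissue_full.astype(np.float32) * spec.hematoxylin_au)[:, :, None] \
        * ref.blue_od.astype(np.float32)
    if spec.noise_sd_au > 0:
        noise = rng.normal(0.0, spec.noise_sd_au,
                           size=density.shape).astype(np.float32)
        density += tissue_full[:, :, None] * noise
        np.clip(density, 0.0, None, out=density)

    i0 = np.asarray(spec.i0, dtype=np.float32)
    intensity = i0 * np.exp(-density)
    if spec.noise_sd_au > 0:
        glass_noise = rng.integers(-1, 2, size=intensity.shape).astype(np.float32)
        intensity += (~tissue_full)[:, :, None] * glass_noise
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    slide = RGBSlide(pixels, mpp=spec.mpp, i0=spec.i0,
                     scan_magnification=spec.scan_magnification)
    plaques = [o for o in objects if o.kind == "plaque"]
    truth = SlideGroundTruth(
        objects=objects,
        tissue_mask_stain=tissue_stain,
        plaque_count=len(plaques),
        plaque_area_um2=float(sum(o.area_um2 for o in plaques)),
    )
    return slide, truth


# ---------------------------------------------------------------------------
# Canonical slide fixtures


def _rect_polygon(x0: float, y0: float, x1: float, y1: float) -> tuple:
    return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))


def clean_section_spec(seed: int = 0) -> SyntheticSlideSpec:
    """The canonical end-to-end fixture: a 4000x4000 px section at
    0.5 um/px with 200 detectable plaques and 50 artifacts (10 per removal
    rule), placed on a jittered grid so no two objects touch.

    Plaque radii, densities and positions are drawn from ranges chosen so
    every plaque passes all five rules with a comfortable margin over 8-bit
    quantisation error (halo radius 4-12 um, core at 35-50 % of the halo
    radius, core 0.65-0.85 au, halo 0.30-0.38 au).
    """
    rng = np.random.default_rng(seed)
    w = h = 4000
    cells = 16
    lo, hi = 75.0, 1925.0  # usable interior, um (75 um inside the glass border)
    cell = (hi - lo) / cells
    slots = [(i, j) for i in range(cells) for j in range(cells)]
    order = rng.permutation(len(slots))

    plaques: list[PlaqueSpec] = []
    artifacts: list[ArtifactSpec] = []
    kinds = [k for k in ARTIFACT_RULES for _ in range(10)]
    for rank, slot_idx in enumerate(order[:250]):
        i, j = slots[slot_idx]
        cx = lo + (i + 0.5) * cell
        cy = lo + (j + 0.5) * cell
        jitter = cell / 2 - 26.0  # keep 26 um of clearance inside each cell
        cx += rng.uniform(-jitter, jitter)
        cy += rng.uniform(-jitter, jitter)
        if rank < 200:
            halo_r = rng.uniform(4.0, 12.0)
            core_r = halo_r * rng.uniform(0.35, 0.50)
            plaques.append(PlaqueSpec(
                center_um=(cx, cy),
                core_radius_um=core_r,
                halo_radius_um=halo_r,
                core_brown_au=rng.uniform(0.65, 0.85),
                halo_brown_au=rng.uniform(0.30, 0.38),
            ))
        else:
            artifacts.append(ArtifactSpec(kind=kinds[rank - 200], origin_um=(cx, cy)))
    return SyntheticSlideSpec(
        width_px=w, height_px=h, mpp=0.5,
        tissue_polygon=_rect_polygon(100, 100, w - 100, h - 100),
        plaques=tuple(plaques), artifacts=tuple(artifacts),
        hematoxylin_au=0.12, noise_sd_au=0.0, seed=seed,
    )


def null_section_spec(seed: int = 0) -> SyntheticSlideSpec:
    """Tissue and glass only: segmentation must find nothing."""
    return SyntheticSlideSpec(
        width_px=800, height_px=800, mpp=0.5,
        tissue_polygon=_rect_polygon(60, 60, 740, 740),
        seed=seed,
    )


def boundary_section_spec(seed: int = 0) -> SyntheticSlideSpec:
    """Objects sitting exactly ON the printed rule thresholds.

    Three rectangles at the 1 um analysis grid: area exactly 10 um^2
    ("smaller than 10" is strict), area exactly 40 um^2 that is both
    non-elliptical and 75 % dark (at exactly 40 neither the under-40 shape
    rule nor the over-40 fraction rule applies), and 100 um^2 at dark
    fraction exactly 0.70 ("greater than 70 %" is strict). All three must
    be accepted as plaques.
    """
    return SyntheticSlideSpec(
        width_px=800, height_px=800, mpp=0.5,
        tissue_polygon=_rect_polygon(60, 60, 740, 740),
        artifacts=(
            ArtifactSpec(kind="edge_area_10", origin_um=(120.0, 120.0)),
            ArtifactSpec(kind="edge_area_40", origin_um=(120.0, 240.0)),
            ArtifactSpec(kind="edge_dark_70", origin_um=(120.0, 360.0)),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Immunoassay plates


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """A simulated calibration plate.

    Defaults mirror the canonical layout: a twelve-point two-fold serial
    dilution loaded in duplicate, duplicate blanks at the lower asymptote,
    and multiplicative signal noise at the given CV %.
    """

    a: float = 100.0
    d: float = 10000.0
    c: float = 50.0
    b: float = 1.2
    top_conc: float = 500.0
    n_points: int = 12
    dilution_factor: float = 2.0
    n_replicates: int = 2
    blank_count: int = 2
    sample_concs: tuple[float, ...] = ()
    noise_cv_pct: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2 or self.dilution_factor <= 1:
            raise ValueError("need a strictly decreasing dilution series")
        if self.noise_cv_pct < 0:
            raise ValueError("noise_cv_pct must be >= 0")

    @property
    def standard_concs(self) -> np.ndarray:
        return self.top_conc / self.dilution_factor ** np.arange(self.n_points)

    def curve(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)


def render_plate(spec: SyntheticPlateSpec) -> tuple[list[Well], dict]:
    """Simulate one plate; returns wells plus a ground-truth dict.

    Signals are ``curve(conc) * (1 + eps)`` with ``eps ~ N(0, cv/100)``
    truncated at -0.99; blanks sit at the lower asymptote under the same
    noise. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    cv = spec.noise_cv_pct / 100.0

    def noisy(true_signal: float) -> float:
        eps = max(float(rng.normal(0.0, cv)), -0.99) if cv > 0 else 0.0
        return float(true_signal) * (1.0 + eps)

    wells: list[Well] = []
    col = 1
    for i, conc in enumerate(spec.standard_concs):
        true_sig = float(spec.curve(conc))
        for rep in range(spec.n_replicates):
            wells.append(Well(
                row=chr(ord("A") + rep), col=col, role="standard",
                analyte="analyte", signal=noisy(true_sig),
                nominal_conc=float(conc), replicate_group=f"STD{i + 1}",
            ))
        col += 1
    for k in range(spec.blank_count):
        wells.append(Well(
            row=chr(ord("A") + k), col=col, role="blank", analyte="analyte",
            signal=noisy(spec.a), replicate_group="BLANK",
        ))
    col += 1
    for i, conc in enumerate(spec.sample_concs):
        true_sig = float(spec.curve(conc))
        for rep in range(spec.n_replicates):
            wells.append(Well(
                row=chr(ord("A") + rep), col=col, role="sample",
                analyte="analyte", signal=noisy(true_sig),
                replicate_group=f"S{i + 1}",
            ))
        col += 1
    truth = {
        "params": {"a": spec.a, "d": spec.d, "c": spec.c, "b": spec.b},
        "standard_concs": spec.standard_concs.copy(),
        "sample_concs": {f"S{i + 1}": c for i, c in enumerate(spec.sample_concs)},
    }
    return wells, truth


# ---------------------------------------------------------------------------
# Grouped measurements


def render_groups(
    medians: Mapping[str, float],
    spreads: Mapping[str, float] | None = None,
    ns: Mapping[str, int] | None = None,
    family: str = "lognormal",
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-group samples whose population median equals the requested one.

    ``family="lognormal"`` draws ``median * exp(spread * Z)`` with Z
    standard normal (spread is the log-scale SD, so the population median
    is exactly the requested value); ``family="normal"`` draws
    ``Normal(median, spread)``. Zero spread returns the median exactly.
    Group sizes default to 5 each, matching typical per-genotype cohort
    sizes. Deterministic per seed.
    """
    if family not in ("lognormal", "normal"):
        raise ValueError("family must be 'lognormal' or 'normal'")
    spreads = spreads or {}
    ns = ns or {}
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for name in medians:
        n = int(ns.get(name, 5))
        if n < 1:
            raise ValueError(f"group {name!r} needs n >= 1")
        med = float(medians[name])
        spread = float(spreads.get(name, 0.0))
        z = rng.standard_normal(n)
        if family == "lognormal":
            out[str(name)] = med * np.exp(spread * z)
        else:
            out[str(name)] = med + spread * z
    return out
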