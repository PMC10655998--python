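"""Readers and writers for slides, region annotations, reports and plate tables.

No science lives here: this module validates external formats (8-bit RGB
TIFF/PNG slides, GeoJSON polygon annotations, CSV plate tables and CSV
region reports) and hands the pipeline clean, typed objects.

Coordinate convention: raster indices are 0-based, x to the right and y
down, with polygon vertices expressed at pixel centres of the full
resolution scan. Physical scale is carried separately as microns per pixel
(``mpp``).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon

from .errors import RegionError, SlideFormatError

__all__ = [
    "RGBSlide",
    "Region",
    "read_slide",
    "write_slide",
    "read_regions",
    "write_report",
    "read_report",
    "read_plate",
]


@dataclass
class RGBSlide:
    """A calibrated 8-bit brightfield scan.

    ``i0`` is the per-channel background (clear glass) reference intensity
    used by the Beer-Lambert transform; brightfield glass is near saturation
    so the default is 255 per channel.
    """

    pixels: np.ndarray
    mpp: float
    i0: tuple[float, float, float] = (255.0, 255.0, 255.0)
    scan_magnification: int = 40

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise SlideFormatError(
                f"expected a 3-channel raster, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise SlideFormatError(
                f"unsupported bit depth: expected 8-bit, got {self.pixels.dtype}"
            )
        if not self.mpp > 0:
            raise SlideFormatError(f"mpp must be positive, got {self.mpp}")
        self.i0 = tuple(float(v) for v in self.i0)
        if len(self.i0) != 3 or not all(0 < v <= 255 for v in self.i0):
            raise SlideFormatError("i0 must be three values in (0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class Region:
    """A named polygonal annotation in full-resolution pixel coordinates."""

    name: str
    vertices: np.ndarray  # (n, 2) array of (x, y)
    polygon: Polygon = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise RegionError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise RegionError(f"region {self.name!r} needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise RegionError(f"region {self.name!r} is not a valid polygon "
                              f"({shapely.is_valid_reason(poly)})")
        if poly.area <= 0:
            raise RegionError(f"region {self.name!r} has zero area")
        self.polygon = poly


def read_slide(
    path: str | pathlib.Path,
    mpp: float,
    i0: Sequence[float] = (255.0, 255.0, 255.0),
    scan_magnification: int = 40,
) -> RGBSlide:
    """Read an 8-bit 3-channel TIFF or PNG into an :class:`RGBSlide`.

    Grayscale, paletted, alpha-carrying or >8-bit images are rejected with
    :class:`~amyquant.errors.SlideFormatError` rather than coerced.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        with Image.open(path) as img:
            if img.mode not in ("RGB",):
                raise SlideFormatError(
                    f"unsupported PNG mode {img.mode!r}; expected 8-bit RGB"
                )
            arr = np.asarray(img)
    else:
        raise SlideFormatError(f"unsupported image format: {suffix!r}")
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        raise SlideFormatError(f"unsupported bit depth: {arr.dtype}")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise SlideFormatError(f"expected 3 channels, got shape {arr.shape}")
    return RGBSlide(arr, mpp=mpp, i0=tuple(i0), scan_magnification=scan_magnification)


def write_slide(slide: RGBSlide, path: str | pathlib.Path) -> None:
    """Write a slide raster to TIFF or PNG (lossless, bit-exact round trip)."""
    path = pathlib.Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, slide.pixels)
    elif suffix == ".png":
        Image.fromarray(slide.pixels, mode="RGB").save(path)
    else:
        raise SlideFormatError(f"unsupported image format: {suffix!r}")


def read_regions(path: str | pathlib.Path) -> list[Region]:
    """Read a GeoJSON FeatureCollection of named polygons.

    Each feature must carry Polygon geometry and a ``name`` property.
    Duplicate names are disambiguated deterministically with ``#2``, ``#3``
    and so on, in file order.
    """
    path = pathlib.Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise RegionError("expected a GeoJSON FeatureCollection")
    regions: list[Region] = []
    seen: dict[str, int] = {}
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            raise RegionError(
                f"unsupported geometry type {geom.get('type')!r}; only Polygon is accepted"
            )
        rings = geom.get("coordinates") or []
        if not rings:
            raise RegionError("polygon feature with no coordinate ring")
        exterior = np.asarray(rings[0], dtype=float)
        # GeoJSON rings repeat the first vertex at the end; drop the closure.
        if len(exterior) > 1 and np.allclose(exterior[0], exterior[-1]):
            exterior = exterior[:-1]
        name = str((feat.get("properties") or {}).get("name", "region"))
        count = seen.get(name, 0) + 1
        seen[name] = count
        if count > 1:
            name = f"{name}#{count}"
        regions.append(Region(name=name, vertices=exterior))
    return regions


_REPORT_COLUMNS = (
    "region",
    "tissue_area_um2",
    "plaque_count",
    "plaque_area_um2",
    "plaque_coverage_pct",
    "brown_coverage_pct",
)


def write_report(reports: Iterable, path: str | pathlib.Path) -> None:
    """Write region reports as CSV, floats at 6 significant digits.

    Accepts any iterable of objects exposing the
    :class:`~amyquant.quantify.RegionReport` fields.
    """
    rows = []
    for rep in reports:
        rows.append({
            "region": rep.region_name,
            "tissue_area_um2": rep.tissue_area_um2,
            "plaque_count": rep.plaque_count,
            "plaque_area_um2": rep.plaque_area_um2,
            "plaque_coverage_pct": rep.plaque_coverage_pct,
            "brown_coverage_pct": rep.brown_coverage_pct,
        })
    if not rows:
        raise ValueError("cannot write an empty report list")
    df = pd.DataFrame(rows, columns=list(_REPORT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6g")


def read_report(path: str | pathlib.Path) -> pd.DataFrame:
    """Read back a region-report CSV written by :func:`write_report`."""
    df = pd.read_csv(path)
    missing = set(_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"report file missing columns: {sorted(missing)}")
    return df


def read_plate(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a plate table CSV (columns row, col, role, analyte,
    replicate_group, nominal_conc, signal) into a validated DataFrame."""
    df = pd.read_csv(path)
    required = {"row", "col", "role", "analyte", "replicate_group", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate file missing columns: {sorted(missing)}")
    if "nominal_conc" not in df.columns:
        df["nominal_conc"] = np.nan
    bad = set(df["role"]) - {"standard", "blank", "sample"}
    if bad:
        raise ValueError(f"unknown well roles: {sorted(bad)}")
    if df.loc[df["role"] == "standard", "nominal_conc"].isna().any():
        raise ValueError("standard wells must carry nominal_conc")
    return df
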