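"""Per-region and whole-section plaque burden aggregation.

A plaque belongs to a region iff its centroid lies inside the region
polygon (boundary inclusive). The centroid rule makes counts additive over
any disjoint partition of the section, which is what a per-region export
implies. Coverage percentages are taken against tissue area within the
region, not raw polygon area, since glass has already been excluded by the
tissue step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import RegionError
from .geometry import polygon_pixel_mask
from .io import Region
from .segmentation import CLASS_NONE, BrownClassMask, CandidateObject

__all__ = ["RegionReport", "quantify_region", "quantify_section"]


@dataclass
class RegionReport:
    """Plaque burden summary for one region (or the whole section)."""

    region_name: str
    tissue_area_um2: float
    plaque_count: int
    plaque_area_um2: float
    plaque_coverage_pct: float
    brown_coverage_pct: float


def _to_stain_grid(vertices: np.ndarray, downsample: int) -> np.ndarray:
    """Map full-resolution pixel-centre coordinates onto the stain grid.

    A block of ``downsample`` x ``downsample`` full-resolution pixels maps
    to one stain-grid pixel whose centre sits at the block centre.
    """
    return (np.asarray(vertices, dtype=float) + 0.5) / downsample - 0.5


def _coverage_report(
    name: str,
    plaques: Sequence[CandidateObject],
    counted: Sequence[CandidateObject],
    classes: BrownClassMask,
    tissue: np.ndarray,
    region_mask: np.ndarray,
) -> RegionReport:
    px_area = classes.mpp ** 2
    tissue_in = tissue & region_mask
    tissue_px = int(np.count_nonzero(tissue_in))
    tissue_area = tissue_px * px_area
    plaque_area = float(sum(p.area_um2 for p in counted))
    brown_px = int(np.count_nonzero((classes.labels != CLASS_NONE) & tissue_in))
    return RegionReport(
        region_name=name,
        tissue_area_um2=tissue_area,
        plaque_count=len(counted),
        plaque_area_um2=plaque_area,
        plaque_coverage_pct=100.0 * plaque_area / tissue_area if tissue_area > 0 else 0.0,
        brown_coverage_pct=100.0 * brown_px / tissue_px if tissue_px > 0 else 0.0,
    )


def quantify_region(
    plaques: Sequence[CandidateObject],
    classes: BrownClassMask,
    tissue: np.ndarray,
    region: Region,
    downsample: int = 2,
) -> RegionReport:
    """Plaque burden within one annotated region.

    Parameters
    ----------
    plaques
        Accepted plaques on the stain grid.
    classes
        Stain class raster (stain grid).
    tissue
        Boolean tissue mask on the stain grid.
    region
        Polygon in full-resolution pixel coordinates; ``downsample`` is the
        stain grid's downsampling factor relative to that coordinate frame.

    A plaque is counted iff its centroid falls inside the polygon,
    boundary included; its full area is attributed to the region.
    """
    verts = _to_stain_grid(region.vertices, downsample)
    poly = Polygon(verts)
    shape = classes.labels.shape
    region_mask = polygon_pixel_mask(shape, verts)
    minx, miny, maxx, maxy = poly.bounds
    if maxx < -0.5 or maxy < -0.5 or minx > shape[1] - 0.5 or miny > shape[0] - 0.5:
        raise RegionError(f"region {region.name!r} lies fully outside the raster")
    counted = [p for p in plaques if poly.covers(Point(p.centroid))]
    return _coverage_report(region.name, plaques, counted, classes, tissue, region_mask)


def quantify_section(
    plaques: Sequence[CandidateObject],
    classes: BrownClassMask,
    tissue: np.ndarray,
    name: str = "section",
) -> RegionReport:
    """Whole-section plaque burden: every plaque counts, the region is the
    full raster."""
    full = np.ones(classes.labels.shape, dtype=bool)
    return _coverage_report(name, plaques, list(plaques), classes, tissue, full)
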