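"""Tumor-region construction and distance-band zonation of TMA cores.

Each core disc is partitioned into three compartments relative to the tumor
region: *intratumoral* (inside the tumor mask, boundary inclusive), *close*
(outside the tumor but within ``close_band_um`` — default 50 µm — of its
boundary, the 50 µm point itself counting as close) and *distant* (the
rest of the core).  Compartments whose area falls below a minimum
(default 0.01 mm²) are flagged excluded and contribute neither cells nor
area to downstream densities, which guards against unstable density
estimates from vanishing denominators.

All geometry is vector-based (shapely polygons) in micron coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class SpatialConfig:
    close_band_um: float = 50.0
    min_region_area_mm2: float = 0.01
    tumor_mask_method: str = "union_of_disks"  # or "provided_mask"
    tumor_disk_radius_um: float = 25.0
    closing_radius_um: float = 30.0
    #: Boundary convention: distance exactly close_band_um from the tumor is
    #: "close" when True (half-open (0, band]), "distant" otherwise.
    band_boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.close_band_um <= 0:
            raise ValueError("close_band_um must be positive")
        if self.min_region_area_mm2 < 0:
            raise ValueError("min_region_area_mm2 must be non-negative")


@dataclass
class CompartmentMap:
    """Per-core tessellation into the three compartments.

    ``regions`` maps compartment name to its (possibly empty) geometry;
    ``areas_mm2`` holds exact vector areas; ``excluded`` lists compartments
    failing the minimum-area rule (0 < area < minimum).  ``tumor`` keeps the
    raw tumor mask used for distance queries.
    """

    core_id: str
    regions: dict
    areas_mm2: dict
    excluded: set
    tumor: Polygon | MultiPolygon
    core: Polygon
    close_band_um: float
    band_boundary_inclusive: bool = True

    @property
    def total_area_mm2(self) -> float:
        """Total retained (non-excluded) area."""
        return sum(a for name, a in self.areas_mm2.items() if name not in self.excluded)

    @property
    def total_area_all_mm2(self) -> float:
        """Total area including excluded sub-minimum regions."""
        return sum(self.areas_mm2.values())


def core_disc(diameter_um: float, center: tuple[float, float] | None = None,
              quad_segs: int = 128) -> Polygon:
    """Circular core boundary polygon of the given diameter (microns)."""
    r = diameter_um / 2.0
    cx, cy = center if center is not None else (r, r)
    return Point(cx, cy).buffer(r, quad_segs=quad_segs)


def build_tumor_mask(
    cells: pd.DataFrame | None,
    core: Polygon,
    cfg: SpatialConfig,
    mask=None,
):
    """Tumor region polygons for one core.

    ``union_of_disks``: the union of disks of ``tumor_disk_radius_um`` around
    Tumor-phenotyped cells, morphologically closed at ``closing_radius_um``
    and clipped to the core disc.  ``provided_mask`` validates and clips the
    supplied geometry instead.
    """
    if cfg.tumor_mask_method == "provided_mask" or mask is not None:
        if mask is None:
            raise ValueError("provided_mask method requires a mask geometry")
        if not mask.is_valid:
            raise ValueError("provided tumor mask is not a valid geometry")
        return mask.intersection(core)
    if cells is None:
        raise ValueError("union_of_disks method requires a phenotyped cell table")
    tumor_cells = cells[cells["phenotype"] == "Tumor"]
    if len(tumor_cells) == 0:
        return Polygon()  # no tumor detected: whole core is distant
    disks = [
        Point(x, y).buffer(cfg.tumor_disk_radius_um, quad_segs=16)
        for x, y in zip(tumor_cells["x_um"], tumor_cells["y_um"])
    ]
    union = unary_union(disks)
    closed = union.buffer(cfg.closing_radius_um).buffer(-cfg.closing_radius_um)
    return closed.intersection(core)


def compute_compartments(tumor, core: Polygon, cfg: SpatialConfig,
                         core_id: str = "core") -> CompartmentMap:
    """Partition a core disc into intratumoral / close / distant regions.

    ``close`` is the set of points outside the tumor whose distance to the
    tumor boundary is at most ``close_band_um``; ``distant`` is the remaining
    core area.  Regions with 0 < area < ``min_region_area_mm2`` are flagged
    excluded.
    """
    if tumor is None:
        tumor = Polygon()
    tumor = tumor.intersection(core)
    if tumor.is_empty:
        close = Polygon()
        distant = core
    else:
        band = tumor.buffer(cfg.close_band_um, quad_segs=64)
        close = band.difference(tumor).intersection(core)
        distant = core.difference(band)
    regions = {"intratumoral": tumor, "close": close, "distant": distant}
    areas = {name: geom.area / UM2_PER_MM2 for name, geom in regions.items()}
    # Excluded <=> area below the minimum (zero-area regions included, so an
    # absent tumor yields missing rather than 0/0 densities downstream).
    excluded = {name for name, a in areas.items() if a < cfg.min_region_area_mm2}
    return CompartmentMap(
        core_id=core_id,
        regions=regions,
        areas_mm2=areas,
        excluded=excluded,
        tumor=tumor,
        core=core,
        close_band_um=cfg.close_band_um,
        band_boundary_inclusive=cfg.band_boundary_inclusive,
    )


def assign_compartment(x_um: float, y_um: float, cmap: CompartmentMap) -> str:
    """Compartment label of a single in-core position.

    The tumor boundary itself is intratumoral; a point exactly
    ``close_band_um`` from the tumor is close under the default inclusive
    convention.  Positions outside the core raise.
    """
    p = Point(x_um, y_um)
    if not cmap.core.covers(p):
        raise ValueError(f"position ({x_um}, {y_um}) lies outside the core")
    if not cmap.tumor.is_empty:
        if cmap.tumor.covers(p):
            return "intratumoral"
        d = cmap.tumor.distance(p)
        if (d <= cmap.close_band_um) if cmap.band_boundary_inclusive else (d < cmap.close_band_um):
            return "close"
    return "distant"


def assign_compartments(cells: pd.DataFrame, cmap: CompartmentMap) -> pd.DataFrame:
    """Vectorized compartment assignment for a whole cell table."""
    import shapely

    xs = cells["x_um"].to_numpy(dtype=float)
    ys = cells["y_um"].to_numpy(dtype=float)
    pts = shapely.points(np.column_stack([xs, ys]))
    outside = ~shapely.covers(cmap.core, pts)
    if outside.any():
        i = int(np.flatnonzero(outside)[0])
        raise ValueError(f"cell at ({xs[i]}, {ys[i]}) lies outside the core")
    labels = np.full(len(cells), "distant", dtype=object)
    if not cmap.tumor.is_empty:
        in_tumor = shapely.covers(cmap.tumor, pts)
        labels[in_tumor] = "intratumoral"
        rest = ~in_tumor
        d = shapely.distance(cmap.tumor, pts[rest])
        in_band = d <= cmap.close_band_um if cmap.band_boundary_inclusive else d < cmap.close_band_um
        lab_rest = np.where(in_band, "close", "distant")
        labels[rest] = lab_rest
    out = cells.copy()
    out["compartment"] = pd.Series(labels, index=cells.index, dtype="string")
    return out
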