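"""Landscape metrics inside a home range: proportion of a class, landscape
shape index, edge density, and Shannon-Wiener diversity.

All metrics operate on a clip of a categorical raster: the cells whose centres
fall inside a range polygon. Edges use 4-neighbour (rook) adjacency. A class
edge is a cell side shared between a class cell and a different class; sides
on the clip boundary (adjacent to a masked cell or to the outside of the
grid) count toward the edge total by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .geo_io import CoverRaster
from .home_range import RangePolygon


@dataclass
class RangeMetrics:
    """Per-animal-year covariates of the home-range-size models."""

    animal_id: object
    year: object
    status: str | None
    hr_area_km2: float
    log10_area: float
    per_season: dict  # season_id -> {"prop": ..., "lsi": ..., "edge": ...}
    lsi_water: float | None
    edge_density_water: float
    shannon: float


def clip_raster(values: np.ndarray, cell_size: float, origin, polygon) -> np.ma.MaskedArray:
    """Mask a raster to the cells whose centres lie inside ``polygon``."""
    values = np.asarray(values)
    geom = polygon.geometry if isinstance(polygon, RangePolygon) else polygon
    n_rows, n_cols = values.shape
    x0, y0 = origin
    xs = x0 + (np.arange(n_cols) + 0.5) * cell_size
    ys = y0 + (np.arange(n_rows) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(values.shape)
    if not inside.any():
        raise ValueError("empty clip: no cell centres inside polygon")
    return np.ma.MaskedArray(values, mask=~inside)


def class_proportion(masked: np.ma.MaskedArray, class_code: int) -> float:
    """Fraction of unmasked cells holding ``class_code``."""
    n = masked.count()
    if n == 0:
        raise ValueError("empty clip")
    return float((masked == class_code).sum() / n)


def class_edge_length(
    masked: np.ma.MaskedArray,
    class_code: int,
    cell_size: float,
    count_boundary: bool = True,
) -> float:
    """Total edge length (metres) of a class under rook adjacency.

    An edge is a side of a class cell adjacent to a different class; sides
    facing masked cells or the grid exterior count iff ``count_boundary``.
    """
    valid = ~np.ma.getmaskarray(masked)
    is_class = (np.ma.getdata(masked) == class_code) & valid
    edges = 0
    pad_class = np.pad(is_class, 1, constant_values=False)
    pad_valid = np.pad(valid, 1, constant_values=False)
    for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
        nb_class = np.roll(np.roll(pad_class, dr, 0), dc, 1)[1:-1, 1:-1]
        nb_valid = np.roll(np.roll(pad_valid, dr, 0), dc, 1)[1:-1, 1:-1]
        interior = is_class & nb_valid & ~nb_class
        boundary = is_class & ~nb_valid
        edges += interior.sum() + (boundary.sum() if count_boundary else 0)
    return float(edges) * cell_size


def landscape_shape_index(
    masked: np.ma.MaskedArray,
    class_code: int,
    cell_size: float,
    count_boundary: bool = True,
) -> float:
    """LSI = 0.25 * E / sqrt(A): standardized perimeter-to-area ratio.

    E is the class's total edge length and A its area; a single compact
    square patch yields exactly 1, dispersed or convoluted classes more.
    Undefined (raises) when the class is absent from the clip.
    """
    n_class = int(((masked == class_code) & ~np.ma.getmaskarray(masked)).sum())
    if n_class == 0:
        raise ValueError("class absent from clip; LSI undefined")
    e = class_edge_length(masked, class_code, cell_size, count_boundary)
    a = n_class * cell_size**2
    return 0.25 * e / np.sqrt(a)


def edge_density(
    masked: np.ma.MaskedArray,
    class_code: int,
    cell_size: float,
    count_boundary: bool = True,
) -> float:
    """Class edge length per landscape area, in metres per hectare."""
    n = masked.count()
    if n == 0:
        raise ValueError("empty clip")
    e = class_edge_length(masked, class_code, cell_size, count_boundary)
    area_ha = n * cell_size**2 / 1e4
    return e / area_ha


def shannon_diversity(masked: np.ma.MaskedArray) -> float:
    """Shannon-Wiener H = -sum p_i ln p_i over classes present in the clip."""
    vals = masked.compressed()
    if len(vals) == 0:
        raise ValueError("empty clip")
    _, counts = np.unique(vals, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


METRIC_COLUMNS = [
    "animal_id", "year", "rs",
    "s1prop", "s1lsi", "s1edge",
    "s2prop", "s2lsi", "s2edge",
    "s3prop", "s3lsi", "s3edge",
    "wlsi", "wedge", "shannon", "hr_area_km2", "log10_area",
]


def range_metrics(
    hr_polygon,
    cover_raster: CoverRaster,
    selection_maps: dict,
    animal_id=None,
    year=None,
    status: str | None = None,
    count_boundary: bool = True,
) -> RangeMetrics:
    """All Table-4-style covariates for one annual kernel home range.

    ``selection_maps`` maps season_id to the reclassified SelectionMap;
    per-season metrics (prop/lsi/edge) target the highly-selected class,
    water metrics the water class of the original raster, and diversity the
    original (not reclassified) cover raster.
    """
    from .rsf import H_CODE  # local import to avoid a cycle

    geom = hr_polygon.geometry if isinstance(hr_polygon, RangePolygon) else hr_polygon
    cover_clip = clip_raster(
        cover_raster.values, cover_raster.cell_size, cover_raster.origin, geom
    )
    c = cover_raster.cell_size
    per_season = {}
    for sid, smap in selection_maps.items():
        clip = clip_raster(smap.values, smap.cell_size, smap.origin, geom)
        prop = class_proportion(clip, H_CODE)
        if prop > 0:
            lsi = landscape_shape_index(clip, H_CODE, c, count_boundary)
            edge = edge_density(clip, H_CODE, c, count_boundary)
        else:
            lsi, edge = np.nan, 0.0
        per_season[sid] = {"prop": prop, "lsi": lsi, "edge": edge}
    water = cover_raster.water_code
    if water is not None and class_proportion(cover_clip, water) > 0:
        lsi_w = landscape_shape_index(cover_clip, water, c, count_boundary)
        edge_w = edge_density(cover_clip, water, c, count_boundary)
    else:
        lsi_w, edge_w = np.nan, 0.0
    area = geom.area / 1e6
    return RangeMetrics(
        animal_id=animal_id,
        year=year,
        status=status,
        hr_area_km2=area,
        log10_area=float(np.log10(area)),
        per_season=per_season,
        lsi_water=lsi_w,
        edge_density_water=edge_w,
        shannon=shannon_diversity(cover_clip),
    )


def metrics_table(metrics: list[RangeMetrics]) -> pd.DataFrame:
    """Stack RangeMetrics into the covariate table used by the model stage."""
    rows = []
    for m in metrics:
        row = {
            "animal_id": m.animal_id,
            "year": m.year,
            "rs": m.status,
            "wlsi": m.lsi_water,
            "wedge": m.edge_density_water,
            "shannon": m.shannon,
            "hr_area_km2": m.hr_area_km2,
            "log10_area": m.log10_area,
        }
        for sid, vals in m.per_season.items():
            row[f"s{sid}prop"] = vals["prop"]
            row[f"s{sid}lsi"] = vals["lsi"]
            row[f"s{sid}edge"] = vals["edge"]
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in METRIC_COLUMNS if c in df.columns]
    return df[cols + [c for c in df.columns if c not in cols]]
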