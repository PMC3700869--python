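"""Raster/vector I/O and GPS-fix annotation.

Conventions (fixed across the package):

* Planar coordinates in metres; any projection happens upstream.
* ``CoverRaster.values[row, col]`` with row 0 at the *bottom* of the grid;
  ``origin = (x0, y0)`` is the lower-left outer corner.
* Cells are half-open: cell (i, j) covers ``[x0+j*c, x0+(j+1)*c) x
  [y0+i*c, y0+(i+1)*c)``, so a point on a shared edge belongs to the cell on
  the +x/+y side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

log = logging.getLogger(__name__)

FIX_COLUMNS = ["animal_id", "timestamp", "x", "y"]


@dataclass
class CoverRaster:
    """Regular categorical grid of cover classes.

    values: integer class codes, shape (n_rows, n_cols), row 0 at the bottom.
    cell_size: cell edge length in metres.
    origin: (x0, y0) of the lower-left outer corner.
    legend: code -> class label; must cover every code in ``values``.
    water_code: the single reference (water) class code.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    legend: dict[int, str] = field(default_factory=dict)
    water_code: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("raster values must be integer class codes")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        present = set(np.unique(self.values).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes {sorted(missing)} absent from legend")
        if self.water_code is not None and self.water_code not in self.legend:
            raise ValueError("water_code not in legend")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer envelope."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def cell_index(self, x, y):
        """Half-open (row, col) indices of the cells containing (x, y)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x, float) - x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, float) - y0) / self.cell_size).astype(int)
        return row, col

    def cell_centers(self):
        """(X, Y) coordinate arrays of every cell centre, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        c = self.cell_size
        xs = x0 + (np.arange(self.n_cols) + 0.5) * c
        ys = y0 + (np.arange(self.n_rows) + 0.5) * c
        return np.meshgrid(xs, ys)

    def class_proportions(self) -> dict[int, float]:
        codes, counts = np.unique(self.values, return_counts=True)
        total = self.values.size
        return {int(k): float(n) / total for k, n in zip(codes, counts)}


def write_raster(raster: CoverRaster, path: str | Path) -> None:
    """Write a single-band integer TIFF plus a legend/georeference sidecar JSON.

    The sidecar (``<path>.json``) holds cell_size, origin, the code->label
    legend with a "role" of cover|water, matching the package's text-based
    exchange format.
    """
    path = Path(path)
    tifffile.imwrite(path, raster.values.astype(np.int32))
    sidecar = {
        "cell_size": raster.cell_size,
        "origin": list(raster.origin),
        "legend": [
            {
                "code": int(code),
                "label": label,
                "role": "water" if code == raster.water_code else "cover",
            }
            for code, label in sorted(raster.legend.items())
        ],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_raster(path: str | Path) -> CoverRaster:
    """Read a raster written by :func:`write_raster`.

    Errors on multi-band or non-integer input and on a missing sidecar legend.
    Round-trips bit-exactly: codes, cell_size, origin and legend are preserved.
    """
    path = Path(path)
    values = tifffile.imread(path)
    if values.ndim != 2:
        raise ValueError("expected a single-band raster")
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError("expected an integer band")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing legend sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    legend = {int(e["code"]): e["label"] for e in meta["legend"]}
    water = [int(e["code"]) for e in meta["legend"] if e.get("role") == "water"]
    if len(water) > 1:
        raise ValueError("more than one water class in legend")
    return CoverRaster(
        values=values,
        cell_size=float(meta["cell_size"]),
        origin=tuple(meta["origin"]),
        legend=legend,
        water_code=water[0] if water else None,
    )


def write_fixes(fixes: pd.DataFrame, path: str | Path) -> None:
    """Write a fix table as CSV with ISO-8601 timestamps."""
    out = fixes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out.to_csv(path, index=False)


def read_fixes(path: str | Path) -> pd.DataFrame:
    fixes = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in fixes.columns]
    if missing:
        raise ValueError(f"fix table missing columns {missing}")
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    return fixes


def annotate_fixes(fixes: pd.DataFrame, raster: CoverRaster) -> pd.DataFrame:
    """Label each fix with the cover code of the cell containing it.

    Cell membership follows the half-open convention. Fixes outside the raster
    are excluded and counted in the log. Also derives ``week_of_year``
    (1 + (day_of_year - 1) // 7). Idempotent: re-annotating changes nothing.
    """
    fixes = fixes.copy()
    row, col = raster.cell_index(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    inside = (row >= 0) & (row < raster.n_rows) & (col >= 0) & (col < raster.n_cols)
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.warning("annotate_fixes: %d fixes outside raster excluded", n_dropped)
    fixes = fixes.loc[inside].reset_index(drop=True)
    fixes["cover_code"] = raster.values[row[inside], col[inside]]
    ts = pd.to_datetime(fixes["timestamp"])
    fixes["week_of_year"] = 1 + (ts.dt.dayofyear - 1) // 7
    return fixes


def assign_seasons(fixes: pd.DataFrame, breaks_week: list[int]) -> pd.DataFrame:
    """Add a 1-based ``season_id`` from ordered week breaks.

    ``breaks_week=[31, 39]`` means season 1 runs through week 31, season 2
    through week 39, season 3 afterwards (the break week belongs to the
    earlier season).
    """
    if sorted(breaks_week) != list(breaks_week):
        raise ValueError("breaks_week must be strictly increasing")
    fixes = fixes.copy()
    week = fixes["week_of_year"].to_numpy()
    season = np.searchsorted(np.asarray(breaks_week), week, side="left") + 1
    fixes["season_id"] = season
    return fixes


def write_polygon_geojson(geometry, path: str | Path, properties: dict | None = None):
    """Write a shapely geometry as a single-feature GeoJSON file."""
    feature = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": mapping(geometry),
    }
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": [feature]})
    )


def read_polygon_geojson(path: str | Path):
    doc = json.loads(Path(path).read_text())
    return shape(doc["features"][0]["geometry"])
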