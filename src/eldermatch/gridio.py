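"""Esri ASCII grid and GeoJSON reading/writing.

The ASCII grid format is six header lines (ncols, nrows, xllcorner,
yllcorner, cellsize, NODATA_value) followed by row-major cell values,
north row first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass
class AsciiGrid:
    """A regular raster with the Esri ASCII-grid georeferencing convention.

    ``data[0, :]`` is the northernmost row; ``(xllcorner, yllcorner)`` is the
    outer corner of the south-west cell.  ``cellsize`` is in the same planar
    units as any coordinates compared against the grid (metres here).
    """

    data: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def value_at(self, x: float, y: float) -> float:
        """Sample the cell containing planar point (x, y); clamps to the edge."""
        col = int((x - self.xllcorner) / self.cellsize)
        row_from_south = int((y - self.yllcorner) / self.cellsize)
        col = min(max(col, 0), self.ncols - 1)
        row_from_south = min(max(row_from_south, 0), self.nrows - 1)
        return float(self.data[self.nrows - 1 - row_from_south, col])


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return AsciiGrid(
        data=data,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: AsciiGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.6f}\n")
        fh.write(f"yllcorner {grid.yllcorner:.6f}\n")
        fh.write(f"cellsize {grid.cellsize:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        np.savetxt(fh, grid.data, fmt="%.4f")


def write_geojson(
    geometries: Iterable[BaseGeometry],
    properties: Iterable[Mapping],
    path: str | Path,
) -> None:
    """Write geometries + per-feature properties as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": dict(props)}
        for geom, props in zip(geometries, properties, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    with open(path) as fh:
        fc = json.load(fh)
    geoms = [shape(feat["geometry"]) for feat in fc["features"]]
    props = [feat.get("properties", {}) for feat in fc["features"]]
    return geoms, props
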