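"""Raster grid geometry and the bioclimatic-layer stack.

A :class:`GridGeometry` is a regular lon/lat (WGS84) grid defined by its
south-west corner, cell size in decimal degrees and cell counts.  Cells are
indexed row-major from the south-west: ``cell_id = iy * n_x + ix`` with
``ix`` increasing eastward and ``iy`` northward.  Point-in-cell membership
uses half-open intervals [west, east) x [south, north) so every point maps
to at most one cell.

A :class:`ClimateStack` holds named co-registered layers (2-d arrays shaped
``(n_y, n_x)``) such as bioclimatic indices, plus an optional altitude band.
Layers are stored and exchanged on disk as ESRI ASCII grids (a plain-text
raster format) with a JSON sidecar naming the bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridGeometry", "ClimateStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridGeometry:
    origin_lon: float  # west edge, degrees
    origin_lat: float  # south edge, degrees
    cell_size_deg: float
    n_x: int
    n_y: int

    def __post_init__(self):
        if self.n_x <= 0 or self.n_y <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size_deg <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    @property
    def east(self) -> float:
        return self.origin_lon + self.n_x * self.cell_size_deg

    @property
    def north(self) -> float:
        return self.origin_lat + self.n_y * self.cell_size_deg

    def contains(self, lon, lat):
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        return (lon >= self.origin_lon) & (lon < self.east) & \
               (lat >= self.origin_lat) & (lat < self.north)

    def cell_index(self, lon, lat):
        """Map points to (ix, iy); raises if any point is outside the grid."""
        lon = np.atleast_1d(np.asarray(lon, float))
        lat = np.atleast_1d(np.asarray(lat, float))
        inside = self.contains(lon, lat)
        if not np.all(inside):
            bad = np.nonzero(~inside)[0]
            raise ValueError(f"points outside raster extent at indices {bad.tolist()}")
        ix = np.floor((lon - self.origin_lon) / self.cell_size_deg).astype(int)
        iy = np.floor((lat - self.origin_lat) / self.cell_size_deg).astype(int)
        # floating point can push a boundary point to the upper edge
        ix = np.clip(ix, 0, self.n_x - 1)
        iy = np.clip(iy, 0, self.n_y - 1)
        return ix, iy

    def cell_id(self, lon, lat):
        ix, iy = self.cell_index(lon, lat)
        return iy * self.n_x + ix

    def cell_center(self, cell_id):
        """Cell-centre (lon, lat) for integer cell ids."""
        cell_id = np.asarray(cell_id, int)
        if np.any(cell_id < 0) or np.any(cell_id >= self.n_cells):
            raise ValueError("cell_id out of range")
        iy, ix = np.divmod(cell_id, self.n_x)
        lon = self.origin_lon + (ix + 0.5) * self.cell_size_deg
        lat = self.origin_lat + (iy + 0.5) * self.cell_size_deg
        return lon, lat

    def all_cell_ids(self):
        return np.arange(self.n_cells)

    def center_arrays(self):
        """Cell-centre lon/lat arrays shaped (n_y, n_x)."""
        lon = self.origin_lon + (np.arange(self.n_x) + 0.5) * self.cell_size_deg
        lat = self.origin_lat + (np.arange(self.n_y) + 0.5) * self.cell_size_deg
        return np.meshgrid(lon, lat)

    def to_dict(self):
        return {"origin_lon": self.origin_lon, "origin_lat": self.origin_lat,
                "cell_size_deg": self.cell_size_deg, "n_x": self.n_x, "n_y": self.n_y}


class ClimateStack:
    """Named co-registered raster layers over one :class:`GridGeometry`.

    ``layers`` maps band name (e.g. ``"bio01"``) to a float array shaped
    ``(n_y, n_x)`` with row 0 at the southern edge.  NaN marks missing data.
    """

    def __init__(self, geometry: GridGeometry, layers: dict[str, np.ndarray],
                 altitude: np.ndarray | None = None):
        if not layers:
            raise ValueError("stack needs at least one layer")
        shape = (geometry.n_y, geometry.n_x)
        checked = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, float)
            if arr.shape != shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} not co-registered with "
                    f"grid shape {shape}")
            checked[name] = arr
        self.geometry = geometry
        self.layers = checked
        if altitude is not None:
            altitude = np.asarray(altitude, float)
            if altitude.shape != shape:
                raise ValueError("altitude band not co-registered with grid")
        self.altitude = altitude

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def values_at_cells(self, name: str, cell_ids) -> np.ndarray:
        arr = self.layers[name] if name != "altitude" else self.altitude
        if arr is None:
            raise ValueError("stack has no altitude band")
        cell_ids = np.asarray(cell_ids, int)
        if np.any(cell_ids < 0) or np.any(cell_ids >= self.geometry.n_cells):
            raise ValueError("cell_id out of range")
        iy, ix = np.divmod(cell_ids, self.geometry.n_x)
        return arr[iy, ix]

    def write(self, directory) -> None:
        """Write each band as an ESRI ASCII grid plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.geometry)
        if self.altitude is not None:
            write_ascii_grid(directory / "altitude.asc", self.altitude, self.geometry)
        manifest = {"geometry": self.geometry.to_dict(),
                    "layers": self.layer_names,
                    "altitude": self.altitude is not None}
        (directory / "stack.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, directory) -> "ClimateStack":
        directory = Path(directory)
        manifest = json.loads((directory / "stack.json").read_text())
        geometry = GridGeometry(**manifest["geometry"])
        layers = {}
        for name in manifest["layers"]:
            arr, geo = read_ascii_grid(directory / f"{name}.asc")
            layers[name] = arr
        altitude = None
        if manifest.get("altitude"):
            altitude, _ = read_ascii_grid(directory / "altitude.asc")
        return cls(geometry, layers, altitude=altitude)


def write_ascii_grid(path, array: np.ndarray, geometry: GridGeometry,
                     nodata: float = -9999.0) -> None:
    """Write one band as an ESRI ASCII grid (text raster, north row first)."""
    array = np.asarray(array, float)
    out = np.where(np.isnan(array), nodata, array)
    header = (f"ncols {geometry.n_x}\n"
              f"nrows {geometry.n_y}\n"
              f"xllcorner {geometry.origin_lon!r}\n"
              f"yllcorner {geometry.origin_lat!r}\n"
              f"cellsize {geometry.cell_size_deg!r}\n"
              f"NODATA_value {nodata!r}\n")
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in out[::-1])
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array row0=south, GridGeometry)."""
    lines = Path(path).read_text().splitlines()
    header = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    n_x, n_y = int(header["ncols"]), int(header["nrows"])
    data = np.loadtxt(lines[i:], dtype=float).reshape(n_y, n_x)
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    geometry = GridGeometry(origin_lon=header["xllcorner"],
                            origin_lat=header["yllcorner"],
                            cell_size_deg=header["cellsize"],
                            n_x=n_x, n_y=n_y)
    return data[::-1].copy(), geometry
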