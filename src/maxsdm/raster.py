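"""Lightweight georeferenced raster grids and predictor stacks.

A :class:`RasterGrid` is a north-up 2D cell lattice with an affine
geotransform ``(x0, dx, y0, dy)``: cell ``(row, col)`` spans the half-open
rectangle ``[x0 + col*dx, x0 + (col+1)*dx) x (y0 - (row+1)*dy, y0 - row*dy]``.
A point exactly on a shared edge belongs to the cell on its right / below,
matching raster indexing. Nodata cells are encoded with a sentinel value
(default -9999) and exposed as a boolean mask.

I/O uses the plain-text ESRI ASCII grid format (``.asc``) with an optional
JSON sidecar (``<name>.asc.json``) carrying the CRS label and layer kind,
so every artifact the pipeline writes is human-readable text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

NODATA = -9999.0


class GeometryError(ValueError):
    """Raster geometries that should match do not."""


class CRSError(ValueError):
    """Coordinate reference systems that should match do not."""


@dataclass
class RasterGrid:
    """A single-band georeferenced raster.

    Parameters
    ----------
    data : 2D float array; nodata cells hold ``nodata``.
    x0, y0 : coordinates of the outer corner of cell (0, 0) (top-left).
    dx, dy : cell width and height in CRS units (both positive; north-up).
    crs : free-form CRS label, e.g. ``"EPSG:32632"``. Compared as a string.
    nodata : sentinel for missing cells.
    """

    data: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    dx: float = 1000.0
    dy: float = 1000.0
    crs: str = "EPSG:32632"
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is nodata."""
        return ~np.isfinite(self.data) | (self.data == self.nodata)

    @property
    def values(self) -> np.ndarray:
        """Data with nodata cells as NaN."""
        out = self.data.copy()
        out[self.mask] = np.nan
        return out

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open rule)."""
        col = np.floor((np.asarray(x, float) - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - np.asarray(y, float)) / self.dy).astype(int)
        return row, col

    def centroid(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(col, float) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row, float) + 0.5) * self.dy
        return x, y

    def contains(self, row, col) -> np.ndarray:
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of x/y coordinates of every cell center."""
        nr, nc = self.shape
        xs = self.x0 + (np.arange(nc) + 0.5) * self.dx
        ys = self.y0 - (np.arange(nr) + 0.5) * self.dy
        return np.meshgrid(xs, ys)

    @property
    def cell_area_km2(self) -> float:
        """Cell area assuming CRS units are meters."""
        return self.dx * self.dy / 1e6

    def copy_with(self, data: np.ndarray) -> "RasterGrid":
        return RasterGrid(
            data=np.asarray(data, float),
            x0=self.x0, y0=self.y0, dx=self.dx, dy=self.dy,
            crs=self.crs, nodata=self.nodata,
        )

    def blank(self, fill: float | None = None) -> "RasterGrid":
        fill = self.nodata if fill is None else fill
        return self.copy_with(np.full(self.shape, fill))

    # -- I/O ------------------------------------------------------------
    def write_ascii(self, path: str | Path, kind: str | None = None) -> Path:
        """Write as ESRI ASCII grid plus a JSON sidecar with the CRS label."""
        if abs(self.dx - self.dy) > 1e-9:
            raise GeometryError("ASCII grid requires square cells")
        path = Path(path)
        nr, nc = self.shape
        yll = self.y0 - nr * self.dy
        header = (
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {self.x0!r}\nyllcorner {yll!r}\n"
            f"cellsize {self.dx!r}\nNODATA_value {self.nodata!r}\n"
        )
        body = "\n".join(
            " ".join(f"{v:.6g}" for v in row) for row in
            np.where(self.mask, self.nodata, self.data)
        )
        path.write_text(header + body + "\n")
        sidecar = {"crs": self.crs}
        if kind is not None:
            sidecar["kind"] = kind
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
        return path

    @classmethod
    def read_ascii(cls, path: str | Path) -> "RasterGrid":
        path = Path(path)
        lines = path.read_text().splitlines()
        hdr: dict[str, float] = {}
        i = 0
        while i < len(lines) and lines[i].split()[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            key, val = lines[i].split()[:2]
            hdr[key.lower()] = float(val)
            i += 1
        data = np.loadtxt(lines[i:], dtype=float)
        data = np.atleast_2d(data)
        nr, nc = int(hdr["nrows"]), int(hdr["ncols"])
        if data.shape != (nr, nc):
            data = data.reshape(nr, nc)
        cell = hdr["cellsize"]
        crs = "EPSG:32632"
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            crs = json.loads(sidecar.read_text()).get("crs", crs)
        return cls(
            data=data,
            x0=hdr["xllcorner"],
            y0=hdr["yllcorner"] + nr * cell,
            dx=cell, dy=cell, crs=crs,
            nodata=hdr.get("nodata_value", NODATA),
        )


CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class EnvStack:
    """Named, grid-aligned predictor layers with per-layer metadata.

    All layers share geometry; the stack-level nodata mask is the union of
    the per-layer masks. Categorical layers hold integer class codes.
    """

    layers: dict[str, RasterGrid]
    meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        names = list(self.layers)
        ref = self.layers[names[0]]
        for name in names[1:]:
            g = self.layers[name]
            if not ref.same_geometry(g):
                raise GeometryError(f"layer {name!r} geometry differs")
            if g.crs != ref.crs:
                raise CRSError(f"layer {name!r} CRS differs")
        for name in names:
            self.meta.setdefault(name, {})
            self.meta[name].setdefault("kind", CONTINUOUS)

    # -- introspection ---------------------------------------------------
    @property
    def grid(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def kind(self, name: str) -> str:
        return self.meta[name]["kind"]

    @property
    def continuous(self) -> list[str]:
        return [n for n in self.layers if self.kind(n) == CONTINUOUS]

    @property
    def categorical(self) -> list[str]:
        return [n for n in self.layers if self.kind(n) == CATEGORICAL]

    @property
    def mask(self) -> np.ndarray:
        """Union of per-layer nodata masks."""
        m = np.zeros(self.grid.shape, bool)
        for g in self.layers.values():
            m |= g.mask
        return m

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    # -- extraction ------------------------------------------------------
    def extract(self, x, y, names: Iterable[str] | None = None):
        """Layer values at point coordinates as a pandas DataFrame.

        Points outside the grid or on nodata cells yield NaN.
        """
        import pandas as pd

        names = list(names) if names is not None else self.names
        row, col = self.grid.cell_of(x, y)
        inside = self.grid.contains(row, col)
        r = np.where(inside, row, 0)
        c = np.where(inside, col, 0)
        out = {}
        for name in names:
            vals = self.layers[name].values[r, c]
            vals = np.where(inside, vals, np.nan)
            out[name] = vals
        return pd.DataFrame(out)

    def table(self, names: Iterable[str] | None = None):
        """All valid cells as a DataFrame plus their (row, col) indices."""
        import pandas as pd

        names = list(names) if names is not None else self.names
        valid = ~self.mask
        rows, cols = np.nonzero(valid)
        data = {n: self.layers[n].values[rows, cols] for n in names}
        return pd.DataFrame(data), rows, cols

    def subset(self, names: Iterable[str]) -> "EnvStack":
        names = list(names)
        return EnvStack(
            layers={n: self.layers[n] for n in names},
            meta={n: dict(self.meta[n]) for n in names},
        )

    # -- I/O ---------------------------------------------------------------
    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = []
        for name, g in self.layers.items():
            fn = f"{name}.asc"
            g.write_ascii(directory / fn, kind=self.kind(name))
            manifest.append({"name": name, "path": fn,
                             "kind": self.kind(name)})
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return directory

    @classmethod
    def read(cls, directory: str | Path) -> "EnvStack":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        layers, meta = {}, {}
        for entry in manifest:
            layers[entry["name"]] = RasterGrid.read_ascii(
                directory / entry["path"])
            meta[entry["name"]] = {"kind": entry.get("kind", CONTINUOUS)}
        return cls(layers=layers, meta=meta)

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray],
                    grid: RasterGrid,
                    kinds: Mapping[str, str] | None = None) -> "EnvStack":
        kinds = kinds or {}
        layers = {n: grid.copy_with(a) for n, a in arrays.items()}
        meta = {n: {"kind": kinds.get(n, CONTINUOUS)} for n in arrays}
        return cls(layers=layers, meta=meta)
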