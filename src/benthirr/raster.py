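"""Minimal raster grids for environmental predictor layers.

A :class:`Raster` is a 2-D array with a cell-center geotransform
(row 0 is the northernmost row) and a missing-value mask.  Layers are
serialised as ESRI ASCII grids (plain-text ``.asc``), which every GIS
reads.  A :class:`PredictorStack` holds named, co-registered layers and
extracts per-station values by the nearest-cell rule (no interpolation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

_DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """2-D grid with cell-center registration.

    ``x0, y0`` are the coordinates of the *center* of the upper-left cell,
    ``dx > 0`` the cell width (x increases with column index) and ``dy > 0``
    the cell height (y *decreases* with row index: row 0 is northernmost).
    ``data`` is a masked array; masked cells are missing.
    """

    data: np.ma.MaskedArray
    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        arr = np.ma.masked_invalid(np.ma.asarray(self.data, dtype=float))
        if arr.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError("cell sizes must be positive")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def transform(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.dx, self.dy)

    def same_grid(self, other: "Raster") -> bool:
        return self.shape == other.shape and np.allclose(
            self.transform, other.transform
        )

    def rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Nearest cell (row, col) for a point; raises if off-grid."""
        col = round((x - self.x0) / self.dx)
        row = round((self.y0 - y) / self.dy)
        nrow, ncol = self.shape
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise ValueError(f"point ({x}, {y}) falls outside the raster")
        return int(row), int(col)

    def sample(self, x: float, y: float) -> float:
        """Value at the nearest cell; NaN when that cell is masked."""
        r, c = self.rowcol(x, y)
        v = self.data[r, c]
        return float("nan") if np.ma.is_masked(v) else float(v)


def write_ascii_grid(
    raster: Raster, path: str | os.PathLike, nodata: float = _DEFAULT_NODATA
) -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    nrow, ncol = raster.shape
    # ESRI headers reference the lower-left *corner*; convert from cell centers
    xll = raster.x0 - raster.dx / 2.0
    yll = raster.y0 - (nrow - 1) * raster.dy - raster.dy / 2.0
    if not np.isclose(raster.dx, raster.dy):
        raise ValueError("ASCII grid requires square cells (dx == dy)")
    filled = raster.data.filled(nodata)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncol}\n")
        fh.write(f"nrows {nrow}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {raster.dx!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in filled:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | os.PathLike) -> Raster:
    """Read an ESRI ASCII grid."""
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    ncol, nrow = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrow, ncol):
        raise ValueError(
            f"grid body {data.shape} does not match header ({nrow}, {ncol})"
        )
    cell = header["cellsize"]
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    masked = np.ma.masked_values(data, nodata)
    x0 = header["xllcorner"] + cell / 2.0
    y0 = header["yllcorner"] + cell / 2.0 + (nrow - 1) * cell
    return Raster(data=masked, x0=x0, y0=y0, dx=cell, dy=cell)


class PredictorStack:
    """Named, co-registered raster layers plus station extraction."""

    def __init__(self, layers: Mapping[str, Raster]):
        if not layers:
            raise ValueError("a predictor stack needs at least one layer")
        self.layers: dict[str, Raster] = dict(layers)
        first = next(iter(self.layers.values()))
        for name, r in self.layers.items():
            if not r.same_grid(first):
                raise ValueError(f"layer {name!r} is not co-registered")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def subset(self, names: Iterable[str]) -> "PredictorStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"missing layer(s): {', '.join(missing)}")
        return PredictorStack({n: self.layers[n] for n in names})

    def extract(self, xs: Sequence[float], ys: Sequence[float]) -> np.ndarray:
        """stations × predictors matrix by nearest-cell lookup (NaN = masked)."""
        out = np.empty((len(xs), len(self.layers)), dtype=float)
        for j, r in enumerate(self.layers.values()):
            for i, (x, y) in enumerate(zip(xs, ys)):
                out[i, j] = r.sample(x, y)
        return out

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(cells × predictors array, combined valid mask flattened).

        A cell is valid only where *every* layer is unmasked.
        """
        stacked = np.stack([r.data.filled(np.nan).ravel() for r in self.layers.values()], axis=1)
        valid = ~np.isnan(stacked).any(axis=1)
        return stacked, valid

    def blank_like(self) -> Raster:
        first = next(iter(self.layers.values()))
        data = np.ma.masked_all(first.shape, dtype=float)
        return Raster(data=data, x0=first.x0, y0=first.y0, dx=first.dx, dy=first.dy)


def read_stack(paths: Mapping[str, str | os.PathLike]) -> PredictorStack:
    """Read named ASCII-grid files into a co-registered stack."""
    return PredictorStack({name: read_ascii_grid(p) for name, p in paths.items()})
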