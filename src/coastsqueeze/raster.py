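"""Minimal georeferenced raster grid with ESRI ASCII (.asc) I/O.

The analysis needs only two raster operations — bilinear sampling of an
elevation model and nearest-cell sampling of a population-density grid —
so the container is a plain numpy grid with a square-cell georeference
(lower-left corner, cell size, nodata marker).  The serialization format
is the plain-text ESRI ASCII grid, which round-trips exactly and needs no
GIS stack.  Row 0 of ``data`` is the northernmost row, as in the format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class Raster:
    data: np.ndarray  # (ny, nx); row 0 = north
    xll: float  # x of the lower-left grid corner
    yll: float  # y of the lower-left grid corner
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def ny(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def ytop(self) -> float:
        return self.yll + self.ny * self.cellsize

    def _grid_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (col, row) of ``points``; integer values = cell centers."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        col = (pts[:, 0] - self.xll) / self.cellsize - 0.5
        row = (self.ytop - pts[:, 1]) / self.cellsize - 0.5
        return col, row

    def sample_nearest(self, points: np.ndarray) -> np.ndarray:
        """Value of the nearest cell per point; NaN outside the grid or nodata."""
        col, row = self._grid_coords(points)
        c = np.rint(col).astype(int)
        r = np.rint(row).astype(int)
        out = np.full(len(c), np.nan)
        ok = (c >= 0) & (c < self.nx) & (r >= 0) & (r < self.ny)
        vals = self.data[r[ok], c[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out

    def sample_bilinear(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation between cell centers; NaN if any corner is
        outside the grid or nodata."""
        col, row = self._grid_coords(points)
        c0 = np.floor(col).astype(int)
        r0 = np.floor(row).astype(int)
        fc = col - c0
        fr = row - r0
        out = np.full(len(col), np.nan)
        ok = (c0 >= 0) & (c0 + 1 < self.nx) & (r0 >= 0) & (r0 + 1 < self.ny)
        if not np.any(ok):
            return out
        c0k, r0k, fck, frk = c0[ok], r0[ok], fc[ok], fr[ok]
        q = np.stack(
            [
                self.data[r0k, c0k],
                self.data[r0k, c0k + 1],
                self.data[r0k + 1, c0k],
                self.data[r0k + 1, c0k + 1],
            ]
        )
        valid = ~np.any(q == self.nodata, axis=0)
        val = (
            q[0] * (1 - fck) * (1 - frk)
            + q[1] * fck * (1 - frk)
            + q[2] * (1 - fck) * frk
            + q[3] * fck * frk
        )
        out[np.nonzero(ok)[0][valid]] = val[valid]
        return out

    def write_ascii(self, path: str | Path) -> None:
        path = Path(path)
        header = (
            f"ncols {self.nx}\n"
            f"nrows {self.ny}\n"
            f"xllcorner {self.xll!r}\n"
            f"yllcorner {self.yll!r}\n"
            f"cellsize {self.cellsize!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with path.open("w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            for _ in range(6):
                key, value = fh.readline().split()
                meta[key.lower()] = float(value)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        if "xllcenter" in meta:  # center-referenced variant of the format
            meta["xllcorner"] = meta["xllcenter"] - meta["cellsize"] / 2
            meta["yllcorner"] = meta["yllcenter"] - meta["cellsize"] / 2
        return cls(
            data=data,
            xll=meta["xllcorner"],
            yll=meta["yllcorner"],
            cellsize=meta["cellsize"],
            nodata=meta.get("nodata_value", -9999.0),
        )
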