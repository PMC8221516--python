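"""Hexagonal landscape: raster I/O, hex tiling, and patch aggregation.

Habitat quality and crop proportion arrive as rasters (ESRI ASCII
grid), are resampled onto a flat-top hexagon tiling (0.86 ha hexagons
by default), and the hexagons are aggregated into a regular grid of
habitat patches of up to 91 hexagons (~79 ha).  Each patch carries the
mean habitat quality and crop proportion of its member hexagons and a
carrying capacity K = 0.062 birds/hexagon times its member count
(0.86 / 0.062 ~ 14 ha per territory).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "HexGrid",
    "build_hex_grid",
    "rasterize_to_hexagons",
    "PatchSet",
    "aggregate_patches",
]

HEX_AREA_HA_DEFAULT = 0.86
K_PER_HEX_DEFAULT = 0.062


@dataclass
class Raster:
    """Single-band raster; nodata cells are NaN in ``data``."""

    data: np.ndarray  # 2-D float array, row 0 = northernmost
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 30.0
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of every cell center (flattened, row-major)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xllcorner + (cols + 0.5) * self.cellsize
        # row 0 is the top of the grid
        y = self.yllcorner + (self.nrows - rows - 0.5) * self.cellsize
        xx, yy = np.meshgrid(x, y)
        return xx.ravel(), yy.ravel()


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field '{key}'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    for lineno, line in enumerate(lines[i:], start=i + 1):
        if not line.strip():
            continue
        try:
            row = np.array(line.split(), dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric raster data") from exc
        rows.append(row)
    if len(rows) != nrows:
        raise ValueError(f"{path}: header says nrows={nrows} but found {len(rows)} data rows")
    for lineno_off, row in enumerate(rows):
        if len(row) != ncols:
            raise ValueError(
                f"{path}: row {lineno_off + 1} has {len(row)} values, header says ncols={ncols}"
            )
    data = np.vstack(rows)
    data[data == nodata] = np.nan
    return Raster(
        data=data,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header["cellsize"],
        nodata=nodata,
    )


def write_ascii_grid(path, raster: Raster) -> None:
    """Write an ESRI ASCII grid; NaN cells become the nodata value."""
    data = np.where(np.isnan(raster.data), raster.nodata, raster.data)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner!r}\n")
        fh.write(f"yllcorner {raster.yllcorner!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"nodata_value {raster.nodata!r}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


@dataclass(frozen=True)
class HexGrid:
    """Flat-top hexagon tiling of a rectangular extent.

    Hexagons are indexed by (col, row) offset coordinates (odd columns
    shifted down half a pitch) and linearly as ``id = row * ncols + col``.
    ``pitch`` (the center-to-center distance of adjacent hexagons) is
    derived from the hexagon area: A = (sqrt(3)/2) * pitch**2.
    """

    ncols: int
    nrows: int
    hex_area_ha: float = HEX_AREA_HA_DEFAULT
    origin_x: float = 0.0
    origin_y: float = 0.0

    @property
    def n_hex(self) -> int:
        return self.ncols * self.nrows

    @property
    def circumradius(self) -> float:
        """Hexagon circumradius in meters."""
        area_m2 = self.hex_area_ha * 1e4
        return float(np.sqrt(2.0 * area_m2 / (3.0 * np.sqrt(3.0))))

    @property
    def pitch(self) -> float:
        """Center-to-center distance between adjacent hexagons, meters."""
        return float(np.sqrt(2.0 * self.hex_area_ha * 1e4 / np.sqrt(3.0)))

    @property
    def dx(self) -> float:
        """Horizontal spacing between hexagon columns, meters (1.5 R)."""
        return 1.5 * self.circumradius

    @property
    def dy(self) -> float:
        """Vertical spacing between hexagon rows, meters (= pitch)."""
        return self.pitch

    def centroids(self) -> tuple[np.ndarray, np.ndarray]:
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        cc, rr = np.meshgrid(cols, rows)
        return self._centroid_xy(cc.ravel(), rr.ravel())

    def _centroid_xy(self, col, row):
        col = np.asarray(col)
        row = np.asarray(row)
        x = self.origin_x + col * self.dx
        y = self.origin_y + row * self.dy + (col % 2) * 0.5 * self.dy
        return x, y

    def point_to_hex(self, x, y) -> np.ndarray:
        """Hexagon id containing each point (nearest-centroid rule); -1 off grid.

        The hexagon containing a point is the Voronoi cell of its
        centroid, so a nearest-centroid search over the 3x3 candidate
        neighbourhood of the rounded offset coordinates is exact.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        c0 = np.rint((x - self.origin_x) / self.dx).astype(int)
        r0 = np.rint((y - self.origin_y) / self.dy).astype(int)
        best_d = np.full(x.shape, np.inf)
        best_c = np.full(x.shape, -1, dtype=int)
        best_r = np.full(x.shape, -1, dtype=int)
        for dc in (-1, 0, 1):
            for dr in (-1, 0, 1):
                c = c0 + dc
                r = r0 + dr
                cx, cy = self._centroid_xy(c, r)
                d = (x - cx) ** 2 + (y - cy) ** 2
                better = d < best_d
                best_d = np.where(better, d, best_d)
                best_c = np.where(better, c, best_c)
                best_r = np.where(better, r, best_r)
        inside = (
            (best_c >= 0) & (best_c < self.ncols) & (best_r >= 0) & (best_r < self.nrows)
        )
        return np.where(inside, best_r * self.ncols + best_c, -1)


def build_hex_grid(
    extent_m: tuple[float, float],
    hex_area_ha: float = HEX_AREA_HA_DEFAULT,
    origin: tuple[float, float] = (0.0, 0.0),
) -> HexGrid:
    """Hex tiling covering a (width, height) extent in meters."""
    width, height = extent_m
    if width <= 0 or height <= 0 or hex_area_ha <= 0:
        raise ValueError("extent and hexagon area must be positive")
    probe = HexGrid(1, 1, hex_area_ha)
    ncols = int(np.ceil(width / probe.dx))
    nrows = int(np.ceil(height / probe.dy))
    return HexGrid(
        ncols=ncols,
        nrows=nrows,
        hex_area_ha=hex_area_ha,
        origin_x=origin[0] + 0.5 * probe.dx,
        origin_y=origin[1] + 0.5 * probe.dy,
    )


def rasterize_to_hexagons(raster: Raster, grid: HexGrid) -> np.ndarray:
    """Per-hexagon mean of the raster cells whose centers fall inside it.

    Hexagons covering no (finite) raster cell come back NaN (missing)
    and are excluded from patch aggregation.
    """
    x, y = raster.cell_centers()
    vals = raster.data.ravel()
    hex_id = grid.point_to_hex(x, y)
    ok = (hex_id >= 0) & np.isfinite(vals)
    if not np.any(ok):
        raise ValueError("raster does not overlap the hexagon grid")
    sums = np.bincount(hex_id[ok], weights=vals[ok], minlength=grid.n_hex)
    counts = np.bincount(hex_id[ok], minlength=grid.n_hex)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


@dataclass
class PatchSet:
    """Aggregated habitat patches with stage-abundance state.

    Array fields are aligned per patch; ``hex_patch`` maps every hexagon
    id to its patch index (-1 for hexagons outside any patch, i.e.
    missing data).
    """

    grid: HexGrid
    q: np.ndarray
    p: np.ndarray
    K: np.ndarray
    n_hex: np.ndarray
    centroid_x: np.ndarray
    centroid_y: np.ndarray
    hex_patch: np.ndarray
    n_j: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_a: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.q)
        if self.n_j is None:
            self.n_j = np.zeros(n)
        if self.n_a is None:
            self.n_a = np.zeros(n)

    @property
    def n_patches(self) -> int:
        return len(self.q)

    def total_abundance(self) -> float:
        return float(self.n_j.sum() + self.n_a.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patch_id": np.arange(self.n_patches),
                "centroid_x": self.centroid_x,
                "centroid_y": self.centroid_y,
                "n_hex": self.n_hex,
                "q": self.q,
                "p": self.p,
                "K": self.K,
                "n_j": self.n_j,
                "n_a": self.n_a,
            }
        )


def aggregate_patches(
    grid: HexGrid,
    hex_q: np.ndarray,
    hex_p: np.ndarray | None = None,
    block_cols: int = 13,
    block_rows: int = 7,
    k_per_hex: float = K_PER_HEX_DEFAULT,
) -> PatchSet:
    """Aggregate hexagons into a regular grid of patches.

    The default 13 x 7 block contains exactly 91 hexagons (~79 ha at
    0.86 ha/hexagon).  Patch habitat quality and crop proportion are
    means over member hexagons; K = k_per_hex x member count.  Hexagons
    with missing quality are excluded; blocks clipped by the extent or
    by missing data simply have fewer members (smaller K).
    """
    hex_q = np.asarray(hex_q, dtype=float)
    if hex_p is None:
        hex_p = np.zeros_like(hex_q)
    hex_p = np.asarray(hex_p, dtype=float)
    cols = np.arange(grid.n_hex) % grid.ncols
    rows = np.arange(grid.n_hex) // grid.ncols
    npc = int(np.ceil(grid.ncols / block_cols))
    block_id = (rows // block_rows) * npc + (cols // block_cols)

    valid = np.isfinite(hex_q)
    n_blocks = int(block_id.max()) + 1
    counts = np.bincount(block_id[valid], minlength=n_blocks)
    occupied = np.flatnonzero(counts > 0)
    remap = np.full(n_blocks, -1, dtype=int)
    remap[occupied] = np.arange(len(occupied))

    hx, hy = grid.centroids()

    def block_mean(values: np.ndarray) -> np.ndarray:
        s = np.bincount(block_id[valid], weights=values[valid], minlength=n_blocks)
        return s[occupied] / counts[occupied]

    crop = np.where(np.isfinite(hex_p), hex_p, 0.0)
    hex_patch = np.where(valid, remap[block_id], -1)
    return PatchSet(
        grid=grid,
        q=block_mean(hex_q),
        p=block_mean(crop),
        K=k_per_hex * counts[occupied].astype(float),
        n_hex=counts[occupied],
        centroid_x=block_mean(hx),
        centroid_y=block_mean(hy),
        hex_patch=hex_patch,
    )
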