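"""Synthetic landscape generator.

Produces spatially autocorrelated habitat-quality rasters, clumped
crop-proportion rasters and range masks with controllable summary
statistics, so the full pipeline runs without any external GIS data.
The habitat field is white noise smoothed with a Gaussian kernel of the
requested correlation length, then rank-transformed so the fraction of
cells with q > 0.5 ("suitable") matches a target.  Crop fields are
square blocks placed preferentially on low-quality cells, emulating
cultivation adjacent to, not on top of, scrub habitat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .landscape import Raster

__all__ = ["SyntheticLandscapeSpec", "generate_habitat_map", "generate_crop_map"]


@dataclass(frozen=True)
class SyntheticLandscapeSpec:
    """Controls for the synthetic habitat/crop raster pair."""

    extent_km: float = 30.0
    resolution_m: float = 30.0
    habitat_corr_length_m: float = 500.0
    suitable_fraction: float = 0.13
    crop_fraction: float = 0.10
    crop_field_size_m: float = 300.0
    crop_low_q_bias: float = 2.0

    def __post_init__(self) -> None:
        if self.extent_km <= 0 or self.resolution_m <= 0:
            raise ValueError("extent and resolution must be positive")
        for name in ("suitable_fraction", "crop_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_cells(self) -> int:
        return int(round(self.extent_km * 1000.0 / self.resolution_m))


def generate_habitat_map(spec: SyntheticLandscapeSpec, rng: np.random.Generator) -> Raster:
    """Autocorrelated habitat-quality raster on [0, 1].

    A smoothed Gaussian random field is mapped through its empirical
    CDF, then piecewise-linearly rescaled so that exactly the target
    fraction of cells exceeds q = 0.5; zero correlation length degrades
    to i.i.d. cell values.
    """
    n = spec.n_cells
    field = rng.standard_normal((n, n))
    sigma = spec.habitat_corr_length_m / spec.resolution_m
    if sigma > 0:
        field = gaussian_filter(field, sigma=sigma, mode="reflect")
    # rank transform -> uniform in (0, 1), preserving spatial pattern
    flat = field.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    u = (ranks + 0.5) / flat.size
    t = spec.suitable_fraction
    # map the top `t` quantile onto (0.5, 1], the rest onto [0, 0.5]
    q = np.where(
        u <= 1.0 - t,
        0.5 * u / max(1.0 - t, 1e-12),
        0.5 + 0.5 * (u - (1.0 - t)) / max(t, 1e-12),
    )
    return Raster(data=q.reshape(n, n), cellsize=spec.resolution_m)


def generate_crop_map(
    spec: SyntheticLandscapeSpec,
    habitat: Raster,
    rng: np.random.Generator,
) -> Raster:
    """Clumped binary crop raster (1 = cultivated) with the target cover.

    Square fields are seeded at cells drawn with probability
    proportional to (1 - q)**bias and grown until total cover reaches
    the target; the final field is trimmed cell-by-cell so measured
    cover matches the requested fraction exactly.
    """
    n = habitat.nrows
    crop = np.zeros((n, n), dtype=float)
    target_cells = int(round(spec.crop_fraction * n * n))
    if target_cells == 0:
        return Raster(data=crop, cellsize=habitat.cellsize)
    side = max(1, int(round(spec.crop_field_size_m / habitat.cellsize)))
    weights = (1.0 - habitat.data.ravel()) ** spec.crop_low_q_bias
    weights = weights / weights.sum()
    placed = 0
    guard = 0
    while placed < target_cells and guard < 100 * target_cells:
        guard += 1
        seed = int(rng.choice(n * n, p=weights))
        i, j = seed // n, seed % n
        i1, j1 = min(i + side, n), min(j + side, n)
        block = crop[i:i1, j:j1]
        newly = int((block == 0).sum())
        if newly == 0:
            continue
        if placed + newly > target_cells:
            # trim the final field: fill only as many free cells as needed
            free = np.argwhere(block == 0)
            take = target_cells - placed
            pick = free[rng.permutation(len(free))[:take]]
            block[pick[:, 0], pick[:, 1]] = 1.0
            placed = target_cells
        else:
            block[:, :] = 1.0
            placed += newly
    return Raster(data=crop, cellsize=habitat.cellsize)
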