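"""Fixation-density maps and vertical-profile densities.

A density map is the sum of unit-mass isotropic Gaussian kernels (default
SD 0.26 deg) centred at fixation locations, evaluated analytically at pixel
centres on a degree grid; fixations are *not* weighted by duration.  The
vertical profile is the exact row-wise (horizontal) sum of the 2D map, a
function of vertical face position.  Densities are dimensionless and only
interpretable relative to one another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import ConfigError, Dataset, select_trials

__all__ = [
    "GridSpec",
    "DensityGrid",
    "fixation_density_2d",
    "vertical_profile",
    "profile_basis",
    "condition_fixations",
    "participant_condition_map",
    "group_average",
]

_TRUNC_SD = 5.0  # kernels are evaluated out to this many SDs


@dataclass(frozen=True)
class GridSpec:
    """Analysis grid in canonical degrees.

    Default extent covers a 10-degree-forehead face with margins of at
    least 3 kernel SDs on every side; ``resolution`` is degrees per pixel.
    Pixel centres sit at ``min + (i + 0.5) * resolution``.
    """

    x_min: float = -8.0
    x_max: float = 8.0
    y_min: float = -8.0
    y_max: float = 10.0
    resolution: float = 0.05
    sigma: float = 0.26

    def __post_init__(self):
        if self.resolution <= 0:
            raise ConfigError("grid resolution must be positive")
        if self.sigma <= 0:
            raise ConfigError("kernel sigma must be positive")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ConfigError("grid extent is empty")

    @property
    def nx(self) -> int:
        return int(round((self.x_max - self.x_min) / self.resolution))

    @property
    def ny(self) -> int:
        return int(round((self.y_max - self.y_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.nx) + 0.5) * self.resolution

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.ny) + 0.5) * self.resolution

    @property
    def pixel_area(self) -> float:
        return self.resolution**2

    def covers(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)


@dataclass
class DensityGrid:
    """A 2D fixation-density map on a :class:`GridSpec`.

    ``values`` has shape (ny, nx); row index increases with y (downward on
    the face).  For fixations at least 3 SD inside the extent, ``values.sum()
    * grid.pixel_area`` approximates the fixation count (each kernel has
    unit mass).  ``clip_fraction`` is the average kernel mass lost off-grid.
    """

    values: np.ndarray
    grid: GridSpec
    n_fixations: int
    label: str = ""
    clip_fraction: float = 0.0

    @property
    def mass(self) -> float:
        return float(self.values.sum() * self.grid.pixel_area)


def _kernel_1d(centers: np.ndarray, pos: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((centers - pos) / sigma) ** 2) / (np.sqrt(2.0 * np.pi) * sigma)


def fixation_density_2d(
    x: Sequence[float], y: Sequence[float], grid: GridSpec, label: str = ""
) -> DensityGrid:
    """Sum of unit-mass Gaussians at (x, y), truncated at 5 SD.

    Fixations outside the extent still contribute whatever kernel mass falls
    on the grid; the clipped fraction is reported, never raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    values = np.zeros(grid.shape)
    if len(x) == 0:
        return DensityGrid(values, grid, 0, label, 0.0)
    sigma = grid.sigma
    res = grid.resolution
    radius = _TRUNC_SD * sigma
    xc, yc = grid.x_centers, grid.y_centers
    for xi, yi in zip(x, y):
        i0 = max(0, int(np.floor((yi - radius - grid.y_min) / res)))
        i1 = min(grid.ny, int(np.ceil((yi + radius - grid.y_min) / res)) + 1)
        j0 = max(0, int(np.floor((xi - radius - grid.x_min) / res)))
        j1 = min(grid.nx, int(np.ceil((xi + radius - grid.x_min) / res)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        gy = _kernel_1d(yc[i0:i1], yi, sigma)
        gx = _kernel_1d(xc[j0:j1], xi, sigma)
        values[i0:i1, j0:j1] += np.outer(gy, gx)
    inside_x = norm.cdf((grid.x_max - x) / sigma) - norm.cdf((grid.x_min - x) / sigma)
    inside_y = norm.cdf((grid.y_max - y) / sigma) - norm.cdf((grid.y_min - y) / sigma)
    clip = 1.0 - float(np.mean(inside_x * inside_y))
    return DensityGrid(values, grid, len(x), label, clip)


def vertical_profile(grid: DensityGrid | np.ndarray) -> np.ndarray:
    """Exact column-wise (over x) sum of a density map: one value per y row.

    The profile total equals the grid total exactly (same summation)."""
    values = grid.values if isinstance(grid, DensityGrid) else np.asarray(grid)
    return values.sum(axis=1)


def profile_basis(x: Sequence[float], y: Sequence[float], grid: GridSpec) -> np.ndarray:
    """Per-fixation vertical-profile contributions, shape (n_fixations, ny).

    Row i equals ``vertical_profile(fixation_density_2d([x_i], [y_i], grid))``
    exactly (the 2D kernel is separable, so its row sum is the y kernel
    scaled by the truncated x mass); summing rows therefore reproduces the
    profile of the joint 2D map without materializing it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sigma, res = grid.sigma, grid.resolution
    radius = _TRUNC_SD * sigma
    xc, yc = grid.x_centers, grid.y_centers
    out = np.zeros((len(x), grid.ny))
    for k, (xi, yi) in enumerate(zip(x, y)):
        i0 = max(0, int(np.floor((yi - radius - grid.y_min) / res)))
        i1 = min(grid.ny, int(np.ceil((yi + radius - grid.y_min) / res)) + 1)
        j0 = max(0, int(np.floor((xi - radius - grid.x_min) / res)))
        j1 = min(grid.nx, int(np.ceil((xi + radius - grid.x_min) / res)) + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        gx_sum = _kernel_1d(xc[j0:j1], xi, sigma).sum()
        out[k, i0:i1] = _kernel_1d(yc[i0:i1], yi, sigma) * gx_sum
    return out


def condition_fixations(
    dataset: Dataset, selector: Mapping[str, object], ordinal: int
) -> pd.DataFrame:
    """Fixations of the given ordinal from trials matched by ``selector``,
    annotated with participant_id from the trial table."""
    trials = select_trials(dataset.trials, selector)
    fx = dataset.fixations
    sub = fx[(fx["trial_id"].isin(trials["trial_id"])) & (fx["ordinal"] == ordinal)]
    return sub


def participant_condition_map(
    dataset: Dataset,
    selector: Mapping[str, object],
    ordinal: int,
    grid: GridSpec,
) -> dict[str, DensityGrid]:
    """One density map per participant from that participant's fixations of
    the given ordinal in the selected condition.  Participants present in
    the design but with no matching fixations get a zero map (flagged by
    ``n_fixations == 0``)."""
    sub = condition_fixations(dataset, selector, ordinal)
    out: dict[str, DensityGrid] = {}
    for pid in sorted(dataset.trials["participant_id"].unique()):
        pfx = sub[sub["participant_id"] == pid]
        out[pid] = fixation_density_2d(
            pfx["x"].to_numpy(), pfx["y"].to_numpy(), grid, label=str(pid)
        )
    return out


def group_average(
    maps: Mapping[str, DensityGrid] | Sequence[DensityGrid],
    scale: float | Mapping[str, float] = 1.0,
    label: str = "",
) -> DensityGrid:
    """Mean over participants of (scale x participant map).

    ``scale`` compensates unequal trial counts between conditions (e.g. 1/2
    when a pooled test condition holds twice as many trials as study).
    """
    items = list(maps.items()) if isinstance(maps, Mapping) else [(m.label, m) for m in maps]
    if not items:
        raise ConfigError("group_average needs at least one map")
    grid = items[0][1].grid
    total = np.zeros(grid.shape)
    n_fix = 0
    for key, m in items:
        if m.grid != grid:
            raise ConfigError("all maps must share one grid spec")
        s = scale[key] if isinstance(scale, Mapping) else scale
        total += s * m.values
        n_fix += m.n_fixations
    return DensityGrid(total / len(items), grid, n_fix, label)
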