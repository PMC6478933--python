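"""Directional accessible-channel filtering of occupancy maps.

Electrolyte pockets — solvent cavities connected to the pore lumen only
through reentrant paths — do not carry trans-membrane current and must be
removed before the occupancy map is turned into a cross-section profile. A
cell belongs to the trans→cis accessible channel when it can be reached from
an open cell of the trans entrance slice by a face-adjacent path whose z index
never decreases (lateral steps at constant z are free); the cis→trans channel
is defined with non-increasing z from the cis entrance. The through-channel
mask is the intersection of the two, which removes reentrant pockets facing
either membrane side while keeping lateral lobes.

Connectivity is 6-neighbour by default (4-neighbour lateral moves plus the
axial step); 26-neighbour is available. A cell is "open" when its normalized
occupancy exceeds the threshold ``theta`` (default 0: any electrolyte
occupancy at all).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .occupancy import GridSpec, OccupancyMap, Stage


class Direction(enum.Enum):
    TRANS_TO_CIS = "TRANS_TO_CIS"   # sweep from z_min upward, z non-decreasing
    CIS_TO_TRANS = "CIS_TO_TRANS"   # sweep from z_max downward, z non-increasing
    INTERSECTION = "INTERSECTION"


@dataclass
class AccessibilityMask:
    grid: GridSpec
    mask: np.ndarray
    direction: Direction

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.dims):
            raise ValidationError("mask shape does not match grid dims")


@dataclass
class ChannelMap:
    """Normalized occupancy restricted to the through-channel (0 elsewhere)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.dims):
            raise ValidationError("values shape does not match grid dims")


def _lateral_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(2, 1)   # 4-neighbour
    if connectivity == 26:
        return ndimage.generate_binary_structure(2, 2)   # 8-neighbour
    raise ValidationError("connectivity must be 6 or 26")


def _seed_slice_mask(
    grid: GridSpec,
    open_slice: np.ndarray,
    seed_center: tuple[float, float] | None,
    seed_radius: float | None,
) -> np.ndarray:
    seeds = open_slice.copy()
    if seed_radius is not None:
        if seed_center is None:
            seed_center = (
                grid.origin[0] + grid.dims[0] * grid.cell[0] / 2.0,
                grid.origin[1] + grid.dims[1] * grid.cell[1] / 2.0,
            )
        xs = grid.axis_centers(0)[:, None]
        ys = grid.axis_centers(1)[None, :]
        lateral = (xs - seed_center[0]) ** 2 + (ys - seed_center[1]) ** 2 <= seed_radius**2
        seeds &= lateral
    return seeds


def directional_accessibility(
    occupancy_map: OccupancyMap,
    direction: Direction,
    theta: float = 0.0,
    seed_center: tuple[float, float] | None = None,
    seed_radius: float | None = None,
    connectivity: int = 6,
) -> AccessibilityMask:
    """Monotone-z reachability sweep from the entrance slice.

    Implemented as a layer sweep: within each z slice, reachability spreads
    through connected components of open cells (scipy.ndimage labeling); the
    axial step carries reachability to the next slice. This is equivalent to
    BFS over the directed graph with lateral and one-signed axial edges.
    """
    if theta < 0:
        raise ValidationError("theta must be >= 0")
    if occupancy_map.stage is Stage.BINARY_FRAME:
        raise ValidationError("accessibility expects an averaged or normalized map")
    if direction is Direction.INTERSECTION:
        raise ValidationError("compute directional masks first, then intersect")

    open_cells = occupancy_map.values > theta
    flip = direction is Direction.CIS_TO_TRANS
    if flip:
        open_cells = open_cells[:, :, ::-1]

    grid = occupancy_map.grid
    structure = _lateral_structure(connectivity)
    nz = grid.dims[2]
    reach = np.zeros_like(open_cells)

    carry = _seed_slice_mask(grid, open_cells[:, :, 0], seed_center, seed_radius)
    if not carry.any():
        warnings.warn(
            f"no open seed cells in the {direction.value} entrance slice; mask is empty",
            stacklevel=2,
        )
        return AccessibilityMask(grid=grid, mask=np.zeros(grid.dims, dtype=bool), direction=direction)

    for k in range(nz):
        if k > 0:
            carry = reach[:, :, k - 1]
            if connectivity == 26:
                carry = ndimage.binary_dilation(carry, structure=structure)
            carry = carry & open_cells[:, :, k]
        if carry.any():
            labels, n = ndimage.label(open_cells[:, :, k], structure=structure)
            if n:
                hit = np.unique(labels[carry & (labels > 0)])
                reach[:, :, k] = np.isin(labels, hit) & (labels > 0)

    if flip:
        reach = reach[:, :, ::-1]
    return AccessibilityMask(grid=grid, mask=reach, direction=direction)


def intersect_masks(a: AccessibilityMask, b: AccessibilityMask) -> AccessibilityMask:
    if a.grid != b.grid:
        raise ValidationError("masks are defined on different grids")
    return AccessibilityMask(grid=a.grid, mask=a.mask & b.mask, direction=Direction.INTERSECTION)


def apply_mask(occupancy_map: OccupancyMap, mask: AccessibilityMask) -> ChannelMap:
    """M̃: the normalized map on masked cells, zero elsewhere."""
    if occupancy_map.grid != mask.grid:
        raise ValidationError("map and mask are defined on different grids")
    return ChannelMap(grid=occupancy_map.grid, values=np.where(mask.mask, occupancy_map.values, 0.0))


def through_channel(
    occupancy_map: OccupancyMap,
    theta: float = 0.0,
    seed_center: tuple[float, float] | None = None,
    seed_radius: float | None = None,
    connectivity: int = 6,
) -> ChannelMap:
    """Convenience: both directional sweeps, intersection, mask application."""
    down = directional_accessibility(
        occupancy_map, Direction.TRANS_TO_CIS, theta, seed_center, seed_radius, connectivity
    )
    up = directional_accessibility(
        occupancy_map, Direction.CIS_TO_TRANS, theta, seed_center, seed_radius, connectivity
    )
    return apply_mask(occupancy_map, intersect_masks(down, up))


def flood_fill_accessibility(
    occupancy_map: OccupancyMap,
    theta: float = 0.0,
    seed_center: tuple[float, float] | None = None,
    seed_radius: float | None = None,
    connectivity: int = 6,
) -> AccessibilityMask:
    """Plain (non-monotone) 3D connectivity from both entrance slices.

    This is the naive cavity filter the directional sweep improves on: it
    keeps every pocket connected to the channel, however reentrant. Exposed
    for comparison studies and as a cross-check for geometries without
    reentrant features, where it must agree with the intersection mask.
    """
    open_cells = occupancy_map.values > theta
    grid = occupancy_map.grid
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n = ndimage.label(open_cells, structure=structure)
    seeds_lo = _seed_slice_mask(grid, open_cells[:, :, 0], seed_center, seed_radius)
    seeds_hi = _seed_slice_mask(grid, open_cells[:, :, -1], seed_center, seed_radius)
    wanted = np.union1d(
        np.unique(labels[:, :, 0][seeds_lo & (labels[:, :, 0] > 0)]),
        np.unique(labels[:, :, -1][seeds_hi & (labels[:, :, -1] > 0)]),
    )
    mask = np.isin(labels, wanted) & (labels > 0)
    return AccessibilityMask(grid=grid, mask=mask, direction=Direction.INTERSECTION)
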