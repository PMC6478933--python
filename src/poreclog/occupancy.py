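"""Electrolyte occupancy maps on a regular 3D grid.

The analysis rasterizes the VdW spheres of electrolyte atoms onto cubic cells
(default 1 Å), frame by frame: a cell is occupied (1) when its center lies
within the VdW radius of at least one selected atom, otherwise 0. Binary
per-frame maps are averaged over the trajectory and normalized by the mean
occupancy of a user-chosen bulk region, yielding the map M whose value is ~1
in bulk-like electrolyte and 0 inside excluded volume.

The membership test is configurable: ``mode="center"`` (cell center inside the
sphere, the default) or ``mode="overlap"`` (sphere overlaps the cell box at
all).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .trajio import AtomMeta, Frame, Trajectory


class Stage(enum.Enum):
    BINARY_FRAME = "BINARY_FRAME"
    AVERAGED = "AVERAGED"
    NORMALIZED = "NORMALIZED"


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: ``origin`` is the lower corner (Å), ``cell`` the cell
    edge lengths (Å), ``dims`` the cell counts. Cell (i, j, k) spans the
    half-open box [origin + idx*cell, origin + (idx+1)*cell); its center is
    origin + (idx + 1/2)*cell."""

    origin: tuple[float, float, float]
    cell: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.origin) != 3 or len(self.cell) != 3 or len(self.dims) != 3:
            raise ValidationError("origin, cell and dims must each have 3 components")
        if not all(c > 0 for c in self.cell):
            raise ValidationError("cell sizes must be positive")
        if not all(int(d) >= 1 for d in self.dims):
            raise ValidationError("dims must be >= 1")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "cell", tuple(float(v) for v in self.cell))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))

    @classmethod
    def cubic(cls, origin, extent, cell_size: float = 1.0) -> "GridSpec":
        """Grid of cubic cells of edge ``cell_size`` covering ``extent`` Å."""
        dims = tuple(int(round(e / cell_size)) for e in extent)
        return cls(tuple(origin), (cell_size,) * 3, dims)

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.dims[axis]) + 0.5) * self.cell[axis]

    @property
    def z_centers(self) -> np.ndarray:
        return self.axis_centers(2)

    @property
    def z_edges(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.dims[2] + 1) * self.cell[2]

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.cell))

    @property
    def upper(self) -> tuple[float, float, float]:
        return tuple(o + d * c for o, c, d in zip(self.origin, self.cell, self.dims))


@dataclass
class OccupancyMap:
    grid: GridSpec
    values: np.ndarray
    stage: Stage

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.dims):
            raise ValidationError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if np.any(self.values < 0):
            raise ValidationError("occupancy values must be >= 0")


def _candidate_offsets(radius: float, cell: Sequence[float], mode: str) -> np.ndarray:
    """Integer cell offsets that can satisfy the membership test for an atom
    anywhere inside the central cell (conservative superset)."""
    cell = np.asarray(cell, dtype=float)
    # farthest relevant cell center: radius + half the cell diagonal (center
    # mode); overlap mode adds another half diagonal for the box extent.
    reach = radius + (np.linalg.norm(cell / 2.0) if mode == "center" else np.linalg.norm(cell))
    nmax = np.ceil(reach / cell).astype(int)
    ii, jj, kk = np.mgrid[-nmax[0]:nmax[0] + 1, -nmax[1]:nmax[1] + 1, -nmax[2]:nmax[2] + 1]
    offs = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    keep = np.linalg.norm((np.abs(offs) - 1).clip(min=0) * cell, axis=1) <= reach
    return offs[keep]


def rasterize_points(
    points: np.ndarray,
    radii: np.ndarray,
    grid: GridSpec,
    mode: str = "center",
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Mark grid cells covered by spheres; returns a {0,1} float array.

    Atoms whose sphere lies wholly outside the grid are ignored (the grid is
    the analysis window). Non-finite coordinates raise.
    """
    if mode not in ("center", "overlap"):
        raise ValidationError(f"unknown rasterization mode {mode!r}")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (points.shape[0],))
    if points.size and not np.all(np.isfinite(points)):
        raise ValidationError("non-finite coordinates in frame")
    values = np.zeros(grid.dims, dtype=float) if out is None else out
    if points.shape[0] == 0:
        return values
    origin = np.asarray(grid.origin)
    cell = np.asarray(grid.cell)
    dims = np.asarray(grid.dims)
    centers0 = origin + cell / 2.0

    for r in np.unique(radii):
        pts = points[radii == r]
        offs = _candidate_offsets(float(r), cell, mode)
        home = np.floor((pts - origin) / cell).astype(int)          # (P, 3)
        cand = home[:, None, :] + offs[None, :, :]                  # (P, O, 3)
        inside = np.all((cand >= 0) & (cand < dims), axis=2)
        if mode == "center":
            cc = centers0 + cand * cell
            hit = np.sum((cc - pts[:, None, :]) ** 2, axis=2) <= r * r
        else:
            lo = origin + cand * cell
            nearest = np.clip(pts[:, None, :], lo, lo + cell)
            hit = np.sum((nearest - pts[:, None, :]) ** 2, axis=2) <= r * r
        sel = cand[hit & inside]
        values[sel[:, 0], sel[:, 1], sel[:, 2]] = 1.0
    return values


def rasterize_frame(
    frame: Frame,
    atom_indices: Sequence[int],
    topology: Sequence[AtomMeta],
    grid: GridSpec,
    mode: str = "center",
) -> OccupancyMap:
    """Binary occupancy of one frame for the selected atoms."""
    idx = np.asarray(atom_indices, dtype=int)
    radii = np.array([topology[i].vdw_radius for i in idx]) if idx.size else np.empty(0)
    values = rasterize_points(frame.coords[idx] if idx.size else np.empty((0, 3)), radii, grid, mode)
    return OccupancyMap(grid=grid, values=values, stage=Stage.BINARY_FRAME)


def average_maps(maps: Iterable[OccupancyMap]) -> OccupancyMap:
    """Arithmetic per-cell mean of binary frame maps (identical grids)."""
    maps = list(maps)
    if not maps:
        raise ValidationError("at least one map is required")
    grid = maps[0].grid
    total = np.zeros(grid.dims, dtype=float)
    for m in maps:
        if m.grid != grid:
            raise ValidationError("all maps must share the same GridSpec")
        total += m.values
    return OccupancyMap(grid=grid, values=total / len(maps), stage=Stage.AVERAGED)


def trajectory_occupancy(
    trajectory: Trajectory,
    atom_indices: Sequence[int],
    grid: GridSpec,
    mode: str = "center",
    frame_range: tuple[int, int] | None = None,
) -> OccupancyMap:
    """Frame-averaged occupancy, streaming over frames to bound memory."""
    lo, hi = frame_range if frame_range is not None else (0, trajectory.n_frames)
    if not 0 <= lo < hi <= trajectory.n_frames:
        raise ValidationError(f"invalid frame_range {frame_range}")
    idx = np.asarray(atom_indices, dtype=int)
    radii = trajectory.radii(idx) if idx.size else np.empty(0)
    total = np.zeros(grid.dims, dtype=float)
    scratch = np.empty(grid.dims, dtype=float)
    for f in range(lo, hi):
        scratch[:] = 0.0
        pts = trajectory.coords[f, idx] if idx.size else np.empty((0, 3))
        rasterize_points(pts, radii, grid, mode, out=scratch)
        total += scratch
    return OccupancyMap(grid=grid, values=total / (hi - lo), stage=Stage.AVERAGED)


def region_from_bounds(
    grid: GridSpec,
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Convert per-axis Å bounds into half-open cell-index bounds, clipped to
    the grid."""
    out = []
    for axis, (lo, hi) in enumerate(bounds):
        i_lo = int(np.floor((lo - grid.origin[axis]) / grid.cell[axis]))
        i_hi = int(np.ceil((hi - grid.origin[axis]) / grid.cell[axis]))
        i_lo, i_hi = max(i_lo, 0), min(i_hi, grid.dims[axis])
        if i_lo >= i_hi:
            raise ValidationError(f"bounds {bounds[axis]} select no cells on axis {axis}")
        out.append((i_lo, i_hi))
    return tuple(out)


def normalize_bulk(
    avg_map: OccupancyMap,
    bulk_region: tuple[tuple[int, int], tuple[int, int], tuple[int, int]],
) -> tuple[OccupancyMap, float]:
    """Divide by the mean occupancy of ``bulk_region`` (half-open index
    bounds per axis); returns the normalized map and the bulk value."""
    if avg_map.stage is not Stage.AVERAGED:
        raise ValidationError("normalize_bulk expects an AVERAGED map")
    sl = []
    for axis, (lo, hi) in enumerate(bulk_region):
        if not (0 <= lo < hi <= avg_map.grid.dims[axis]):
            raise ValidationError(f"bulk_region out of bounds on axis {axis}: {(lo, hi)}")
        sl.append(slice(lo, hi))
    bulk_value = float(avg_map.values[tuple(sl)].mean())
    if bulk_value <= 0:
        raise DegenerateInputError("bulk region has zero mean occupancy")
    return (
        OccupancyMap(grid=avg_map.grid, values=avg_map.values / bulk_value, stage=Stage.NORMALIZED),
        bulk_value,
    )
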