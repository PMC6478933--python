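"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: reachability is a
naive breadth-first search over an explicit directed edge set, correlation is
the covariance formula evaluated directly, and sphere rasterization counts
lattice offsets by exhaustive enumeration.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def monotone_reachable_bfs(
    open_cells: np.ndarray, z_sign: int, connectivity: int = 6
) -> np.ndarray:
    """Cells reachable from the entrance slice by open paths whose z index
    changes only by ``z_sign`` (lateral steps free).

    ``z_sign=+1`` seeds slice k=0 and allows dz in {0, +1} (trans→cis);
    ``z_sign=-1`` seeds the top slice and allows dz in {0, −1}.
    """
    open_cells = np.asarray(open_cells, dtype=bool)
    nx, ny, nz = open_cells.shape
    if connectivity == 6:
        steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, z_sign)]
    elif connectivity == 26:
        steps = [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (0, z_sign)
            if (dx, dy, dz) != (0, 0, 0)
        ]
    else:
        raise ValueError(connectivity)
    k0 = 0 if z_sign > 0 else nz - 1
    reach = np.zeros_like(open_cells)
    queue: deque[tuple[int, int, int]] = deque()
    for i in range(nx):
        for j in range(ny):
            if open_cells[i, j, k0]:
                reach[i, j, k0] = True
                queue.append((i, j, k0))
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in steps:
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
                if open_cells[a, b, c] and not reach[a, b, c]:
                    reach[a, b, c] = True
                    queue.append((a, b, c))
    return reach


def plain_reachable_bfs(open_cells: np.ndarray) -> np.ndarray:
    """Undirected 6-connectivity flood fill from both entrance slices."""
    open_cells = np.asarray(open_cells, dtype=bool)
    nx, ny, nz = open_cells.shape
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    reach = np.zeros_like(open_cells)
    queue: deque[tuple[int, int, int]] = deque()
    for i in range(nx):
        for j in range(ny):
            for k in (0, nz - 1):
                if open_cells[i, j, k] and not reach[i, j, k]:
                    reach[i, j, k] = True
                    queue.append((i, j, k))
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in steps:
            a, b, c = i + di, j + dj, k + dk
            if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
                if open_cells[a, b, c] and not reach[a, b, c]:
                    reach[a, b, c] = True
                    queue.append((a, b, c))
    return reach


def pearson_fit_bruteforce(x, y) -> tuple[float, float, float]:
    """(r, slope, intercept) from the raw covariance sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    mx, my = x.sum() / n, y.sum() / n
    sxy = float(((x - mx) * (y - my)).sum())
    sxx = float(((x - mx) ** 2).sum())
    syy = float(((y - my) ** 2).sum())
    r = sxy / np.sqrt(sxx * syy)
    slope = sxy / sxx
    return r, slope, my - slope * mx


def sphere_cell_count(radius: float, cell: float, center_on_cell_center: bool = True) -> int:
    """Number of cell centers within ``radius`` of a sphere center placed on a
    cell center, by exhaustive lattice enumeration."""
    n = int(np.ceil(radius / cell)) + 1
    count = 0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if (i * i + j * j + k * k) * cell * cell <= radius * radius:
                    count += 1
    return count
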