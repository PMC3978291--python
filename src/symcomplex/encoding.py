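"""Grid discretization of continuous 2-D trajectories.

A trajectory sampled in a rectangular workspace is coarse-grained by a grid
of square cells; each crossing of a cell boundary emits one symbol
(``l``/``r``/``u``/``d``).  This is the standard symbolic-dynamics
construction: the entropy of the symbol string lower-bounds the entropy of
the underlying smooth system for any choice of partition.

Conventions
-----------
* Cells are half-open: cell ``(i, j)`` covers
  ``[i*s, (i+1)*s) x [j*s, (j+1)*s)`` relative to the lower-left origin.
* ``x`` increasing emits ``r``; ``y`` increasing emits ``u``.
* Samples outside the workspace are clamped onto the boundary within a
  tolerance of 1e-6 cm; beyond that they are an error.
* If one sampling interval crosses several boundaries, the symbols are
  emitted in the order the linearly interpolated segment crosses them;
  exact ties (corner hits) are broken by the larger absolute displacement
  component, then x-first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import EmptyInputError, SymbolSequence

CLAMP_TOL_CM = 1e-6


class OutOfBoundsError(ValueError):
    """A sample lies outside the workspace beyond the clamping tolerance."""


class GridConfigError(ValueError):
    """An inconsistent grid/workspace configuration."""


@dataclass(frozen=True)
class GridSpec:
    """A rectangular grid of square cells.

    Parameters
    ----------
    width_cells, height_cells : int
        Number of cells along x and y (>= 1).
    cell_size : float
        Cell edge length in cm.
    origin : (float, float)
        Lower-left corner of the workspace in cm.
    """

    width_cells: int = 10
    height_cells: int = 10
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width_cells < 1 or self.height_cells < 1:
            raise GridConfigError("grid must have at least one cell per axis")
        if not self.cell_size > 0:
            raise GridConfigError("cell size must be positive")

    @property
    def extent(self) -> tuple[float, float]:
        """Workspace extent (width, height) in cm."""
        return (self.width_cells * self.cell_size, self.height_cells * self.cell_size)

    def n_moves(self, i: int, j: int) -> int:
        """Number of admissible unit moves from cell (i, j)."""
        return (
            (i > 0)
            + (i < self.width_cells - 1)
            + (j > 0)
            + (j < self.height_cells - 1)
        )

    def _to_units(self, x: float, y: float) -> tuple[float, float]:
        """Map cm coordinates to cell units, clamping within tolerance."""
        ox, oy = self.origin
        w, h = self.extent
        tol = CLAMP_TOL_CM
        if not (ox - tol <= x <= ox + w + tol and oy - tol <= y <= oy + h + tol):
            raise OutOfBoundsError(
                f"sample ({x}, {y}) outside workspace "
                f"[{ox}, {ox + w}] x [{oy}, {oy + h}]"
            )
        px = min(max(x, ox), ox + w) - ox
        py = min(max(y, oy), oy + h) - oy
        return px / self.cell_size, py / self.cell_size

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """Cell containing a point (half-open convention, edges clamped in)."""
        px, py = self._to_units(x, y)
        i = min(int(math.floor(px)), self.width_cells - 1)
        j = min(int(math.floor(py)), self.height_cells - 1)
        return i, j

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        ox, oy = self.origin
        return (ox + (i + 0.5) * self.cell_size, oy + (j + 0.5) * self.cell_size)


@dataclass(frozen=True)
class Trajectory:
    """An ordered list of (time ms, x cm, y cm) samples."""

    samples: np.ndarray  # shape (n, 3): t_ms, x_cm, y_cm
    sampling_rate: float | None = None  # Hz, informational

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of (t, x, y)")
        if arr.shape[0] and np.any(np.diff(arr[:, 0]) <= 0):
            raise ValueError("sample times must be strictly increasing")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]

    @classmethod
    def from_csv(cls, path, sampling_rate: float | None = None) -> "Trajectory":
        """Read a ``t_ms,x_cm,y_cm`` CSV file."""
        df = pd.read_csv(path)
        expected = ["t_ms", "x_cm", "y_cm"]
        if list(df.columns[:3]) != expected:
            raise ValueError(f"trajectory CSV must have columns {expected}")
        return cls(df[expected].to_numpy(float), sampling_rate=sampling_rate)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.samples, columns=["t_ms", "x_cm", "y_cm"]).to_csv(
            path, index=False
        )


def _segment_crossings(grid: GridSpec, p0, p1):
    """Boundary crossings of the straight segment p0→p1, in cm coordinates.

    Returns a list of (t, priority, symbol) where t is the interpolation
    parameter in (0, 1] and priority implements the corner tie-break.
    """
    ux0, uy0 = grid._to_units(*p0)
    ux1, uy1 = grid._to_units(*p1)
    i0 = min(int(math.floor(ux0)), grid.width_cells - 1)
    i1 = min(int(math.floor(ux1)), grid.width_cells - 1)
    j0 = min(int(math.floor(uy0)), grid.height_cells - 1)
    j1 = min(int(math.floor(uy1)), grid.height_cells - 1)
    dx, dy = ux1 - ux0, uy1 - uy0
    # Tie-break: larger |displacement| first, then x before y.
    x_prio = 0 if abs(dx) >= abs(dy) else 1
    out = []
    if i1 > i0:
        for b in range(i0 + 1, i1 + 1):
            out.append(((b - ux0) / dx, x_prio, "r"))
    elif i1 < i0:
        for b in range(i0, i1, -1):
            out.append(((b - ux0) / dx, x_prio, "l"))
    if j1 > j0:
        for b in range(j0 + 1, j1 + 1):
            out.append(((b - uy0) / dy, 1 - x_prio, "u"))
    elif j1 < j0:
        for b in range(j0, j1, -1):
            out.append(((b - uy0) / dy, 1 - x_prio, "d"))
    out.sort()
    return out


def discretize(traj: Trajectory, grid: GridSpec, label: str | None = None) -> SymbolSequence:
    """Convert a trajectory into its cell-transition symbol sequence.

    One symbol is emitted per cell-boundary crossing; samples that stay
    within their cell emit nothing.

    Raises
    ------
    EmptyInputError
        If the trajectory has no samples.
    OutOfBoundsError
        If any sample lies outside the workspace beyond tolerance.
    """
    if len(traj) == 0:
        raise EmptyInputError("cannot discretize an empty trajectory")
    xy = traj.xy
    symbols: list[str] = []
    p_prev = tuple(xy[0])
    grid.cell_index(*p_prev)  # bounds check for the first sample
    for row in xy[1:]:
        p = (float(row[0]), float(row[1]))
        for _, _, sym in _segment_crossings(grid, p_prev, p):
            symbols.append(sym)
        p_prev = p
    return SymbolSequence("".join(symbols), label=label)


def regrid(
    traj: Trajectory,
    sizes: list[float],
    workspace: tuple[float, float] = (10.0, 10.0),
    origin: tuple[float, float] = (0.0, 0.0),
) -> dict[float, SymbolSequence]:
    """Re-discretize one trajectory at several grid sizes.

    Each cell size must tile the workspace exactly.  For smooth
    trajectories the sequence length is non-decreasing as the cell size
    decreases.
    """
    out: dict[float, SymbolSequence] = {}
    for size in sizes:
        w = workspace[0] / size
        h = workspace[1] / size
        if round(w) < 1 or round(h) < 1:
            raise GridConfigError(f"cell size {size} larger than workspace")
        if abs(w - round(w)) > 1e-9 or abs(h - round(h)) > 1e-9:
            raise GridConfigError(f"cell size {size} does not tile workspace {workspace}")
        grid = GridSpec(int(round(w)), int(round(h)), size, origin)
        out[size] = discretize(traj, grid)
    return out


def replay(seq: SymbolSequence, grid: GridSpec, start: tuple[int, int] | None = None,
           dt_ms: float = 1.0) -> Trajectory:
    """Replay a symbol sequence as cell-center waypoints.

    The inverse of :func:`discretize` up to within-cell detail:
    re-discretizing the replayed trajectory on the same grid reproduces the
    sequence exactly, provided the path stays inside the grid.
    """
    from .sequences import MOVES

    if start is None:
        start = (grid.width_cells // 2, grid.height_cells // 2)
    i, j = start
    pts = [(0.0, *grid.cell_center(i, j))]
    for t, c in enumerate(seq.symbols, start=1):
        dx, dy = MOVES[c]
        i, j = i + dx, j + dy
        if not (0 <= i < grid.width_cells and 0 <= j < grid.height_cells):
            raise OutOfBoundsError("sequence walks outside the grid during replay")
        pts.append((t * dt_ms, *grid.cell_center(i, j)))
    return Trajectory(np.array(pts))
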