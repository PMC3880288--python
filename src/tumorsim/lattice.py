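"""Grid geometry, neighborhoods and the tumor-cell lattice.

Coordinates are 0-based integer lattice indices; a physical position is
``index * spacing``.  Each grid point holds at most one tumor cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .config import SimulationConfig
from .errors import ConfigError, GridError

# phenotype codes
EMPTY = 0
ACTIVE = 1
QUIESCENT = 2
NECROTIC = 3

PHENOTYPE_NAMES = {EMPTY: "empty", ACTIVE: "active",
                   QUIESCENT: "quiescent", NECROTIC: "necrotic"}


@dataclass(frozen=True)
class GridSpec:
    shape: tuple[int, int, int]
    spacing: float  # m

    @property
    def center(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.shape)


def make_grid(config: SimulationConfig) -> GridSpec:
    """Grid descriptor: shape and spacing = domain_edge / points per axis."""
    n = config.grid_points_per_axis
    if n <= 0:
        raise ConfigError(f"grid size must be positive, got {n}")
    return GridSpec(shape=(n, n, n), spacing=config.domain_edge / n)


def cube_offsets(K: int) -> list[tuple[int, int, int]]:
    """All nonzero offsets of the (2K+1)^3 cube."""
    return [
        (dx, dy, dz)
        for dx in range(-K, K + 1)
        for dy in range(-K, K + 1)
        for dz in range(-K, K + 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]


FACE_OFFSETS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)
MOORE_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(cube_offsets(1))


def neighborhood(point, shape, mode: str = "moore26",
                 K: int | None = None) -> list[tuple[int, int, int]]:
    """In-bounds neighbors of ``point``.

    ``mode`` is one of ``"faces6"`` (the 6 face neighbors), ``"moore26"``
    (the 26 neighbors of the surrounding cube) or ``"cube"`` with an explicit
    half-width ``K``.  Boundary points return truncated lists.
    """
    x, y, z = point
    nx, ny, nz = shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise IndexError(f"point {point} outside grid {shape}")
    if mode == "faces6":
        offsets: Iterable = FACE_OFFSETS
    elif mode == "moore26":
        offsets = MOORE_OFFSETS
    elif mode == "cube":
        if K is None or K < 1:
            raise ValueError("cube mode requires K >= 1")
        offsets = cube_offsets(K)
    else:
        raise ValueError(f"unknown neighborhood mode {mode!r}")
    out = []
    for dx, dy, dz in offsets:
        px, py, pz = x + dx, y + dy, z + dz
        if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz:
            out.append((px, py, pz))
    return out


class CellLattice:
    """Per-voxel tumor-cell records stored as dense arrays.

    ``phenotype`` is 0 where no cell sits; activity, CVE and age are only
    meaningful at occupied voxels.  Necrotic cells keep occupying their voxel
    forever (the model removes no cells).
    """

    def __init__(self, shape):
        self.shape = tuple(shape)
        self.phenotype = np.zeros(self.shape, dtype=np.int8)
        self.activity = np.zeros(self.shape, dtype=np.float64)
        self.cve = np.zeros(self.shape, dtype=np.float64)
        self.age_steps = np.zeros(self.shape, dtype=np.int32)

    # -- queries ----------------------------------------------------------
    @property
    def occupied(self) -> np.ndarray:
        return self.phenotype != EMPTY

    @property
    def alive(self) -> np.ndarray:
        return (self.phenotype == ACTIVE) | (self.phenotype == QUIESCENT)

    def count(self, phenotype: int | None = None) -> int:
        if phenotype is None:
            return int(np.count_nonzero(self.phenotype))
        return int(np.count_nonzero(self.phenotype == phenotype))

    def positions(self, phenotype: int | None = None) -> np.ndarray:
        """(P, 3) integer positions of (all or one phenotype of) cells."""
        mask = self.occupied if phenotype is None else self.phenotype == phenotype
        return np.argwhere(mask)

    # -- mutation ---------------------------------------------------------
    def add_cell(self, point, phenotype: int = ACTIVE, activity: float = 1.0,
                 cve: float = 0.0, age: int = 0) -> None:
        if self.phenotype[point] != EMPTY:
            raise GridError(f"voxel {tuple(point)} already holds a cell")
        self.phenotype[point] = phenotype
        self.activity[point] = activity
        self.cve[point] = cve
        self.age_steps[point] = age

    def copy(self) -> "CellLattice":
        out = CellLattice(self.shape)
        out.phenotype = self.phenotype.copy()
        out.activity = self.activity.copy()
        out.cve = self.cve.copy()
        out.age_steps = self.age_steps.copy()
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellLattice):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.phenotype, other.phenotype)
            and np.array_equal(self.activity, other.activity)
            and np.array_equal(self.cve, other.cve)
            and np.array_equal(self.age_steps, other.age_steps)
        )


def cell_density_theta(lattice: CellLattice, point, K: int) -> float:
    """Local tumor-cell number fraction theta^c in the K-cube around ``point``.

    The denominator is always the nominal (2K+1)^3 even at domain boundaries:
    points outside the domain cannot hold cells and count as empty.
    """
    x, y, z = point
    nx, ny, nz = lattice.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise IndexError(f"point {point} outside grid {lattice.shape}")
    xs = slice(max(0, x - K), min(nx, x + K + 1))
    ys = slice(max(0, y - K), min(ny, y + K + 1))
    zs = slice(max(0, z - K), min(nz, z + K + 1))
    occ = int(np.count_nonzero(lattice.phenotype[xs, ys, zs]))
    return occ / float((2 * K + 1) ** 3)
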