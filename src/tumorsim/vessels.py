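"""The endothelial segment network.

Vessels are chains/trees of segments, one segment per lattice voxel.  Every
non-root segment has exactly one parent; sprouting adds children, pruning
removes a segment together with its distal subtree.  Tumor cells and
endothelial cells live on separate lattices, so a voxel may hold one of each,
but never two vessel segments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SimulationConfig
from .errors import GridError, VesselFileError

ROOT = -1


@dataclass
class Segment:
    id: int
    parent: int
    pos: tuple[int, int, int]
    age: float
    radius: float
    is_tip: bool = False
    stall: int = 0          # consecutive stalled migration attempts (tips)
    acc: float = 0.0        # accumulated growth toward the next voxel (tips)


class VesselNetwork:
    """Forest of vessel segments with a voxel-occupancy index."""

    def __init__(self):
        self.segments: dict[int, Segment] = {}
        self._occupancy: dict[tuple[int, int, int], int] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------
    def add_segment(self, pos, parent: int = ROOT, age: float = 0.0,
                    radius: float = 0.0, is_tip: bool = False,
                    seg_id: int | None = None) -> int:
        pos = tuple(int(v) for v in pos)
        if pos in self._occupancy:
            raise GridError(f"voxel {pos} already holds a vessel segment")
        if parent != ROOT and parent not in self.segments:
            raise GridError(f"parent segment {parent} does not exist")
        if seg_id is None:
            seg_id = self._next_id
        elif seg_id in self.segments:
            raise GridError(f"segment id {seg_id} already exists")
        self._next_id = max(self._next_id, seg_id + 1)
        self.segments[seg_id] = Segment(seg_id, parent, pos, float(age),
                                        float(radius), is_tip)
        self._occupancy[pos] = seg_id
        return seg_id

    # -- queries ----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.segments)

    def __contains__(self, seg_id: int) -> bool:
        return seg_id in self.segments

    def segment_at(self, pos) -> Segment | None:
        sid = self._occupancy.get(tuple(pos))
        return None if sid is None else self.segments[sid]

    def occupies(self, pos) -> bool:
        return tuple(pos) in self._occupancy

    @property
    def roots(self) -> list[int]:
        return [s.id for s in self.segments.values() if s.parent == ROOT]

    @property
    def tips(self) -> list[int]:
        return sorted(s.id for s in self.segments.values() if s.is_tip)

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {sid: [] for sid in self.segments}
        for s in self.segments.values():
            if s.parent != ROOT:
                out[s.parent].append(s.id)
        return out

    def positions(self) -> np.ndarray:
        """(P, 3) array of segment voxel positions, ordered by id."""
        if not self.segments:
            return np.empty((0, 3), dtype=np.intp)
        return np.array([self.segments[i].pos for i in sorted(self.segments)],
                        dtype=np.intp)

    def occupancy_grid(self, shape) -> np.ndarray:
        grid = np.zeros(shape, dtype=bool)
        for pos in self._occupancy:
            grid[pos] = True
        return grid

    def radius_grid(self, shape) -> np.ndarray:
        grid = np.zeros(shape, dtype=np.float64)
        for pos, sid in self._occupancy.items():
            grid[pos] = self.segments[sid].radius
        return grid

    def is_forest(self) -> bool:
        """True when parent links are acyclic and reference live segments."""
        for s in self.segments.values():
            seen = set()
            cur = s.id
            while cur != ROOT:
                if cur in seen:
                    return False
                seen.add(cur)
                seg = self.segments.get(cur)
                if seg is None:
                    return False
                cur = seg.parent
        return True

    def descendants(self, seg_id: int) -> set[int]:
        children = self.children_map()
        stack, out = [seg_id], set()
        while stack:
            cur = stack.pop()
            for c in children.get(cur, ()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    # -- removal ----------------------------------------------------------
    def remove_subtree(self, seg_id: int) -> int:
        """Remove ``seg_id`` and its whole distal subtree; return count removed."""
        doomed = {seg_id} | self.descendants(seg_id)
        for sid in doomed:
            seg = self.segments.pop(sid)
            del self._occupancy[seg.pos]
        # a surviving parent whose children were all removed becomes a tip again
        children = self.children_map()
        for s in self.segments.values():
            if not children[s.id] and not s.is_tip:
                s.is_tip = True
        return len(doomed)

    def copy(self) -> "VesselNetwork":
        out = VesselNetwork()
        for sid in sorted(self.segments):
            s = self.segments[sid]
            out.segments[sid] = Segment(s.id, s.parent, s.pos, s.age, s.radius,
                                        s.is_tip, s.stall, s.acc)
            out._occupancy[s.pos] = sid
        out._next_id = self._next_id
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, VesselNetwork):
            return NotImplemented
        if set(self.segments) != set(other.segments):
            return False
        # structural equality; tip/stall bookkeeping is runtime-only state
        for sid, s in self.segments.items():
            o = other.segments[sid]
            if (s.parent, s.pos, s.age, s.radius) != (
                    o.parent, o.pos, o.age, o.radius):
                return False
        return True


# ---------------------------------------------------------------------------
# file I/O: CSV edge list, columns id,parent_id,x,y,z,radius,age
# ---------------------------------------------------------------------------

def write_vessel_file(network: VesselNetwork, path, units: str = "grid",
                      spacing: float | None = None) -> None:
    """Write the network as a CSV edge list (UTF-8, comma-separated).

    ``units`` is recorded in a leading comment line; with ``units="meters"``
    coordinates are written as ``index * spacing``.
    """
    if units not in ("grid", "meters"):
        raise ValueError(f"units must be 'grid' or 'meters', got {units!r}")
    if units == "meters" and not spacing:
        raise ValueError("units='meters' requires a spacing")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# units={units}\n")
        writer = csv.writer(fh)
        writer.writerow(["id", "parent_id", "x", "y", "z", "radius", "age"])
        for sid in sorted(network.segments):
            s = network.segments[sid]
            if units == "meters":
                coords = [repr(v * spacing) for v in s.pos]
            else:
                coords = list(s.pos)
            writer.writerow([s.id, s.parent, *coords, repr(s.radius), repr(s.age)])


def load_vessel_file(path, spacing: float | None = None) -> VesselNetwork:
    """Load a CSV edge list written by :func:`write_vessel_file`.

    Root segments carry ``parent_id = -1``.  Malformed rows, duplicate ids and
    references to unknown parents raise :class:`VesselFileError` naming the
    offending line.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    units = "grid"
    start = 0
    if lines and lines[0].startswith("#"):
        tag = lines[0].lstrip("#").strip()
        if tag.startswith("units="):
            units = tag.split("=", 1)[1].strip()
        start = 1
    if units not in ("grid", "meters"):
        raise VesselFileError(f"line 1: unknown units flag {units!r}")
    if units == "meters" and not spacing:
        raise VesselFileError("file stores meters; a grid spacing is required")
    if start >= len(lines):
        raise VesselFileError("missing header row")
    header = [h.strip() for h in lines[start].split(",")]
    if header != ["id", "parent_id", "x", "y", "z", "radius", "age"]:
        raise VesselFileError(f"line {start + 1}: unexpected header {header}")

    rows = []
    for lineno, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise VesselFileError(f"line {lineno}: expected 7 fields, got {len(parts)}")
        try:
            sid = int(parts[0])
            parent = int(parts[1])
            coords = [float(v) for v in parts[2:5]]
            radius = float(parts[5])
            age = float(parts[6])
        except ValueError as exc:
            raise VesselFileError(f"line {lineno}: {exc}") from None
        if units == "meters":
            pos = tuple(int(round(v / spacing)) for v in coords)
        else:
            pos = tuple(int(round(v)) for v in coords)
        rows.append((lineno, sid, parent, pos, radius, age))

    network = VesselNetwork()
    ids = {r[1] for r in rows}
    for lineno, sid, parent, pos, radius, age in rows:
        if sid in network.segments:
            raise VesselFileError(f"line {lineno}: duplicate id {sid}")
        if parent != ROOT and parent not in ids:
            raise VesselFileError(f"line {lineno}: unknown parent {parent}")
        try:
            network.segments[sid] = Segment(sid, parent, pos, age, radius)
            if pos in network._occupancy:
                raise VesselFileError(
                    f"line {lineno}: voxel {pos} listed twice")
            network._occupancy[pos] = sid
        except GridError as exc:
            raise VesselFileError(f"line {lineno}: {exc}") from None
    network._next_id = max(ids, default=-1) + 1
    if not network.is_forest():
        raise VesselFileError("parent links contain a cycle")
    # segments without children are growth tips
    children = network.children_map()
    for s in network.segments.values():
        s.is_tip = not children[s.id]
    return network


# ---------------------------------------------------------------------------
# parent-vasculature fixtures
# ---------------------------------------------------------------------------

def generate_parent_vessel_fixture(config: SimulationConfig,
                                   style: str = "single_axis") -> VesselNetwork:
    """Deterministic pre-existing vasculature for sprouting to start from.

    ``single_axis``: one straight vessel spanning the x-axis, offset from the
    tumor center by ``parent_vessel_offset`` along y.  ``face_grid``: a planar
    comb of ``parent_vessel_count`` parallel x-axis vessels in the plane
    y = offset.
    """
    from .angiogenesis import radius_map  # local import: avoids module cycle

    n = config.grid_points_per_axis
    c = n // 2
    age = config.parent_vessel_age
    radius = radius_map(age, config)
    network = VesselNetwork()

    def add_line(y: int, z: int) -> None:
        # mature parent voxels are independent roots: the pre-existing vessel
        # is perfused from outside the box, so losing one voxel to the
        # necrotic core must not sever the rest of the line
        for x in range(n):
            network.add_segment((x, y, z), parent=ROOT, age=age,
                                radius=radius)

    if style == "single_axis":
        y = min(n - 1, max(0, c + config.parent_vessel_offset))
        add_line(y, c)
    elif style == "face_grid":
        y = min(n - 1, max(0, c + config.parent_vessel_offset))
        count = config.parent_vessel_count
        zs = np.linspace(0, n - 1, count + 2)[1:-1].round().astype(int)
        for z in zs:
            add_line(y, int(z))
    else:
        raise ValueError(f"unknown fixture style {style!r}")
    return network
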