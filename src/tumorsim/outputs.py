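"""Run outputs: time series, volumetric snapshots, checkpoints, manifest."""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .fields import ScalarField
from .lattice import CellLattice
from .state import SimulationState
from .vessels import VesselNetwork, load_vessel_file, write_vessel_file

__all__ = [
    "write_vtk_structured_points",
    "write_outputs",
    "save_state",
    "load_state",
    "rerun_from_manifest",
]


def write_vtk_structured_points(path, name: str, values: np.ndarray,
                                spacing: float) -> None:
    """Write a 3D scalar array as legacy ASCII VTK structured points.

    Values are emitted in VTK's x-fastest order so the file opens in standard
    viewers.
    """
    v = np.asarray(values, dtype=np.float64)
    nx, ny, nz = v.shape
    with open(path, "w", encoding="ascii") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} double 1\n")
        fh.write("LOOKUP_TABLE default\n")
        flat = v.ravel(order="F")
        for start in range(0, flat.size, 9):
            fh.write(" ".join(f"{x:.9g}" for x in flat[start:start + 9]) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(state: SimulationState, record: pd.DataFrame, outdir,
                  tag: str = "final") -> dict:
    """Write the standard output set and return the manifest dictionary.

    Files: the time-series CSV, one ASCII VTK volume per species plus a
    compressed array archive, the vessel edge list, and a JSON manifest
    (config + seed + version + checksums) that can reproduce the run.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    ts = outdir / "timeseries.csv"
    record.to_csv(ts, index=False)
    files.append(ts)

    arrays = {"pressure": state.pressure.values}
    for name, f in state.fields.items():
        arrays[name] = f.values
    for name, values in arrays.items():
        vtk = outdir / f"field_{name}_{tag}.vtk"
        write_vtk_structured_points(vtk, name, values, state.grid.spacing)
        files.append(vtk)
    npz = outdir / f"fields_{tag}.npz"
    np.savez_compressed(npz, **arrays)
    files.append(npz)

    vessels = outdir / "vessels.csv"
    write_vessel_file(state.vessels, vessels)
    files.append(vessels)

    manifest = {
        "package": "tumorsim",
        "version": __version__,
        "seed": state.config.rng_seed,
        "final_step": state.step,
        "config": state.config.to_dict(),
        "checksums": {f.name: _sha256(f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def rerun_from_manifest(path):
    """Re-run the simulation recorded in a manifest; returns the RunResult."""
    from .driver import run_simulation

    manifest = json.loads(Path(path).read_text())
    config = SimulationConfig.from_dict(manifest["config"])
    return run_simulation(config)


# ---------------------------------------------------------------------------
# checkpoint / restart
# ---------------------------------------------------------------------------

def save_state(state: SimulationState, path) -> None:
    """Checkpoint the full state into one compressed archive."""
    buf = io.StringIO()
    write_vessel_file_to_buffer(state.vessels, buf)
    payload = {
        "step": np.array([state.step]),
        "phenotype": state.lattice.phenotype,
        "activity": state.lattice.activity,
        "cve": state.lattice.cve,
        "age_steps": state.lattice.age_steps,
        "pressure": state.pressure.values,
        "division_threshold": np.array([state.division_threshold]),
        "drug_source_clipped": np.array([state.drug_source_clipped]),
        "config_json": np.frombuffer(
            json.dumps(state.config.to_dict()).encode(), dtype=np.uint8),
        "vessels_csv": np.frombuffer(buf.getvalue().encode(), dtype=np.uint8),
        # runtime tip bookkeeping is not part of the edge-list format
        "seg_ids": np.array(sorted(state.vessels.segments), dtype=np.int64),
        "seg_tip": np.array([state.vessels.segments[i].is_tip
                             for i in sorted(state.vessels.segments)],
                            dtype=bool),
        "seg_stall": np.array([state.vessels.segments[i].stall
                               for i in sorted(state.vessels.segments)],
                              dtype=np.int64),
        "seg_acc": np.array([state.vessels.segments[i].acc
                             for i in sorted(state.vessels.segments)],
                            dtype=np.float64),
    }
    for name, f in state.fields.items():
        payload[f"field_{name}"] = f.values
        payload[f"clipped_{name}"] = np.array([f.clipped_mass])
    np.savez_compressed(path, **payload)


def write_vessel_file_to_buffer(network: VesselNetwork, buf) -> None:
    import csv

    buf.write("# units=grid\n")
    writer = csv.writer(buf)
    writer.writerow(["id", "parent_id", "x", "y", "z", "radius", "age"])
    for sid in sorted(network.segments):
        s = network.segments[sid]
        writer.writerow([s.id, s.parent, *s.pos, repr(s.radius), repr(s.age)])


def load_state(path) -> SimulationState:
    """Restore a checkpoint written by :func:`save_state`."""
    import tempfile

    from .pressure import darcy_velocity
    from .state import init_state

    with np.load(path) as data:
        config = SimulationConfig.from_dict(
            json.loads(bytes(data["config_json"]).decode()))
        state = init_state(config, vessels=VesselNetwork())

        lattice = CellLattice(config.shape)
        lattice.phenotype = data["phenotype"].copy()
        lattice.activity = data["activity"].copy()
        lattice.cve = data["cve"].copy()
        lattice.age_steps = data["age_steps"].copy()
        state.lattice = lattice

        with tempfile.NamedTemporaryFile("w", suffix=".csv",
                                         delete=False) as fh:
            fh.write(bytes(data["vessels_csv"]).decode())
            vname = fh.name
        state.vessels = load_vessel_file(vname)
        Path(vname).unlink()
        for sid, tip, stall, acc in zip(data["seg_ids"], data["seg_tip"],
                                        data["seg_stall"], data["seg_acc"]):
            seg = state.vessels.segments[int(sid)]
            seg.is_tip = bool(tip)
            seg.stall = int(stall)
            seg.acc = float(acc)

        for name in state.fields:
            state.fields[name] = ScalarField(
                data[f"field_{name}"].copy(),
                boundary_value=state.fields[name].boundary_value,
                species=state.fields[name].species,
                clipped_mass=float(data[f"clipped_{name}"][0]))
        state.pressure = ScalarField(data["pressure"].copy(),
                                     boundary_value=0.0, species="pressure")
        state.velocity = darcy_velocity(state.pressure, config.k_hydraulic,
                                        state.grid.spacing)
        state.step = int(data["step"][0])
        state.division_threshold = float(data["division_threshold"][0])
        state.drug_source_clipped = float(data["drug_source_clipped"][0])
    return state
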