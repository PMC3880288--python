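"""The simulation state bundle and its initialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cells import CellRuleParams, calibrate_division_threshold, cell_activity
from .config import SimulationConfig
from .angiogenesis import AngioParams
from .fields import ScalarField
from .lattice import ACTIVE, QUIESCENT, CellLattice, GridSpec, make_grid
from .pharmacology import DrugParams
from .vessels import VesselNetwork, generate_parent_vessel_fixture

__all__ = ["SimulationState", "init_state"]


@dataclass
class SimulationState:
    """Everything one iteration advances: lattice, network, fields, clock."""

    config: SimulationConfig
    grid: GridSpec
    step: int
    lattice: CellLattice
    vessels: VesselNetwork
    fields: dict[str, ScalarField]
    pressure: ScalarField
    velocity: tuple[np.ndarray, np.ndarray, np.ndarray]
    division_threshold: float
    cell_params: CellRuleParams
    angio_params: AngioParams
    drug_params: DrugParams
    drug_source_clipped: float = 0.0

    @property
    def day(self) -> float:
        return self.step / self.config.steps_per_day

    def equals(self, other: "SimulationState") -> bool:
        """Bitwise state equality (configuration, cells, vessels, fields)."""
        if self.config != other.config or self.step != other.step:
            return False
        if self.lattice != other.lattice or self.vessels != other.vessels:
            return False
        for name, f in self.fields.items():
            if not np.array_equal(f.values, other.fields[name].values):
                return False
        return bool(np.array_equal(self.pressure.values, other.pressure.values))

    def copy(self) -> "SimulationState":
        return SimulationState(
            config=self.config,
            grid=self.grid,
            step=self.step,
            lattice=self.lattice.copy(),
            vessels=self.vessels.copy(),
            fields={k: f.copy() for k, f in self.fields.items()},
            pressure=self.pressure.copy(),
            velocity=tuple(u.copy() for u in self.velocity),
            division_threshold=self.division_threshold,
            cell_params=self.cell_params,
            angio_params=self.angio_params,
            drug_params=self.drug_params,
            drug_source_clipped=self.drug_source_clipped,
        )


def _seed_positions(center) -> list[tuple[int, int, int]]:
    cx, cy, cz = center
    # center plus the four in-plane face neighbors of the central z-plane
    return [(cx, cy, cz), (cx + 1, cy, cz), (cx - 1, cy, cz),
            (cx, cy + 1, cz), (cx, cy - 1, cz)]


def init_state(config: SimulationConfig,
               vessels: Optional[VesselNetwork] = None) -> SimulationState:
    """Build the initial state: a five-cell tumor seed at the domain center,
    homogeneous normalized fields, and the configured parent vasculature.

    The seed cells start with half of the calibrated division threshold (a
    newborn's CVE) and an activity evaluated at the initial field values, so
    the first division round falls one full cell cycle after t = 0.
    """
    from .pressure import (combined_pressure, ctp_field, darcy_velocity,
                           vtp_field)

    grid = make_grid(config)
    lattice = CellLattice(grid.shape)

    cell_params = CellRuleParams.from_config(config)
    threshold = config.cve_division_threshold
    if threshold is None:
        threshold = calibrate_division_threshold(cell_params,
                                                 config.steps_per_day)

    a0 = cell_activity(config.n_init, config.w_init, cell_params)
    phen0 = ACTIVE if a0 > config.activity_threshold else QUIESCENT
    for pos in _seed_positions(grid.center):
        lattice.add_cell(pos, phenotype=phen0, activity=a0,
                         cve=threshold / 2.0, age=0)

    if vessels is None:
        if config.parent_vessel == "none":
            vessels = VesselNetwork()
        else:
            vessels = generate_parent_vessel_fixture(config,
                                                     config.parent_vessel)

    fields = {
        "oxygen": ScalarField.uniform(grid.shape, config.n_init, "oxygen"),
        "co2": ScalarField.uniform(grid.shape, config.w_init, "co2"),
        "taf": ScalarField.uniform(grid.shape, config.c_init, "taf"),
        "drug": ScalarField.uniform(grid.shape, config.d_init, "drug"),
    }

    state = SimulationState(
        config=config,
        grid=grid,
        step=0,
        lattice=lattice,
        vessels=vessels,
        fields=fields,
        pressure=ScalarField.uniform(grid.shape, 0.0, "pressure"),
        velocity=(np.zeros(grid.shape), np.zeros(grid.shape),
                  np.zeros(grid.shape)),
        division_threshold=float(threshold),
        cell_params=cell_params,
        angio_params=AngioParams.from_config(config),
        drug_params=DrugParams.from_config(config),
    )
    state.pressure = combined_pressure(ctp_field(state), vtp_field(state))
    state.velocity = darcy_velocity(state.pressure, config.k_hydraulic,
                                    grid.spacing)
    return state
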