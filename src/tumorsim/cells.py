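"""Cellular-scale rules: activity, Cell Vital Energy (CVE), phenotype and
division.

Activity A couples a cell to its metabolic microenvironment: it rises with
local oxygen n and falls with local carbon dioxide w through a product of
Hill terms,

    A(n, w) = n^a / (n^a + K_n^a) * K_w^b / (w^b + K_w^b)     in [0, 1].

The oxygen term (exponent a = 2) models cooperative oxygen dependence of the
cycle; the steep waste term (exponent b = 4) models the sharp loss of
proliferative capacity once acidosis/waste rises a few tens of percent above
the baseline level, which is what ultimately drives the growth-stasis stage.

Cells with A above 0.5 are active: they add CVE at rate k_active * A minus a
Hill-shaped synthesis cost, and divide once the CVE reaches a proliferation
threshold, placing the daughter on the unoccupied Moore neighbor with the
largest pressure drop.  The default Hill constants put the cost just above
the gross gain over mid activities, so the net gain is positive only above a
proliferation checkpoint (A around 0.75): well-resourced cells cycle, cells
between the checkpoint and the quiescence threshold idle and slowly spend
their reserve, and cells at or below 0.5 are quiescent, draining CVE at the
housekeeping rate k_quiescent.  A cell whose CVE reaches zero is necrotic,
irreversibly.  Cytotoxic drug adds an activity-proportional CVE drain
k_drug * A * d to every live compartment.

The division threshold is calibrated so that a newborn cell (which starts
with half of its parent's CVE) under abundant oxygen divides after exactly
``steps_per_day`` iterations, i.e. the 24-hour cell cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .errors import DomainError
from .lattice import ACTIVE, EMPTY, MOORE_OFFSETS, NECROTIC, QUIESCENT

__all__ = [
    "CellRuleParams",
    "cell_activity",
    "hill_consumption",
    "net_cve_gain",
    "calibrate_division_threshold",
    "cve_update",
    "classify_phenotype",
    "attempt_division",
]


@dataclass(frozen=True)
class CellRuleParams:
    k_active: float = 1.0
    k_quiescent: float = 0.1
    activity_threshold: float = 0.5
    K_n_half: float = 0.25
    K_w_half: float = 1.25
    oxygen_hill: float = 2.0
    co2_hill: float = 8.0
    hill_coefficient: float = 6.0
    hill_halfmax: float = 0.45
    hill_max_fraction: float = 0.76
    k_drug: float = 0.5

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "CellRuleParams":
        return cls(
            k_active=config.k_active,
            k_quiescent=config.k_quiescent,
            activity_threshold=config.activity_threshold,
            K_n_half=config.K_n_half,
            K_w_half=config.K_w_half,
            oxygen_hill=config.oxygen_hill,
            co2_hill=config.co2_hill,
            hill_coefficient=config.hill_coefficient,
            hill_halfmax=config.hill_halfmax,
            hill_max_fraction=config.hill_max_fraction,
            k_drug=config.k_drug,
        )

    @property
    def hill_amplitude(self) -> float:
        # chosen so hill(A=1) = hill_max_fraction * k_active
        h = self.hill_halfmax ** self.hill_coefficient
        return self.hill_max_fraction * self.k_active * (1.0 + h)


def cell_activity(n_local, w_local, params: CellRuleParams):
    """Cell activity A in [0, 1]; increasing in oxygen, decreasing in CO2."""
    n = np.asarray(n_local, dtype=np.float64)
    w = np.asarray(w_local, dtype=np.float64)
    if np.any(n < 0) or np.any(w < 0):
        raise DomainError("oxygen and CO2 levels must be non-negative")
    an, bw = params.oxygen_hill, params.co2_hill
    kn = params.K_n_half ** an
    kw = params.K_w_half ** bw
    a = (n ** an / (n ** an + kn)) * (kw / (w ** bw + kw))
    return a if a.ndim else float(a)


def hill_consumption(activity, params: CellRuleParams):
    """Activity-dependent CVE synthesis cost (Hill form)."""
    a = np.asarray(activity, dtype=np.float64)
    m = params.hill_coefficient
    h = params.hill_halfmax ** m
    out = params.hill_amplitude * a ** m / (a ** m + h)
    return out if out.ndim else float(out)


def net_cve_gain(n_local, w_local, params: CellRuleParams) -> float:
    """Per-step CVE gain of a drug-free active cell at the given exposure."""
    a = cell_activity(n_local, w_local, params)
    return params.k_active * a - hill_consumption(a, params)


def calibrate_division_threshold(params: CellRuleParams,
                                 steps_per_day: int) -> float:
    """Threshold giving a one-day birth-to-division time at n = w = 1.

    A newborn starts at half the threshold, so the threshold is twice the CVE
    accumulated over one day at the abundant-oxygen net gain.
    """
    gain = net_cve_gain(1.0, 1.0, params)
    if gain <= 0:
        raise DomainError("net CVE gain at n=w=1 must be positive; "
                          "check the Hill constants")
    return 2.0 * steps_per_day * gain


def cve_update(cve, activity, drug_local, dt, params: CellRuleParams):
    """One CVE step for live cells (vectorized).

    Active cells (A > threshold) gain k_active*A minus the Hill cost; quiescent
    cells drain k_quiescent.  Drug drains k_drug*A*d from both.  The result may
    go negative; classification turns that into necrosis.
    """
    cve = np.asarray(cve, dtype=np.float64)
    a = np.asarray(activity, dtype=np.float64)
    d = np.asarray(drug_local, dtype=np.float64)
    damage = params.k_drug * a * d
    active_rate = params.k_active * a - hill_consumption(a, params) - damage
    quiescent_rate = -(params.k_quiescent + damage)
    rate = np.where(a > params.activity_threshold, active_rate, quiescent_rate)
    out = cve + dt * rate
    return out if out.ndim else float(out)


def classify_phenotype(phenotype, activity, cve, params: CellRuleParams):
    """Phenotype pass: CVE <= 0 is necrotic (terminal); otherwise the activity
    threshold separates active from quiescent, reversibly."""
    ph = np.asarray(phenotype).copy()
    occupied = ph != EMPTY
    necrotic = ph == NECROTIC
    dead = occupied & ~necrotic & (np.asarray(cve) <= 0.0)
    ph[dead] = NECROTIC
    live = occupied & (ph != NECROTIC)
    ph[live & (np.asarray(activity) > params.activity_threshold)] = ACTIVE
    ph[live & (np.asarray(activity) <= params.activity_threshold)] = QUIESCENT
    return ph


def attempt_division(state, point, tie_break_u: float | None = None):
    """Divide the cell at ``point`` if possible; return the daughter position.

    The daughter goes to the unoccupied in-bounds Moore neighbor with the
    largest pressure drop (parent pressure minus neighbor pressure); exact
    ties are broken by ``tie_break_u`` (a uniform in [0,1), drawn from the
    state's division stream when not supplied).  Parent and daughter each
    keep half of the parent's pre-division CVE.  With no free neighbor the
    division is deferred and the CVE capped at the threshold.
    """
    from . import rng

    lattice = state.lattice
    point = tuple(int(v) for v in point)
    p = state.pressure.values
    nx, ny, nz = lattice.shape
    x, y, z = point

    if tie_break_u is None:
        gen = rng.purpose_generator(state.config.rng_seed, state.step,
                                    rng.DIVISION)
        tie_break_u = float(gen.random())

    free = []
    drops = []
    parent_p = p[point]
    for dx, dy, dz in MOORE_OFFSETS:
        nb = (x + dx, y + dy, z + dz)
        if not (0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz):
            continue
        if lattice.phenotype[nb] != EMPTY:
            continue
        free.append(nb)
        drops.append(parent_p - p[nb])

    threshold = state.division_threshold
    if not free:
        lattice.cve[point] = min(lattice.cve[point], threshold)
        return None

    drops = np.asarray(drops)
    best = drops.max()
    ties = [i for i, d in enumerate(drops) if d >= best - 1e-12 * (1.0 + abs(best))]
    chosen = free[ties[min(int(tie_break_u * len(ties)), len(ties) - 1)]]

    half = lattice.cve[point] / 2.0
    lattice.cve[point] = half
    lattice.add_cell(chosen, phenotype=ACTIVE,
                     activity=lattice.activity[point], cve=half, age=0)
    return chosen


def update_cells(state) -> int:
    """Full cellular pass for one iteration; returns the number of divisions.

    Order: recompute activity from the end-of-transport fields, advance CVE,
    classify phenotypes, then let eligible active cells divide in increasing
    linear-index order (so earlier daughters block later ones, preserving the
    one-cell-per-voxel rule).
    """
    from . import rng

    lattice = state.lattice
    params = state.cell_params
    occ = lattice.occupied
    if not occ.any():
        return 0
    necrotic = lattice.phenotype == NECROTIC
    live = occ & ~necrotic

    n = state.fields["oxygen"].values
    w = state.fields["co2"].values
    d = state.fields["drug"].values

    a = np.zeros_like(lattice.activity)
    a[live] = cell_activity(n[live], w[live], params)
    lattice.activity = a

    lattice.cve[live] = cve_update(lattice.cve[live], a[live], d[live], 1.0,
                                   params)
    lattice.phenotype = classify_phenotype(lattice.phenotype, lattice.activity,
                                           lattice.cve, params)
    lattice.age_steps[lattice.occupied] += 1

    candidates = np.argwhere((lattice.phenotype == ACTIVE)
                             & (lattice.cve >= state.division_threshold))
    if candidates.size == 0:
        return 0
    # increasing linear index ordering
    lin = np.ravel_multi_index(candidates.T, lattice.shape)
    candidates = candidates[np.argsort(lin)]
    u_grid = rng.uniform_grid(state.config.rng_seed, state.step, rng.DIVISION,
                              lattice.shape)
    divisions = 0
    for pt in map(tuple, candidates):
        if attempt_division(state, pt, tie_break_u=float(u_grid[pt])) is not None:
            divisions += 1
    return divisions
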