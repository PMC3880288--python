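"""Sprouting angiogenesis: TAF-directed tip migration, branching hotpoints,
vessel maturation and pruning.

Tips advance up the TAF gradient, one lattice step at a time, once their
accumulated growth (a pressure-boosted proliferation rate, in grid steps per
iteration) reaches one grid spacing.  Branching happens at "branching
hotpoints": vessel-adjacent voxels flagged with probability
min(1, k_BH * c^alpha_BH) from the local TAF concentration.  Segments age
each iteration and their radius follows a saturating age map; a tip that has
stalled for longer than the stall limit ages backwards, and any segment that
reaches age zero is pruned together with its distal subtree.  Vessels can
never occupy necrotic-cell voxels: segments caught inside the necrotic core
collapse (age set to zero) and are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .lattice import FACE_OFFSETS, NECROTIC
from .vessels import VesselNetwork

__all__ = [
    "AngioParams",
    "vessel_growth_rate",
    "branching_probability",
    "radius_map",
    "age_and_radius_update",
    "prune_vessels",
    "tip_migration_step",
    "sample_branching_hotpoints",
    "apply_branching",
    "step_angiogenesis",
]


@dataclass(frozen=True)
class AngioParams:
    k_BH: float = 0.3e-3
    alpha_BH: float = 1.3
    k_AR1: float = 1.0
    k_AR2: float = 500.0
    R_max: float = 1e-5          # m
    g1_normal: float = 0.1       # baseline tip advance, grid steps/iteration
    g1_tumor: float = 1.0 / 3.0
    g2_fraction: float = 1.0     # pressure boost amplitude relative to g1
    p_v: float = 30.0            # mmHg
    stall_limit: int = 10
    sprout_age_init: float = 1.0
    branch_min_age: float = 0.0  # immature sprouts do not branch

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "AngioParams":
        return cls(
            k_BH=config.k_BH,
            alpha_BH=config.alpha_BH,
            k_AR1=config.k_AR1,
            k_AR2=config.k_AR2,
            R_max=config.vessel_R_max,
            g1_normal=config.tip_rate_normal,
            g1_tumor=config.tip_rate_tumor,
            g2_fraction=config.g2_fraction,
            p_v=config.p_v,
            stall_limit=config.stall_limit,
            sprout_age_init=config.sprout_age_init,
            branch_min_age=config.branch_min_age,
        )


def vessel_growth_rate(delta_p_wall: float, params: AngioParams,
                       in_tumor: bool = False) -> float:
    """Endothelial proliferation rate (grid steps per iteration).

    rate = g1 + g2 * max(delta_p, 0) / p_v with g2 = g2_fraction * g1; the
    baseline g1 is higher inside tumor tissue, and negative transmural heads
    fall back to the baseline floor.
    """
    g1 = params.g1_tumor if in_tumor else params.g1_normal
    g2 = params.g2_fraction * g1
    return g1 + g2 * max(float(delta_p_wall), 0.0) / params.p_v


def branching_probability(taf_local, params: AngioParams):
    """Branching-hotpoint probability min(1, k_BH * c^alpha_BH)."""
    c = np.asarray(taf_local, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("TAF concentration must be non-negative")
    p = np.minimum(1.0, params.k_BH * np.power(c, params.alpha_BH,
                                               where=c > 0,
                                               out=np.zeros_like(c)))
    return p if p.ndim else float(p)


def radius_map(age, config_or_params) -> float | np.ndarray:
    """Saturating vessel radius from endothelial age:
    R = k_AR1 * R_max * Age / (k_AR2 + Age), zero at and below age zero."""
    cp = config_or_params
    r_max = cp.vessel_R_max if isinstance(cp, SimulationConfig) else cp.R_max
    a = np.clip(np.asarray(age, dtype=np.float64), 0.0, None)
    r = cp.k_AR1 * r_max * a / (cp.k_AR2 + a)
    return r if r.ndim else float(r)


def age_and_radius_update(network: VesselNetwork, params: AngioParams,
                          dt: float = 1.0) -> VesselNetwork:
    """Advance segment ages by one iteration and refresh radii.

    Tips stalled beyond the stall limit have lost perfusion pressure and age
    backwards; everything else matures.  Radii follow the age map, so they
    are monotone in age and saturate at k_AR1 * R_max.
    """
    for seg in network.segments.values():
        if seg.is_tip and seg.stall > params.stall_limit:
            seg.age -= dt
        else:
            seg.age += dt
        seg.radius = radius_map(seg.age, params)
    return network


def prune_vessels(network: VesselNetwork) -> VesselNetwork:
    """Remove every segment with age <= 0 along with its distal subtree."""
    while True:
        doomed = [sid for sid, s in sorted(network.segments.items())
                  if s.age <= 0.0]
        if not doomed:
            return network
        for sid in doomed:
            if sid in network.segments:
                network.remove_subtree(sid)


def _admissible_moves(state, pos):
    nx, ny, nz = state.lattice.shape
    taf = state.fields["taf"].values
    here = taf[pos]
    out = []
    for dx, dy, dz in FACE_OFFSETS:
        nb = (pos[0] + dx, pos[1] + dy, pos[2] + dz)
        if not (0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz):
            continue
        if state.vessels.occupies(nb):
            continue
        if state.lattice.phenotype[nb] == NECROTIC:
            continue
        out.append((nb, max(taf[nb] - here, 0.0)))
    return out


def tip_migration_step(state, tip_id: int, u: float):
    """Move one tip a single lattice step, or stall.

    Direction weights are the positive directional TAF derivatives over the
    six face neighbors; when every derivative is non-positive the tip samples
    uniformly among admissible voxels (necrotic and vessel-occupied voxels
    are never admissible).  Returns the new tip's segment id, or None on
    stall.
    """
    params = state.angio_params
    net = state.vessels
    seg = net.segments[tip_id]
    moves = _admissible_moves(state, seg.pos)
    if not moves:
        seg.stall += 1
        return None
    weights = np.array([m[1] for m in moves])
    total = weights.sum()
    if total <= 0.0:
        probs = np.full(len(moves), 1.0 / len(moves))
    else:
        probs = weights / total
    idx = min(int(np.searchsorted(np.cumsum(probs), u, side="right")),
              len(moves) - 1)
    target = moves[idx][0]
    child = net.add_segment(target, parent=tip_id,
                            age=params.sprout_age_init,
                            radius=radius_map(params.sprout_age_init, params),
                            is_tip=True)
    new = net.segments[child]
    new.acc = seg.acc - 1.0
    seg.is_tip = False
    seg.stall = 0
    seg.acc = 0.0
    return child


def sample_branching_hotpoints(state, u_grid: np.ndarray):
    """Per-step branching hotpoints adjacent to existing vessels.

    Every vessel-adjacent free voxel is flagged with its TAF-dependent
    branching probability using the voxel-indexed uniforms ``u_grid``.
    Returns [(segment id, hotpoint voxel), ...] with at most one hotpoint
    per segment (the flagged neighbor with the lowest linear index).
    """
    params = state.angio_params
    net = state.vessels
    taf = state.fields["taf"].values
    nx, ny, nz = state.lattice.shape
    # one vectorized Bernoulli per voxel; per-segment scan only consults it
    flagged = u_grid < np.minimum(
        1.0, params.k_BH * np.power(np.clip(taf, 0.0, None), params.alpha_BH))
    if not flagged.any():
        return []
    out = []
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        if seg.age < params.branch_min_age:
            continue
        best = None
        for dx, dy, dz in FACE_OFFSETS:
            nb = (seg.pos[0] + dx, seg.pos[1] + dy, seg.pos[2] + dz)
            if not (0 <= nb[0] < nx and 0 <= nb[1] < ny and 0 <= nb[2] < nz):
                continue
            if not flagged[nb]:
                continue
            if net.occupies(nb) or state.lattice.phenotype[nb] == NECROTIC:
                continue
            lin = (nb[0] * ny + nb[1]) * nz + nb[2]
            if best is None or lin < best[0]:
                best = (lin, nb)
        if best is not None:
            out.append((sid, best[1]))
    return out


def apply_branching(state, hotpoints) -> int:
    """Spawn one new tip per (segment, hotpoint) pair; returns branches made."""
    params = state.angio_params
    net = state.vessels
    made = 0
    for sid, voxel in hotpoints:
        if sid not in net.segments or net.occupies(voxel):
            continue
        if state.lattice.phenotype[voxel] == NECROTIC:
            continue
        net.add_segment(voxel, parent=sid, age=params.sprout_age_init,
                        radius=radius_map(params.sprout_age_init, params),
                        is_tip=True)
        made += 1
    return made


def step_angiogenesis(state) -> None:
    """One angiogenesis iteration: collapse, migrate, branch, mature, prune."""
    from . import rng

    net = state.vessels
    if not net.segments:
        return
    params = state.angio_params
    cfg = state.config
    lattice = state.lattice
    p = state.pressure.values

    # vessels trapped in the necrotic core collapse
    for seg in net.segments.values():
        if lattice.phenotype[seg.pos] == NECROTIC:
            seg.age = 0.0
    prune_vessels(net)
    if not net.segments:
        return

    # in-tumor mask: the tip voxel or any face neighbor holds a tumor cell
    occ = lattice.occupied
    in_tumor = occ.copy()
    for axis in range(3):
        for shift in (1, -1):
            in_tumor |= np.roll(occ, shift, axis=axis)

    u_tip = rng.uniform_grid(cfg.rng_seed, state.step, rng.TIP, lattice.shape)
    for tip_id in net.tips:
        seg = net.segments.get(tip_id)
        if seg is None or not seg.is_tip:
            continue
        dp = cfg.p_v - p[seg.pos]
        seg.acc += vessel_growth_rate(dp, params, in_tumor=bool(in_tumor[seg.pos]))
        if seg.acc >= 1.0:
            tip_migration_step(state, tip_id, float(u_tip[seg.pos]))

    u_branch = rng.uniform_grid(cfg.rng_seed, state.step, rng.BRANCH,
                                lattice.shape)
    apply_branching(state, sample_branching_hotpoints(state, u_branch))

    age_and_radius_update(net, params)
    prune_vessels(net)
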