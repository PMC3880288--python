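"""Explicit finite-difference transport of the continuum species.

Each species obeys a diffusion-convection-reaction equation

    dphi/dt = D lap(phi) - div(u phi) + source - sink

advanced with a forward-Euler step: 7-point Laplacian, first-order upwind
convection in flux form, Dirichlet values re-imposed on all six faces after
every step, and negative values clipped to zero (with the clipped mass
logged on the field).  The explicit step is only taken within its stability
bound; :func:`stability_substeps` chooses the sub-step count.

Source and sink fields are built from the simulation state: vascular exchange
is weighted by the local vessel radius, g(R) = R / R_sat, and by the positive
transmural pressure head, h = max(p_v - p_i, 0) / p_v, so perfusion shuts
down wherever interstitial pressure exceeds vascular pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import StabilityError
from .fields import ScalarField
from .lattice import NECROTIC

__all__ = [
    "TransportSpec",
    "stability_substeps",
    "advance_scalar",
    "advance",
    "vessel_exchange_weights",
    "oxygen_source",
    "oxygen_sink",
    "co2_source",
    "co2_sink",
    "taf_source",
    "taf_removal",
]


@dataclass
class TransportSpec:
    """Coefficients for one species' transport step.

    ``source`` and ``sink`` are absolute rate fields in normalized units per
    second (or None); both are held frozen across sub-steps of one iteration.
    """
    D: float                      # m^2/s
    bc_value: float
    source: np.ndarray | None = None
    sink: np.ndarray | None = None


def _max_abs_velocity_sum(velocity) -> float:
    if velocity is None:
        return 0.0
    return float(sum(np.abs(u).max() for u in velocity))


def stability_substeps(spec: TransportSpec | float, dt: float, spacing: float,
                       velocity=None) -> int:
    """Smallest m with (dt/m) * (6 D / h^2 + sum|u|_max / h) <= 1/2."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    D = spec.D if isinstance(spec, TransportSpec) else float(spec)
    coef = dt * (6.0 * D / spacing ** 2
                 + _max_abs_velocity_sum(velocity) / spacing)
    return max(1, math.ceil(coef / 0.5 - 1e-12))


def _upwind_divergence(v: np.ndarray, velocity, spacing: float) -> np.ndarray:
    """div(u phi) on the interior, first-order upwind with face velocities."""
    div = np.zeros_like(v)
    inner = [slice(1, -1)] * 3
    for axis in range(3):
        u = velocity[axis]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        u_face = 0.5 * (u[tuple(lo)] + u[tuple(hi)])
        flux = np.where(u_face >= 0.0, u_face * v[tuple(lo)],
                        u_face * v[tuple(hi)])
        dflux_lo = [slice(1, -1)] * 3
        dflux_hi = [slice(1, -1)] * 3
        dflux_lo[axis] = slice(None, -1)
        dflux_hi[axis] = slice(1, None)
        target = list(inner)
        target[axis] = slice(1, -1)
        div[tuple(target)] += (flux[tuple(dflux_hi)]
                               - flux[tuple(dflux_lo)]) / spacing
    return div


def advance_scalar(field: ScalarField, spec: TransportSpec, dt: float,
                   spacing: float, velocity=None,
                   _usum: float | None = None) -> ScalarField:
    """One explicit Euler step; raises StabilityError beyond the CFL bound."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if _usum is None:
        _usum = _max_abs_velocity_sum(velocity)
    coef = dt * (6.0 * spec.D / spacing ** 2 + _usum / spacing)
    if coef > 0.5 + 1e-9:
        raise StabilityError(
            f"explicit step unstable (coefficient {coef:.3g} > 0.5); "
            "use stability_substeps / advance")

    v = field.values
    inner = (slice(1, -1),) * 3
    rhs = np.zeros_like(v[inner])
    if spec.D > 0.0:
        rhs += v[2:, 1:-1, 1:-1]
        rhs += v[:-2, 1:-1, 1:-1]
        rhs += v[1:-1, 2:, 1:-1]
        rhs += v[1:-1, :-2, 1:-1]
        rhs += v[1:-1, 1:-1, 2:]
        rhs += v[1:-1, 1:-1, :-2]
        rhs -= 6.0 * v[inner]
        rhs *= spec.D / spacing ** 2
    # convection is skipped when the fluid moves less than 1e-4 voxel per
    # step (Darcy speeds at tabulated conductivities are ~1e-13 m/s, i.e.
    # well under one voxel of total displacement per simulated run)
    if velocity is not None and _usum * dt / spacing > 1e-4:
        rhs -= _upwind_divergence(v, velocity, spacing)[inner]
    if spec.source is not None:
        rhs += spec.source[inner]
    if spec.sink is not None:
        rhs -= spec.sink[inner]
    rhs *= dt
    v[inner] += rhs
    field.apply_dirichlet()
    field.clip_negative()
    if not np.isfinite(v.sum()):
        raise StabilityError(f"non-finite values in {field.species} field")
    return field


def advance(field: ScalarField, spec: TransportSpec, dt: float, spacing: float,
            velocity=None) -> ScalarField:
    """Advance one full iteration, sub-stepping to respect stability."""
    usum = _max_abs_velocity_sum(velocity)
    m = stability_substeps(spec, dt, spacing, velocity)
    sub = dt / m
    for _ in range(m):
        advance_scalar(field, spec, sub, spacing, velocity, _usum=usum)
    return field


# ---------------------------------------------------------------------------
# source/sink builders
# ---------------------------------------------------------------------------

def vessel_exchange_weights(state) -> tuple[np.ndarray, np.ndarray]:
    """(g, h) vascular exchange weight fields, zero off-vessel.

    g is the radius weight R / (k_AR1 * R_sat) in [0, 1]; h is the clamped
    transmural pressure head max(p_v - p_i, 0) / p_v.
    """
    cfg = state.config
    shape = state.lattice.shape
    radius = state.vessels.radius_grid(shape)
    r_sat = cfg.k_AR1 * cfg.vessel_R_max
    g = np.clip(radius / r_sat, 0.0, 1.0)
    on_vessel = radius > 0.0
    h = np.where(on_vessel,
                 np.clip(cfg.p_v - state.pressure.values, 0.0, None) / cfg.p_v,
                 0.0)
    g[~on_vessel] = 0.0
    return g, h


def oxygen_source(state) -> np.ndarray:
    """Oxygen supply by perfused vessels, normalized units per second."""
    cfg = state.config
    g, h = vessel_exchange_weights(state)
    return (cfg.rho_n0 / cfg.n0) * g * h


def oxygen_sink(state) -> np.ndarray:
    """Activity-proportional oxygen consumption at cell voxels."""
    cfg = state.config
    n = state.fields["oxygen"].values
    return cfg.lambda_n0 * state.lattice.activity * n * state.lattice.occupied


def co2_source(state) -> np.ndarray:
    """CO2 secretion proportional to cell activity."""
    cfg = state.config
    return (cfg.rho_w0 / cfg.w0) * state.lattice.activity * state.lattice.occupied


def co2_sink(state) -> np.ndarray:
    """CO2 uptake by perfused vessels."""
    cfg = state.config
    g, h = vessel_exchange_weights(state)
    w = state.fields["co2"].values
    return cfg.lambda_w0 * g * h * w


def taf_source(state) -> np.ndarray:
    """Hypoxia-weighted TAF secretion by live tumor cells.

    The secretion weight s(n) = max(0, 1 - n / n_threshold) vanishes at full
    oxygenation and saturates at 1 in anoxia, so TAF originates from hypoxic
    (typically quiescent) tumor regions.
    """
    cfg = state.config
    n = state.fields["oxygen"].values
    s = np.clip(1.0 - n / cfg.taf_oxygen_threshold, 0.0, 1.0)
    live = state.lattice.occupied & (state.lattice.phenotype != NECROTIC)
    return (cfg.rho_c0 / cfg.c0) * s * live


def taf_removal(state) -> np.ndarray:
    """TAF clearance, suppressed in high-pressure regions.

    r(p) = p_ref / (p_ref + max(p, 0)) decreases with pressure and equals 1 at
    zero pressure.  The tabulated clearance rate is zero, so this term is off
    by default.
    """
    cfg = state.config
    if cfg.lambda_c0 == 0.0:
        return np.zeros(state.lattice.shape)
    p = state.pressure.values
    r = cfg.taf_pressure_ref / (cfg.taf_pressure_ref + np.clip(p, 0.0, None))
    return cfg.lambda_c0 * r * state.fields["taf"].values
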