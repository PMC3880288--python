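"""Drug delivery and pharmacodynamics.

Drug enters the interstitium across the walls of neo-vessels.  The
transvascular fluid flux per unit tissue volume follows Starling's law,

    J_v = L_p (S/V) (p_v - p_i - sigma_avg (pi_v - pi_e)),

with the exchange surface per unit volume S/V computed from the local vessel
radius (a cylinder through the voxel: 2 pi R h / h^3).  The transmural Peclet
number Pe = J_v (1 - sigma_f) / (P_perm S/V) partitions exchange between
convection and diffusion; the diffusive (Patlak) term carries the factor
Pe / (e^Pe - 1), continuous at Pe = 0.  Inside the tissue the drug diffuses,
convects with the Darcy flow, is taken up by cells linearly in their
activity, and decays naturally.  Plasma concentration is a constant infusion
level from the dosing schedule; net tissue-to-blood exchange is clipped off
by default (no washout through tumor vessels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .errors import ConfigError

__all__ = [
    "DrugParams",
    "surface_per_volume",
    "transvascular_fluid_flux",
    "peclet_number",
    "patlak_factor",
    "drug_source",
    "drug_sink",
    "dosing_schedule",
    "apply_plasma_saturation",
]


@dataclass(frozen=True)
class DrugParams:
    D_d: float = 1.5e-14
    lambda_d0: float = 2.5e-7
    lambda_d2: float = 1e-8
    L_p: float = 2.8e-9
    P_perm: float = 1.49e-9
    sigma_avg: float = 0.82
    sigma_f: float = 0.1
    pi_v: float = 0.3546
    pi_e: float = 0.2667
    p_v: float = 30.0
    d0: float = 2.13
    drug_start_day: float = 40.0
    drug_dose: float = 0.0

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "DrugParams":
        return cls(
            D_d=config.D_d,
            lambda_d0=config.lambda_d0,
            lambda_d2=config.lambda_d2,
            L_p=config.L_p,
            P_perm=config.P_perm,
            sigma_avg=config.sigma_avg,
            sigma_f=config.sigma_f,
            pi_v=config.pi_v,
            pi_e=config.pi_e,
            p_v=config.p_v,
            d0=config.d0,
            drug_start_day=config.drug_start_day,
            drug_dose=config.drug_dose,
        )


def surface_per_volume(radius, spacing: float):
    """Vessel exchange surface per unit tissue volume, S/V = 2 pi R / h^2."""
    r = np.asarray(radius, dtype=np.float64)
    sv = 2.0 * np.pi * r / spacing ** 2
    return sv if sv.ndim else float(sv)


def transvascular_fluid_flux(p_v: float, p_i_local, radius, spacing: float,
                             params: DrugParams):
    """Starling volumetric flow out of the vasculature per unit volume (1/s).

    Negative values mean reabsorption; the sign is preserved here and only
    handled downstream.
    """
    sv = surface_per_volume(radius, spacing)
    pi_jump = params.sigma_avg * (params.pi_v - params.pi_e)
    jv = params.L_p * sv * (p_v - np.asarray(p_i_local, dtype=np.float64)
                            - pi_jump)
    return jv if np.ndim(jv) else float(jv)


def peclet_number(j_v, radius, spacing: float, params: DrugParams):
    """Transmural Peclet number Pe = J_v (1 - sigma_f) / (P_perm S/V)."""
    if params.P_perm <= 0:
        raise ConfigError("vascular permeability P_perm must be positive")
    sv = np.asarray(surface_per_volume(radius, spacing), dtype=np.float64)
    jv = np.asarray(j_v, dtype=np.float64)
    out = np.zeros(np.broadcast_shapes(jv.shape, sv.shape))
    pos = sv > 0
    out = np.divide(jv * (1.0 - params.sigma_f), params.P_perm * sv,
                    out=out, where=pos)
    return out if out.ndim else float(out)


def patlak_factor(pe):
    """Pe / (e^Pe - 1) with its continuous limit 1 at Pe = 0."""
    p = np.asarray(pe, dtype=np.float64)
    small = np.abs(p) < 1e-8
    denom = np.where(small, 1.0, np.expm1(p))
    out = np.where(small, 1.0 - p / 2.0, p / denom)
    return out if out.ndim else float(out)


def dosing_schedule(config: SimulationConfig, day: float) -> float:
    """Plasma drug concentration (mol/m^3) at the given simulation day.

    Zero before the treatment start day, then a constant infusion level.
    Time-varying plasma profiles can be modeled by subclassing or by
    sweeping ``drug_dose``.
    """
    if day < 0:
        raise ValueError("day must be non-negative")
    if config.drug_dose < 0:
        raise ConfigError("drug_dose must be non-negative")
    return config.drug_dose if day >= config.drug_start_day else 0.0


def drug_source(state, params: DrugParams | None = None) -> np.ndarray:
    """Transvascular drug supply field, normalized units per second.

    Nonzero only at vessel voxels while dosing is active: convective
    extravasation (1 - sigma_f) J_v d_plasma plus Patlak-modulated diffusive
    exchange P_perm (S/V) (d_plasma - d_i) Pe/(e^Pe - 1).  Net negative
    exchange (tissue to blood) is clipped to zero and logged on the state.
    """
    cfg = state.config
    if params is None:
        params = DrugParams.from_config(cfg)
    shape = state.lattice.shape
    d_plasma_phys = dosing_schedule(cfg, state.day)
    if d_plasma_phys == 0.0:
        return np.zeros(shape)
    d_plasma = d_plasma_phys / params.d0

    radius = state.vessels.radius_grid(shape)
    on = radius > 0.0
    if not on.any():
        return np.zeros(shape)
    spacing = state.grid.spacing
    p_i = state.pressure.values
    d_local = state.fields["drug"].values

    jv = transvascular_fluid_flux(params.p_v, p_i[on], radius[on], spacing,
                                  params)
    pe = peclet_number(jv, radius[on], spacing, params)
    sv = surface_per_volume(radius[on], spacing)
    raw = ((1.0 - params.sigma_f) * jv * d_plasma
           + params.P_perm * sv * (d_plasma - d_local[on]) * patlak_factor(pe))
    clipped = np.clip(raw, 0.0, None)
    state.drug_source_clipped += float((clipped - raw).sum())
    out = np.zeros(shape)
    out[on] = clipped
    return out


def drug_sink(state, params: DrugParams | None = None) -> np.ndarray:
    """Cellular uptake lambda_d0 A d plus natural decay lambda_d2 d (1/s)."""
    cfg = state.config
    if params is None:
        params = DrugParams.from_config(cfg)
    d = state.fields["drug"].values
    uptake = params.lambda_d0 * state.lattice.activity * d * state.lattice.occupied
    return uptake + params.lambda_d2 * d


def apply_plasma_saturation(state) -> None:
    """Cap interstitial drug at vessel voxels at the plasma concentration.

    Filtration-driven extravasation cannot raise the local interstitial level
    above plasma; without this cap the convective term, which has no
    equilibrating back-flux, grows without bound.
    """
    cfg = state.config
    d_plasma = dosing_schedule(cfg, state.day) / cfg.d0
    if d_plasma <= 0.0:
        return
    on = state.vessels.occupancy_grid(state.lattice.shape)
    d = state.fields["drug"].values
    over = on & (d > d_plasma)
    if over.any():
        d[over] = d_plasma
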