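"""Simulation configuration.

Every model parameter has a physical default taken from the standard parameter
table of the underlying growth/angiogenesis model (diffusion coefficients in
m^2/s, supply rates in mol/(m^3 s), consumption rates in 1/s, pressures in
mmHg, concentrations in mol/m^3).  Concentration fields are evolved in units
normalized by the standard concentrations ``n0``, ``w0``, ``c0``, ``d0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError

__all__ = ["SimulationConfig", "ConfigError"]


@dataclass(frozen=True)
class SimulationConfig:
    # --- grid and clock -------------------------------------------------
    grid_points_per_axis: int = 200
    domain_edge: float = 0.01          # m; 1 cm^3 box at full scale
    steps_per_day: int = 33            # 1 day == 33 iterations
    total_days: float = 60.0
    rng_seed: int = 0
    K_neighborhood: int = 3            # half-width of pressure/density cubes

    # --- oxygen ---------------------------------------------------------
    D_n: float = 8e-14                 # m^2/s, oxygen diffusion
    rho_n0: float = 6.8e-4             # mol/(m^3 s), oxygen supply rate
    lambda_n0: float = 3e-5            # 1/s, oxygen consumption rate

    # --- carbon dioxide -------------------------------------------------
    D_w: float = 4e-14                 # m^2/s
    rho_w0: float = 1e-5               # mol/(m^3 s), CO2 secretion rate
    lambda_w0: float = 2.5e-5          # 1/s, CO2 consumption rate (vessels)

    # --- TAF ------------------------------------------------------------
    D_c: float = 1.2e-13               # m^2/s
    rho_c0: float = 2e-9               # mol/(m^3 s), TAF secretion rate
    lambda_c0: float = 0.0             # 1/s, TAF consumption rate

    # --- drug -----------------------------------------------------------
    D_d: float = 1.5e-14               # m^2/s
    lambda_d0: float = 2.5e-7          # 1/s, drug consumption by cells
    lambda_d2: float = 1e-8            # 1/s, drug natural decay

    # --- angiogenesis constants ----------------------------------------
    k_BH: float = 0.3e-3               # branching-hotpoint constant
    alpha_BH: float = 1.3              # branching-hotpoint exponent
    k_AR1: float = 1.0                 # vessel radius constant
    k_AR2: float = 500.0               # vessel radius constant (age scale)

    # --- CVE ------------------------------------------------------------
    k_active: float = 1.0              # CVE addition rate, per step
    k_quiescent: float = 0.1           # CVE housekeeping drain, per step

    # --- fluid / transvascular exchange ---------------------------------
    k_hydraulic: float = 4.5e-15       # cm^2/(mmHg s), interstitium conductivity
    L_p: float = 2.8e-9                # m/(mmHg s), microvascular wall conductivity
    P_perm: float = 1.49e-9            # m/s, vascular permeability
    sigma_avg: float = 0.82            # osmotic reflection coefficient (Starling)
    sigma_f: float = 0.1               # osmotic reflection coefficient (solute drag)
    pi_v: float = 0.3546               # mmHg, plasma osmotic pressure
    pi_e: float = 0.2667               # mmHg, interstitial osmotic pressure
    p_v: float = 30.0                  # mmHg, capillary/vascular pressure
    p_tumor: float = 60.0              # mmHg, dense-core tumor pressure target
    d_i: float = 1.0                   # mol/m^3, reference interstitial drug conc.

    # --- standard concentrations (normalization scales) -----------------
    n0: float = 8.4                    # mol/m^3
    w0: float = 10.5                   # mol/m^3
    c0: float = 4.3e-4                 # standard TAF concentration (printed scale)
    d0: float = 2.13                   # mol/m^3

    # --- dosing ---------------------------------------------------------
    drug_start_day: float = 40.0
    drug_dose: float = 0.0             # mol/m^3 plasma concentration; 0 = untreated

    # --- initial / boundary field values (normalized) -------------------
    n_init: float = 1.0
    w_init: float = 1.0
    c_init: float = 1.0
    d_init: float = 0.0

    # --- pressure-kernel knobs ------------------------------------------
    lam_min: float = 0.75              # kernel width at theta=0, index units
    lam_max: float = 2.0               # kernel width at theta=1, index units
    vtp_amplitude: float = 6.0         # mmHg; dense-vasculature pressure target
    pressure_every: int = 1            # recompute pressure every k steps

    # --- cell-rule knobs ------------------------------------------------
    activity_threshold: float = 0.5
    K_n_half: float = 0.25             # oxygen half-saturation in activity
    K_w_half: float = 1.25             # CO2 inhibition constant in activity
    oxygen_hill: float = 2.0           # Hill exponent of the oxygen term
    co2_hill: float = 8.0              # Hill exponent of the waste term
    hill_coefficient: float = 6.0
    hill_halfmax: float = 0.45
    hill_max_fraction: float = 0.76    # hill(A=1) = fraction * k_active
    k_drug: float = 0.5                # CVE damage per unit normalized drug, per step
    cve_division_threshold: Optional[float] = None  # None -> auto-calibrated

    # --- TAF response knobs ---------------------------------------------
    taf_oxygen_threshold: float = 1.0  # s(n) = max(0, 1 - n/threshold)
    taf_pressure_ref: float = 30.0     # r(p) = ref / (ref + max(p, 0))

    # --- angiogenesis knobs ---------------------------------------------
    angiogenesis_enabled: bool = True
    tip_rate_normal: float = 0.1       # grid steps per iteration outside tumor
    tip_rate_tumor: float = 1.0 / 3.0  # grid steps per iteration inside tumor
    g2_fraction: float = 1.0           # g2 = g2_fraction * g1 in the growth law
    stall_limit: int = 10              # stalled steps before a tip ages backwards
    sprout_age_init: float = 1.0       # iterations
    branch_min_age: float = 0.0        # segments younger than this cannot branch
    vessel_R_max: float = 1e-5         # m, saturation radius scale

    # --- parent vasculature fixture -------------------------------------
    parent_vessel: str = "none"        # none | single_axis | face_grid
    parent_vessel_offset: int = 12     # index offset from the tumor center
    parent_vessel_age: float = 1000.0  # iterations; a mature parent vessel
    parent_vessel_count: int = 5       # vessels in the face_grid comb

    def __post_init__(self) -> None:
        if self.grid_points_per_axis < 8:
            raise ConfigError(
                f"grid_points_per_axis must be >= 8, got {self.grid_points_per_axis}"
            )
        if self.steps_per_day < 1:
            raise ConfigError(f"steps_per_day must be >= 1, got {self.steps_per_day}")
        if self.domain_edge <= 0:
            raise ConfigError(f"domain_edge must be > 0, got {self.domain_edge}")
        if self.total_days < 0:
            raise ConfigError(f"total_days must be >= 0, got {self.total_days}")
        if self.K_neighborhood < 1:
            raise ConfigError(f"K_neighborhood must be >= 1, got {self.K_neighborhood}")
        for name in ("D_n", "D_w", "D_c", "D_d"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n0", "w0", "c0", "d0"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("sigma_avg", "sigma_f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.activity_threshold < 1.0:
            raise ConfigError(
                f"activity_threshold must lie in (0, 1), got {self.activity_threshold}"
            )
        if self.drug_dose < 0:
            raise ConfigError(f"drug_dose must be >= 0, got {self.drug_dose}")
        if self.lam_min <= 0 or self.lam_max <= 0:
            raise ConfigError("kernel widths lam_min/lam_max must be > 0")
        if self.parent_vessel not in ("none", "single_axis", "face_grid"):
            raise ConfigError(f"unknown parent_vessel style {self.parent_vessel!r}")
        if self.pressure_every < 1:
            raise ConfigError("pressure_every must be >= 1")

    # --- derived quantities ---------------------------------------------
    @property
    def spacing(self) -> float:
        """Lattice spacing in meters."""
        return self.domain_edge / self.grid_points_per_axis

    @property
    def dt_seconds(self) -> float:
        """Physical duration of one iteration."""
        return 86400.0 / self.steps_per_day

    @property
    def n_steps(self) -> int:
        return int(round(self.total_days * self.steps_per_day))

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.grid_points_per_axis
        return (n, n, n)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # --- file round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)
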