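"""Growth-pressurization model (GPM).

Interstitial pressure is the sum of cell-induced tumor pressure (CTP) and
vasculature-induced tumor pressure (VTP).  Each is a Gaussian-like kernel sum:
at grid point X0,

    P(X0) = sum_{sources X_i, |X_i - X0|_inf <= K}
            rho(theta(X0)) * exp(-|X_i - X0|^2 / (2 lambda(theta(X0))^2))

with density feedback through the local occupancy fraction theta evaluated at
the field point X0 (not at each source).  The shipped maps are
rho(theta) = rho_max * theta and lambda(theta) = lam_min + (lam_max - lam_min)
* theta; rho_max is calibrated so a fully dense core reaches the configured
dense-core pressure.  Interstitial fluid moves down pressure gradients by
Darcy's law, u = -k grad p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .errors import GridError
from .fields import ScalarField

__all__ = [
    "PressureKernelParams",
    "calibrate_rho_max",
    "gaussian_kernel_field",
    "ctp_field",
    "vtp_field",
    "combined_pressure",
    "darcy_velocity",
]


@dataclass(frozen=True)
class PressureKernelParams:
    rho_max: float   # mmHg at theta = 1
    lam_min: float   # kernel width (index units) at theta = 0
    lam_max: float   # kernel width (index units) at theta = 1
    K: int           # cube half-width

    def rho(self, theta):
        return self.rho_max * theta

    def lam(self, theta):
        return self.lam_min + (self.lam_max - self.lam_min) * theta


def calibrate_rho_max(p_target: float, lam_max: float, K: int) -> float:
    """Amplitude for which a fully occupied K-cube produces ``p_target``.

    At theta = 1 the kernel sum over the full cube factorizes into the cube of
    a 1D Gaussian sum, so rho_max = p_target / S^3.
    """
    k = np.arange(-K, K + 1, dtype=float)
    s1 = np.exp(-(k ** 2) / (2.0 * lam_max ** 2)).sum()
    return float(p_target / s1 ** 3)


def tumor_kernel_params(config: SimulationConfig) -> PressureKernelParams:
    return PressureKernelParams(
        rho_max=calibrate_rho_max(config.p_tumor, config.lam_max,
                                  config.K_neighborhood),
        lam_min=config.lam_min,
        lam_max=config.lam_max,
        K=config.K_neighborhood,
    )


def vascular_kernel_params(config: SimulationConfig) -> PressureKernelParams:
    return PressureKernelParams(
        rho_max=calibrate_rho_max(config.vtp_amplitude, config.lam_max,
                                  config.K_neighborhood),
        lam_min=config.lam_min,
        lam_max=config.lam_max,
        K=config.K_neighborhood,
    )


def _squared_distance_groups(K: int) -> dict[int, list[tuple[int, int, int]]]:
    groups: dict[int, list[tuple[int, int, int]]] = {}
    for dx in range(-K, K + 1):
        for dy in range(-K, K + 1):
            for dz in range(-K, K + 1):
                groups.setdefault(dx * dx + dy * dy + dz * dz, []).append(
                    (dx, dy, dz))
    return groups


def gaussian_kernel_field(occupancy: np.ndarray,
                          params: PressureKernelParams) -> np.ndarray:
    """Kernel pressure field from a boolean source-occupancy grid.

    Sources are grouped by squared distance to the field point; each group's
    occupancy count is obtained by shifted adds restricted to the bounding box
    of the sources (outside of which the field is exactly zero), and the
    Gaussian weight is applied with the field point's own theta-dependent
    width.  Identical, to rounding, to the brute-force pairwise sum.
    """
    occ = np.asarray(occupancy)
    shape = occ.shape
    out = np.zeros(shape, dtype=np.float64)
    pts = np.argwhere(occ)
    if pts.size == 0:
        return out
    K = params.K
    lo = np.maximum(pts.min(axis=0) - K, 0)
    hi = np.minimum(pts.max(axis=0) + K, np.array(shape) - 1)
    box = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    sub = occ[box].astype(np.float64)
    padded = np.pad(sub, K)
    bshape = sub.shape

    groups = _squared_distance_groups(K)
    s_values = sorted(groups)
    counts = np.zeros((len(s_values),) + bshape, dtype=np.float64)
    for si, s in enumerate(s_values):
        acc = counts[si]
        for dx, dy, dz in groups[s]:
            acc += padded[K + dx: K + dx + bshape[0],
                          K + dy: K + dy + bshape[1],
                          K + dz: K + dz + bshape[2]]

    total = counts.sum(axis=0)
    theta = total / float((2 * K + 1) ** 3)
    lam = params.lam(theta)
    inv = 1.0 / (2.0 * lam * lam)
    acc = np.zeros(bshape, dtype=np.float64)
    for si, s in enumerate(s_values):
        if s == 0:
            acc += counts[si]
        else:
            acc += counts[si] * np.exp(-s * inv)
    out[box] = params.rho(theta) * acc
    return out


def ctp_field(state, params: PressureKernelParams | None = None) -> ScalarField:
    """Cell-induced tumor pressure (mmHg) from all tumor cells."""
    if params is None:
        params = tumor_kernel_params(state.config)
    values = gaussian_kernel_field(state.lattice.occupied, params)
    return ScalarField(values, boundary_value=0.0, species="pressure")


def vtp_field(state, params: PressureKernelParams | None = None) -> ScalarField:
    """Vasculature-induced tumor pressure (mmHg) from endothelial cells."""
    if params is None:
        params = vascular_kernel_params(state.config)
    occ = state.vessels.occupancy_grid(state.lattice.shape)
    values = gaussian_kernel_field(occ, params)
    return ScalarField(values, boundary_value=0.0, species="pressure")


def combined_pressure(ctp: ScalarField, vtp: ScalarField) -> ScalarField:
    """Pointwise sum p = CTP + VTP."""
    if ctp.shape != vtp.shape:
        raise GridError(f"pressure grids differ: {ctp.shape} vs {vtp.shape}")
    return ScalarField(ctp.values + vtp.values, boundary_value=0.0,
                       species="pressure")


def darcy_velocity(pressure: np.ndarray | ScalarField, k_hydraulic: float,
                   spacing: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interstitial fluid velocity u = -k grad p.

    ``k_hydraulic`` is in cm^2/(mmHg s) as tabulated and is converted to
    m^2/(mmHg s); with pressure in mmHg and spacing in m the result is m/s.
    Central differences in the interior, one-sided at the boundary.
    """
    p = pressure.values if isinstance(pressure, ScalarField) else pressure
    if not np.all(np.isfinite(p)):
        raise GridError("pressure field contains non-finite values")
    k = k_hydraulic * 1e-4  # cm^2 -> m^2
    gx, gy, gz = np.gradient(p, spacing)
    return (-k * gx, -k * gy, -k * gz)
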