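"""Run analytics: growth stages, morphology, parameter sensitivity."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import DomainError

__all__ = [
    "detect_growth_stages",
    "sphericity_metric",
    "sensitivity_scan",
    "SENSITIVITY_PARAMETERS",
    "SENSITIVITY_PERTURBATIONS",
]

STAGES = ("T1", "T2", "T3", "T4")


def detect_growth_stages(record: pd.DataFrame, r_exp: float = 0.30,
                         stasis_tol: float = 0.12, t4_tol: float = 0.10,
                         window_days: float = 1.0) -> dict:
    """Classify the total-cell-count curve into growth stages.

    Daily relative growth rates over a sliding window label each day:
    exponential growth (T1) when the relative rate is at least ``r_exp`` per
    day; stasis (T3) when it falls below ``stasis_tol`` per day; linear
    expansion (T2) in between.  After stasis has been seen, renewed growth of
    at least ``t4_tol`` marks secondary (vascular) growth T4.  The two
    tolerances are deliberately asymmetric: ``stasis_tol`` describes the
    downward crossing out of the expansion phase, ``t4_tol`` the
    re-acceleration out of stasis.  Returns per-day labels, the first day of
    each stage (None if absent) and the stage sequence.
    """
    if record["day"].iloc[-1] < 3:
        raise DomainError("record must cover at least 3 days")

    # count at the end of each whole day (the last row with day <= d)
    days_f = record["day"].to_numpy(dtype=float)
    totals = record["total"].to_numpy(dtype=float)
    days = np.arange(0, int(np.floor(days_f[-1] + 1e-9)) + 1)
    idx = np.searchsorted(days_f, days + 1e-9, side="right") - 1
    counts = totals[np.clip(idx, 0, len(totals) - 1)]
    w = max(1, int(round(window_days)))

    # the lag before growth is established is not stasis: classification
    # starts at the first completed doubling (or first growth, if the curve
    # never doubles; immediately, if it never grows - a flat curve is stasis)
    doubled = np.nonzero(counts >= 2 * counts[0])[0]
    grown = np.nonzero(counts > counts[0])[0]
    if doubled.size:
        first = int(doubled[0])
    elif grown.size:
        first = int(grown[0])
    else:
        first = 1

    labels: dict[int, str] = {}
    seen_stasis = False
    for i in range(max(1, first), len(days)):
        j = max(0, i - w)
        span = max(days[i] - days[j], 1)
        base = max(counts[j], 1.0)
        rate = (counts[i] - counts[j]) / base / span
        if abs(rate) < stasis_tol:
            label = "T3"
            seen_stasis = True
        elif seen_stasis:
            label = "T4" if rate >= t4_tol else "T3"
        elif rate >= r_exp:
            label = "T1"
        else:
            label = "T2"
        labels[int(days[i])] = label

    boundaries = {s: None for s in STAGES}
    sequence = []
    for day in sorted(labels):
        s = labels[day]
        if boundaries[s] is None:
            boundaries[s] = day
        if not sequence or sequence[-1] != s:
            sequence.append(s)
    return {"labels": labels, "boundaries": boundaries, "sequence": sequence}


def sphericity_metric(occupancy) -> float:
    """Discrete sphericity pi^(1/3) (6V)^(2/3) / A of the occupied region.

    V counts occupied voxels and A counts exposed voxel faces, both in voxel
    units; the metric approaches 1 from below for large discrete balls and
    drops toward 0 for dendritic shapes.
    """
    if hasattr(occupancy, "lattice"):  # a SimulationState
        occ = occupancy.lattice.occupied
    else:
        occ = np.asarray(getattr(occupancy, "occupied", occupancy), dtype=bool)
    V = int(occ.sum())
    if V == 0:
        raise DomainError("sphericity undefined for an empty tumor")
    shared = 0
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        shared += int((occ[tuple(lo)] & occ[tuple(hi)]).sum())
    area = 6 * V - 2 * shared
    return float(np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / area)


SENSITIVITY_PARAMETERS = ("rho_n0", "lambda_n0", "rho_w0", "lambda_w0",
                          "rho_c0", "lambda_d0", "lambda_d2")
SENSITIVITY_PERTURBATIONS = (-10.0, -1.0, -0.1, 0.1, 1.0, 10.0)
_SENSITIVITY_SPECIES = {"nutrient": "oxygen", "waste": "co2",
                        "taf": "taf", "drug": "drug"}


def sensitivity_scan(config: SimulationConfig,
                     parameters=SENSITIVITY_PARAMETERS,
                     perturbations=SENSITIVITY_PERTURBATIONS) -> pd.DataFrame:
    """One-at-a-time parameter sensitivity of the end-of-run field averages.

    For each (parameter, perturbation %) pair a full run with that single
    change (same seed) is compared to the shared baseline run; the table
    reports |mean - mean_baseline| / mean_baseline * 100 for the nutrient,
    waste, TAF and drug fields, averaged over the whole grid at the final
    step.
    """
    from .driver import run_simulation

    def end_means(cfg):
        state = run_simulation(cfg).state
        return {label: float(state.fields[species].values.mean())
                for label, species in _SENSITIVITY_SPECIES.items()}

    base = end_means(config)
    rows = []
    for name in parameters:
        default = getattr(config, name)
        for pct in perturbations:
            if pct == 0.0:
                perturbed = base.copy()
            else:
                cfg = dataclasses.replace(config,
                                          **{name: default * (1.0 + pct / 100.0)})
                perturbed = end_means(cfg)
            row = {"parameter": name, "perturbation_pct": pct}
            for label in _SENSITIVITY_SPECIES:
                b = base[label]
                row[label] = (abs(perturbed[label] - b) / b * 100.0
                              if b != 0.0 else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
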