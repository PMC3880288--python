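"""Continuum fields on the lattice."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError

SPECIES = ("pressure", "oxygen", "co2", "taf", "drug")


@dataclass
class ScalarField:
    """A 3D scalar field on the simulation grid.

    Concentration species are stored in units normalized by their standard
    concentration; pressure is stored in mmHg.  ``boundary_value`` is the
    Dirichlet value imposed on all six faces.  ``clipped_mass`` accumulates
    (in normalized units x voxels) whatever negative mass was clipped to keep
    concentrations physical.
    """

    values: np.ndarray
    boundary_value: float = 0.0
    species: str = "oxygen"
    clipped_mass: float = 0.0
    #: optional inhomogeneous Dirichlet data: {face: scalar or 2D array} with
    #: faces named x0, x1, y0, y1, z0, z1; overrides ``boundary_value``.
    face_values: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise GridError(f"field must be 3D, got ndim={self.values.ndim}")
        if self.species not in SPECIES:
            raise GridError(f"unknown species tag {self.species!r}")

    @classmethod
    def uniform(cls, shape, value: float, species: str,
                boundary_value: float | None = None) -> "ScalarField":
        bv = value if boundary_value is None else boundary_value
        return cls(np.full(shape, float(value)), boundary_value=bv, species=species)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    _FACES = {"x0": (0, slice(None), slice(None)),
              "x1": (-1, slice(None), slice(None)),
              "y0": (slice(None), 0, slice(None)),
              "y1": (slice(None), -1, slice(None)),
              "z0": (slice(None), slice(None), 0),
              "z1": (slice(None), slice(None), -1)}

    def apply_dirichlet(self) -> None:
        v = self.values
        for name, index in self._FACES.items():
            b = self.boundary_value
            if self.face_values is not None and name in self.face_values:
                b = self.face_values[name]
            v[index] = b

    def clip_negative(self) -> None:
        neg = self.values < 0.0
        if neg.any():
            self.clipped_mass += float(-self.values[neg].sum())
            self.values[neg] = 0.0

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.boundary_value,
                           self.species, self.clipped_mass,
                           None if self.face_values is None
                           else dict(self.face_values))
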