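"""Distance <-> FRET efficiency conversion and density transforms.

Two standard model families are covered by one parameterization

    E(r) = 1 / (1 + prefactor * (r / R0)^exponent):

the point-dipole Forster form (exponent 6, prefactor 1) and the empirical
restricted-dye form for conformationally heterogeneous proteins
(exponent 2.65, prefactor 0.975).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EfficiencyModel",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "transform_density",
]


@dataclass(frozen=True)
class EfficiencyModel:
    """E(r) = 1 / (1 + prefactor (r/R0)^exponent); R0 in A."""

    R0: float
    exponent: float = 6.0
    prefactor: float = 1.0

    def __post_init__(self) -> None:
        if not self.R0 > 0:
            raise ValueError("R0 must be > 0")
        if not self.exponent > 0:
            raise ValueError("exponent must be > 0")
        if not self.prefactor > 0:
            raise ValueError("prefactor must be > 0")

    @classmethod
    def forster(cls, R0: float) -> "EfficiencyModel":
        """Classical sixth-power point-dipole model."""
        return cls(R0=R0, exponent=6.0, prefactor=1.0)

    @classmethod
    def restricted_dye(cls, R0: float) -> "EfficiencyModel":
        """Inverse-2.65 model with prefactor 0.975 for heterogeneous proteins."""
        return cls(R0=R0, exponent=2.65, prefactor=0.975)

    def efficiency(self, r):
        return efficiency_from_distance(self, r)

    def distance(self, E):
        return distance_from_efficiency(self, E)

    def to_dict(self) -> dict:
        return {"R0": self.R0, "exponent": self.exponent, "prefactor": self.prefactor}

    @classmethod
    def from_dict(cls, d: dict) -> "EfficiencyModel":
        return cls(R0=d["R0"], exponent=d.get("exponent", 6.0),
                   prefactor=d.get("prefactor", 1.0))


def efficiency_from_distance(model: EfficiencyModel, r):
    """E(r); strictly decreasing in r, E(0) = 1."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("distance must be non-negative")
    out = 1.0 / (1.0 + model.prefactor * (r_arr / model.R0) ** model.exponent)
    return float(out) if np.ndim(r) == 0 else out


def distance_from_efficiency(model: EfficiencyModel, E):
    """Exact inverse r(E) = R0 ((1/E - 1)/prefactor)^(1/exponent) for E in (0,1)."""
    e_arr = np.asarray(E, dtype=float)
    if np.any((e_arr <= 0) | (e_arr >= 1)):
        raise ValueError("efficiency must lie strictly inside (0, 1)")
    out = model.R0 * ((1.0 / e_arr - 1.0) / model.prefactor) ** (1.0 / model.exponent)
    return float(out) if np.ndim(E) == 0 else out


def _abs_dr_dE(model: EfficiencyModel, E):
    """|dr/dE| evaluated analytically at efficiency E in (0,1)."""
    E = np.asarray(E, dtype=float)
    u = (1.0 / E - 1.0) / model.prefactor
    r = model.R0 * u ** (1.0 / model.exponent)
    # dr/dE = -(1/n) * r / (u * prefactor * E^2) * (1/E - 1)' ... simplified:
    return r / (model.exponent * E * (1.0 - E))


def transform_density(model: EfficiencyModel, grid, values, direction: str):
    """Change of variables for a 1D density between r- and E-space.

    Input is a (grid, values) pair normalized over its support; output is the
    transformed (grid, values) pair, again integrating to 1 up to quadrature
    error.  ``direction`` is ``"r_to_E"`` or ``"E_to_r"``.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if grid.shape != values.shape or grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid and values must be matching 1D arrays")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if direction == "r_to_E":
        E = efficiency_from_distance(model, grid)
        if E.max() > 1 - 1e-12 or E.min() < 1e-12:
            warnings.warn("density support touches E=0 or E=1; transform truncated",
                          RuntimeWarning, stacklevel=2)
        jac = _abs_dr_dE(model, np.clip(E, 1e-300, 1 - 1e-16))
        # E(r) is decreasing: reverse so the new grid increases
        return E[::-1], (values * jac)[::-1]
    if direction == "E_to_r":
        if grid.min() <= 0 or grid.max() >= 1:
            warnings.warn("efficiency grid touches 0 or 1; transform truncated",
                          RuntimeWarning, stacklevel=2)
            grid = np.clip(grid, 1e-12, 1 - 1e-12)
        r = distance_from_efficiency(model, grid)
        jac = 1.0 / _abs_dr_dE(model, grid)
        return r[::-1], (values * jac)[::-1]
    raise ValueError("direction must be 'r_to_E' or 'E_to_r'")
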