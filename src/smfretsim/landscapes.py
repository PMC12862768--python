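"""One-dimensional free-energy landscapes and their equilibrium kinetics.

Distances are in angstrom (A), energies in kcal/mol, the inverse temperature
``beta`` in (kcal/mol)^-1, conformational diffusion coefficients in A^2/ns and
interconversion rates in 1/ms.  The landscape kinds mirror the standard smFRET
simulation setups: a harmonic well (single conformational state), a symmetric
quartic double well (two interconverting states) and an arbitrary tabulated
potential.

Interconversion rates over a barrier are computed with the Berezhkovskii–Szabo
expression for diffusive barrier crossing,

    k(R -> P) = 1 / [ (int_{-inf}^{x*} e^{-beta V} dx) *
                      (int_R^P e^{beta V} / D dx) ],

where ``x*`` is the barrier top, and the corresponding finite-lag transition
matrix is T(tau) = exp(tau Q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy.linalg import expm

__all__ = [
    "ThermoState",
    "FreeEnergyLandscape",
    "HarmonicLandscape",
    "BistableLandscape",
    "TabulatedLandscape",
    "RateResult",
    "evaluate_potential",
    "evaluate_gradient",
    "barrier_height",
    "boltzmann_density",
    "two_state_harmonic_density",
    "partition_function",
    "bs_transition_rate",
    "transition_matrix",
    "symmetric_rate_matrix",
    "landscape_from_dict",
]

NS_PER_MS = 1.0e6  # rate unit conversion: 1/ns -> 1/ms multiplies by 1e6


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic context: beta = 1/(kB T) in (kcal/mol)^-1.

    ``temperature_label`` is informational only; beta is authoritative (quoted
    beta/temperature pairs are often not exactly consistent with standard
    constants).
    """

    beta: float
    temperature_label: float | None = None

    def __post_init__(self) -> None:
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")


class FreeEnergyLandscape:
    """Base class for 1D potentials V(r)."""

    kind: str = "abstract"

    def potential(self, r):
        raise NotImplementedError

    def gradient(self, r):
        raise NotImplementedError

    def curvature(self, r):
        """V''(r); used for integrator stability bounds."""
        raise NotImplementedError

    def support(self, thermo: ThermoState, rel_cutoff: float = 1e-12) -> tuple[float, float]:
        """Interval outside of which exp(-beta V) < rel_cutoff * its maximum."""
        lo, hi = self._scan_range()
        grid = np.linspace(lo, hi, 4097)
        w = np.exp(-thermo.beta * (self.potential(grid) - self.potential(grid).min()))
        keep = np.flatnonzero(w > rel_cutoff)
        if keep.size == 0:
            raise ValueError("landscape has no numerically normalizable support")
        return float(grid[keep[0]]), float(grid[keep[-1]])

    def _scan_range(self) -> tuple[float, float]:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class HarmonicLandscape(FreeEnergyLandscape):
    """V(r) = k/2 (r - center)^2 with k in kcal/(mol A^2)."""

    k_harmonic: float
    center: float
    kind: str = field(default="harmonic", init=False)

    def __post_init__(self) -> None:
        if not self.k_harmonic > 0:
            raise ValueError("k_harmonic must be > 0")

    def potential(self, r):
        d = np.asarray(r, dtype=float) - self.center
        return 0.5 * self.k_harmonic * d * d

    def gradient(self, r):
        return self.k_harmonic * (np.asarray(r, dtype=float) - self.center)

    def curvature(self, r):
        return np.full_like(np.asarray(r, dtype=float), self.k_harmonic)

    def stationary_std(self, thermo: ThermoState) -> float:
        """Boltzmann standard deviation 1/sqrt(beta k)."""
        return 1.0 / math.sqrt(thermo.beta * self.k_harmonic)

    def _scan_range(self) -> tuple[float, float]:
        # 40 thermal sigmas at beta=1 covers any sensible beta after rescan
        half = 40.0 / math.sqrt(self.k_harmonic)
        return self.center - half, self.center + half

    def to_dict(self) -> dict:
        return {"kind": "harmonic", "k_harmonic": self.k_harmonic, "center": self.center}


@dataclass(frozen=True)
class BistableLandscape(FreeEnergyLandscape):
    """V(r) = k/4 ((r - center)^2 - W^2)^2, minima at center +- W.

    ``k_bistable`` (kcal/(mol A^4)) is the bistable force constant -- a
    deliberately distinct name from the Boltzmann constant.
    """

    k_bistable: float
    center: float
    well_offset: float
    kind: str = field(default="bistable", init=False)

    def __post_init__(self) -> None:
        if not self.k_bistable > 0:
            raise ValueError("k_bistable must be > 0")
        if not self.well_offset > 0:
            raise ValueError("well_offset must be > 0")

    def potential(self, r):
        d2 = (np.asarray(r, dtype=float) - self.center) ** 2
        return 0.25 * self.k_bistable * (d2 - self.well_offset**2) ** 2

    def gradient(self, r):
        d = np.asarray(r, dtype=float) - self.center
        return self.k_bistable * d * (d * d - self.well_offset**2)

    def curvature(self, r):
        d2 = (np.asarray(r, dtype=float) - self.center) ** 2
        return self.k_bistable * (3.0 * d2 - self.well_offset**2)

    @property
    def minima(self) -> tuple[float, float]:
        return self.center - self.well_offset, self.center + self.well_offset

    def _scan_range(self) -> tuple[float, float]:
        half = self.well_offset + 40.0 / (self.k_bistable * self.well_offset**2) ** 0.5
        return self.center - half, self.center + half

    def to_dict(self) -> dict:
        return {
            "kind": "bistable",
            "k_bistable": self.k_bistable,
            "center": self.center,
            "well_offset": self.well_offset,
        }


class TabulatedLandscape(FreeEnergyLandscape):
    """Piecewise-linear V(r) from (grid, values); linear interpolation inside the
    grid, range error outside.  Gradient is a central finite difference."""

    kind = "tabulated"

    def __init__(self, grid, values):
        grid = np.asarray(grid, dtype=float)
        values = np.asarray(values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape or grid.size < 3:
            raise ValueError("grid/values must be 1D, equal length >= 3")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("tabulated grid must be strictly increasing")
        self.grid = grid
        self.values = values

    @classmethod
    def from_text(cls, path) -> "TabulatedLandscape":
        """Read a two-column (r in A, V in kcal/mol) whitespace- or
        comma-delimited text file."""
        from .dynamics import _parse_two_column  # shared strict parser

        r, v = _parse_two_column(path)
        return cls(r, v)

    def _check_range(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r < self.grid[0]) or np.any(r > self.grid[-1]):
            raise ValueError(
                f"r outside tabulated grid range [{self.grid[0]}, {self.grid[-1]}]"
            )
        return r

    def potential(self, r):
        r = self._check_range(r)
        return np.interp(r, self.grid, self.values)

    def gradient(self, r):
        r = self._check_range(r)
        h = np.diff(self.grid).mean()
        lo, hi = self.grid[0], self.grid[-1]
        rp = np.minimum(r + h, hi)
        rm = np.maximum(r - h, lo)
        return (np.interp(rp, self.grid, self.values) - np.interp(rm, self.grid, self.values)) / (rp - rm)

    def curvature(self, r):
        r = self._check_range(r)
        h = np.diff(self.grid).mean()
        rp = np.clip(r + h, self.grid[0], self.grid[-1])
        rm = np.clip(r - h, self.grid[0], self.grid[-1])
        vp = np.interp(rp, self.grid, self.values)
        vm = np.interp(rm, self.grid, self.values)
        v0 = np.interp(r, self.grid, self.values)
        return (vp + vm - 2 * v0) / h**2

    def _scan_range(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def support(self, thermo: ThermoState, rel_cutoff: float = 1e-12) -> tuple[float, float]:
        return self._scan_range()

    def to_dict(self) -> dict:
        return {"kind": "tabulated", "grid": self.grid.tolist(), "values": self.values.tolist()}


def landscape_from_dict(d: dict) -> FreeEnergyLandscape:
    kind = d.get("kind")
    if kind == "harmonic":
        return HarmonicLandscape(k_harmonic=d["k_harmonic"], center=d["center"])
    if kind == "bistable":
        return BistableLandscape(
            k_bistable=d["k_bistable"], center=d["center"], well_offset=d["well_offset"]
        )
    if kind == "tabulated":
        return TabulatedLandscape(d["grid"], d["values"])
    raise ValueError(f"unknown landscape kind {kind!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def evaluate_potential(landscape: FreeEnergyLandscape, r):
    """V(r) in kcal/mol."""
    r_arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r_arr)):
        raise ValueError("r must be finite")
    out = landscape.potential(r_arr)
    return float(out) if np.isscalar(r) or np.ndim(r) == 0 else out


def evaluate_gradient(landscape: FreeEnergyLandscape, r):
    """dV/dr in kcal/(mol A)."""
    r_arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r_arr)):
        raise ValueError("r must be finite")
    out = landscape.gradient(r_arr)
    return float(out) if np.isscalar(r) or np.ndim(r) == 0 else out


def barrier_height(landscape: FreeEnergyLandscape) -> float:
    """Barrier top minus well minimum for a bistable landscape: k W^4 / 4."""
    if not isinstance(landscape, BistableLandscape):
        raise TypeError("barrier_height is defined for bistable landscapes only")
    return 0.25 * landscape.k_bistable * landscape.well_offset**4


def partition_function(landscape: FreeEnergyLandscape, thermo: ThermoState) -> float:
    """Z = int_0^inf exp(-beta V(r)) dr by adaptive quadrature (units A)."""
    lo, hi = landscape.support(thermo)
    lo = max(lo, 0.0)
    z, err = integrate.quad(
        lambda x: math.exp(-thermo.beta * float(landscape.potential(x))),
        lo,
        hi,
        limit=200,
    )
    if not (z > 0 and math.isfinite(z)) or err > 1e-6 * z:
        raise ArithmeticError(
            f"partition-function quadrature did not converge: Z={z}, err={err}"
        )
    return z


def boltzmann_density(landscape, thermo: ThermoState, r):
    """Equilibrium probability density (1/A) at distance r.

    Accepts a single landscape (quadrature-normalized over [0, inf)) or a pair
    of harmonic landscapes sharing a force constant, for which the equal-weight
    two-Gaussian closed form is used.
    """
    if isinstance(landscape, (tuple, list)) and len(landscape) == 2:
        return two_state_harmonic_density(landscape[0], landscape[1], thermo, r)
    z = partition_function(landscape, thermo)
    out = np.exp(-thermo.beta * landscape.potential(np.asarray(r, dtype=float))) / z
    return float(out) if np.ndim(r) == 0 else out


def two_state_harmonic_density(
    l1: HarmonicLandscape, l2: HarmonicLandscape, thermo: ThermoState, r
):
    """Equal-weight mixture of the Boltzmann densities of two harmonic wells:

        P(r) = 1/2 sqrt(beta k / 2 pi) (exp(-beta V1) + exp(-beta V2)).
    """
    if not isinstance(l1, HarmonicLandscape) or not isinstance(l2, HarmonicLandscape):
        raise TypeError("two_state_harmonic_density needs two harmonic landscapes")
    if not math.isclose(l1.k_harmonic, l2.k_harmonic, rel_tol=1e-12):
        raise ValueError("the closed form assumes a shared harmonic force constant")
    b, k = thermo.beta, l1.k_harmonic
    amp = 0.5 * math.sqrt(b * k / (2.0 * math.pi))
    r_arr = np.asarray(r, dtype=float)
    out = amp * (np.exp(-b * l1.potential(r_arr)) + np.exp(-b * l2.potential(r_arr)))
    return float(out) if np.ndim(r) == 0 else out


def _well_point(landscape, interval_or_point) -> float:
    """Resolve a well specification: a float, or an (a, b) interval whose
    minimum-V point is used."""
    if np.ndim(interval_or_point) == 0:
        return float(interval_or_point)
    a, b = float(interval_or_point[0]), float(interval_or_point[1])
    grid = np.linspace(a, b, 2001)
    return float(grid[np.argmin(landscape.potential(grid))])


def bs_transition_rate(
    landscape: FreeEnergyLandscape,
    thermo: ThermoState,
    D_conf: float,
    barrier_location: float,
    reactant_range,
    product_range,
) -> float:
    """Berezhkovskii–Szabo diffusive barrier-crossing rate in 1/ms.

    ``D_conf`` is the conformational diffusion coefficient in A^2/ns.  The
    formally infinite lower limit of the population integral is truncated where
    exp(-beta V) falls below 1e-12 of its maximum over the reactant side.
    """
    if not D_conf > 0:
        raise ValueError("D_conf must be > 0")
    beta = thermo.beta
    r_well = _well_point(landscape, reactant_range)
    p_well = _well_point(landscape, product_range)
    lo_r, hi_r = min(r_well, p_well), max(r_well, p_well)
    if not lo_r < barrier_location < hi_r:
        raise ValueError("barrier_location must lie between the well points")

    # population integral over the reactant side, up to the barrier top
    side = np.linspace(min(r_well, barrier_location) - 1e-9, barrier_location, 2001)
    v_side = landscape.potential(side)
    v_min = float(v_side.min())
    # adaptive truncation of the -inf limit
    lo = r_well
    step = max(abs(barrier_location - r_well), 1.0)
    while True:
        trial = lo - step
        try:
            v_trial = float(landscape.potential(trial))
        except ValueError:  # tabulated edge
            lo = landscape._scan_range()[0]
            break
        if math.exp(-beta * (v_trial - v_min)) < 1e-12:
            # refine: walk back in small steps
            fine = np.linspace(trial, lo, 513)
            w = np.exp(-beta * (landscape.potential(fine) - v_min))
            idx = np.flatnonzero(w > 1e-12)
            lo = float(fine[idx[0]]) if idx.size else trial
            break
        lo = trial
        if abs(lo - r_well) > 1e4 * step:
            raise ArithmeticError("population integrand does not decay; divergent")

    pop, pop_err = integrate.quad(
        lambda x: math.exp(-beta * (float(landscape.potential(x)) - v_min)),
        lo,
        barrier_location,
        limit=400,
    )
    pop *= math.exp(-beta * v_min)

    a, b = min(r_well, p_well), max(r_well, p_well)
    flux, flux_err = integrate.quad(
        lambda x: math.exp(beta * float(landscape.potential(x))) / D_conf,
        a,
        b,
        limit=400,
    )
    if not (pop > 0 and flux > 0) or not math.isfinite(pop * flux):
        raise ArithmeticError(f"quadrature failed: pop={pop}, flux={flux}")
    rate_per_ns = 1.0 / (pop * flux)
    return rate_per_ns * NS_PER_MS


@dataclass(frozen=True)
class RateResult:
    """A 2x2 rate matrix Q (1/ms), a lag time tau (ms) and T = exp(tau Q)."""

    Q: np.ndarray
    tau: float
    T: np.ndarray
    barrier_location: float | None = None

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        T = np.asarray(self.T, dtype=float)
        if np.abs(Q.sum(axis=1)).max() > 1e-10:
            raise ValueError("rows of Q must sum to 0")
        if np.abs(T.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("rows of T must sum to 1")
        if T.min() < -1e-12 or T.max() > 1 + 1e-12:
            raise ValueError("entries of T must lie in [0, 1]")


def symmetric_rate_matrix(q: float) -> np.ndarray:
    """Two-state symmetric rate matrix with interconversion rate q (1/ms)."""
    if q < 0:
        raise ValueError("rate must be non-negative")
    return np.array([[-q, q], [q, -q]], dtype=float)


def transition_matrix(Q, tau: float, barrier_location: float | None = None) -> RateResult:
    """Finite-lag transition matrix T(tau) = exp(tau Q).

    ``tau`` is a required lag time in ms; it is deliberately never defaulted.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    if np.abs(Q.sum(axis=1)).max() > 1e-8:
        raise ValueError("rows of Q must sum to 0")
    if np.any(Q - np.diag(np.diag(Q)) < -1e-12):
        raise ValueError("off-diagonal entries of Q must be non-negative")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    T = expm(tau * Q)
    # clean tiny negative round-off so the stochastic-matrix invariant holds
    T = np.clip(T, 0.0, None)
    T /= T.sum(axis=1, keepdims=True)
    return RateResult(Q=Q, tau=float(tau), T=T, barrier_location=barrier_location)
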