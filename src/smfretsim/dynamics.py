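"""Per-molecule conformational trajectories.

Three sources of dye–dye dynamics are supported:

* overdamped Langevin dynamics on a free-energy landscape (Euler–Maruyama,
  with automatic substepping for stiff parameter sets, or the exact
  Ornstein–Uhlenbeck update for harmonic landscapes),
* discrete-state switching with exponentially distributed residence times,
* externally supplied distance trajectories (e.g. MD-derived), optionally
  time-rescaled.

The Langevin step is r(t+dt) = r(t) - beta D_L V'(r) dt + xi with
xi ~ N(0, 2 D_L dt); distances in A, dt in ns, trajectory times in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .landscapes import FreeEnergyLandscape, HarmonicLandscape, ThermoState

__all__ = [
    "LangevinConfig",
    "DistanceTrajectory",
    "EfficiencyTrajectory",
    "StateTrajectory",
    "IntegrationError",
    "propagate_langevin",
    "sample_initial_distance",
    "generate_switching_trajectory",
    "constant_trajectory",
    "import_distance_trajectory",
]

NS_TO_S = 1e-9


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LangevinConfig:
    """Parameters of the overdamped Langevin propagator.

    D_conf in A^2/ns, dt in ns.  ``integrator`` is one of ``auto`` (exact OU
    for harmonic landscapes, substepped Euler–Maruyama otherwise),
    ``euler_maruyama`` (plain, diverges when beta*D*|V''|*dt is large),
    ``substepped`` or ``exact_ou``.  ``max_stability`` bounds
    beta*D*max|V''|*dt_sub for the substepped scheme.
    """

    D_conf: float
    dt: float
    thermo: ThermoState
    integrator: str = "auto"
    max_stability: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.D_conf > 0:
            raise ValueError("D_conf must be > 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not (0 < self.max_stability < 2):
            raise ValueError("max_stability must be in (0, 2)")
        if self.integrator not in {"auto", "euler_maruyama", "substepped", "exact_ou"}:
            raise ValueError(f"unknown integrator {self.integrator!r}")


@dataclass
class DistanceTrajectory:
    """Dye–dye distance r(t): times in seconds, distances in A."""

    times: np.ndarray
    distances: np.ndarray
    molecule_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape or self.times.ndim != 1:
            raise ValueError("times and distances must be equal-length 1D arrays")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("distances must be finite")

    def __len__(self) -> int:
        return self.times.size

    def value_at(self, t):
        """Nearest-previous-sample lookup (piecewise constant from the left)."""
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0, len(self) - 1)
        return self.distances[idx]

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.distances]),
                   delimiter=",", header="time_s,distance_A", comments="")

    def to_hdf5(self, group) -> None:
        group.create_dataset("times", data=self.times)
        group.create_dataset("values", data=self.distances)
        group.attrs["molecule_id"] = self.molecule_id


@dataclass
class EfficiencyTrajectory:
    """FRET efficiency E(t) sampled on a clock; piecewise constant from the left."""

    times: np.ndarray
    efficiencies: np.ndarray
    molecule_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.efficiencies = np.asarray(self.efficiencies, dtype=float)
        if self.times.shape != self.efficiencies.shape or self.times.ndim != 1:
            raise ValueError("times and efficiencies must be equal-length 1D arrays")
        if np.any((self.efficiencies < 0) | (self.efficiencies > 1)):
            raise ValueError("efficiencies must lie in [0, 1]")

    def value_at(self, t):
        idx = np.clip(np.searchsorted(self.times, t, side="right") - 1, 0,
                      self.times.size - 1)
        return self.efficiencies[idx]

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0


@dataclass
class StateTrajectory:
    """Piecewise-constant efficiency states.

    ``switch_times`` (s) start at 0; segment i has efficiency
    ``state_efficiencies[i]`` on [switch_times[i], switch_times[i+1]) and the
    last segment extends to ``duration``.
    """

    switch_times: np.ndarray
    state_efficiencies: np.ndarray
    duration: float
    molecule_id: int = 0

    def __post_init__(self) -> None:
        self.switch_times = np.asarray(self.switch_times, dtype=float)
        self.state_efficiencies = np.asarray(self.state_efficiencies, dtype=float)
        if self.switch_times.shape != self.state_efficiencies.shape:
            raise ValueError("switch_times and state_efficiencies must match")
        if self.switch_times.size == 0:
            raise ValueError("trajectory must have at least one segment")
        if self.switch_times[0] != 0.0:
            raise ValueError("first switch time must be 0")
        if np.any(np.diff(self.switch_times) <= 0):
            raise ValueError("switch times must be increasing")
        if np.any((self.state_efficiencies < 0) | (self.state_efficiencies > 1)):
            raise ValueError("state efficiencies must lie in [0, 1]")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")

    def value_at(self, t):
        idx = np.searchsorted(self.switch_times, t, side="right") - 1
        idx = np.clip(idx, 0, self.switch_times.size - 1)
        return self.state_efficiencies[idx]

    @property
    def residence_times(self) -> np.ndarray:
        """Lengths (s) of all completed segments plus the truncated last one."""
        edges = np.append(self.switch_times, self.duration)
        return np.diff(edges)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.switch_times, self.state_efficiencies]),
                   delimiter=",", header="time_s,efficiency", comments="")

    def to_hdf5(self, group) -> None:
        group.create_dataset("times", data=self.switch_times)
        group.create_dataset("values", data=self.state_efficiencies)
        group.attrs["molecule_id"] = self.molecule_id
        group.attrs["duration"] = self.duration


# ---------------------------------------------------------------------------
# Langevin propagation
# ---------------------------------------------------------------------------

def _max_abs_curvature(landscape: FreeEnergyLandscape, thermo: ThermoState) -> float:
    lo, hi = landscape.support(thermo, rel_cutoff=1e-14)
    grid = np.linspace(lo, hi, 2049)
    return float(np.abs(landscape.curvature(grid)).max())


def _resolve_integrator(landscape, config: LangevinConfig) -> str:
    name = config.integrator
    if name == "auto":
        return "exact_ou" if isinstance(landscape, HarmonicLandscape) else "substepped"
    if name == "exact_ou" and not isinstance(landscape, HarmonicLandscape):
        raise ValueError("exact_ou integrator requires a harmonic landscape")
    return name


def _ou_ensemble(landscape: HarmonicLandscape, config: LangevinConfig,
                 r0: np.ndarray, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Exact Ornstein–Uhlenbeck discretization of the harmonic Langevin SDE."""
    beta = config.thermo.beta
    theta = beta * config.D_conf * landscape.k_harmonic  # 1/ns
    rho = math.exp(-theta * config.dt)
    sigma_st = 1.0 / math.sqrt(beta * landscape.k_harmonic)
    m = r0.size
    out = np.empty((n_steps + 1, m))
    out[0] = r0
    if rho < 1e-12:
        # fully decorrelated at this step size: i.i.d. stationary draws
        out[1:] = landscape.center + sigma_st * rng.standard_normal((n_steps, m))
        return out
    sig_step = sigma_st * math.sqrt(1.0 - rho * rho)
    noise = rng.standard_normal((n_steps, m))
    # y_n = rho y_{n-1} + w_n solved with an IIR filter (C speed)
    from scipy.signal import lfilter, lfiltic

    w = sig_step * noise
    y0 = r0 - landscape.center
    for j in range(m):  # lfilter is 1D per initial condition
        zi = lfiltic([1.0], [1.0, -rho], [y0[j]])
        y, _ = lfilter([1.0], [1.0, -rho], w[:, j], zi=zi)
        out[1:, j] = y + landscape.center
    return out


def _em_ensemble(landscape, config: LangevinConfig, r0: np.ndarray, n_steps: int,
                 rng: np.random.Generator, substep: bool) -> np.ndarray:
    beta = config.thermo.beta
    stiffness = beta * config.D_conf * _max_abs_curvature(landscape, config.thermo) * config.dt
    if substep:
        n_sub = max(1, int(math.ceil(stiffness / config.max_stability)))
    else:
        n_sub = 1
    dt_sub = config.dt / n_sub
    drift = beta * config.D_conf * dt_sub
    noise_sd = math.sqrt(2.0 * config.D_conf * dt_sub)
    m = r0.size
    out = np.empty((n_steps + 1, m))
    out[0] = r0
    r = r0.astype(float).copy()
    for i in range(n_steps):
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(n_sub):
                r = r - drift * landscape.gradient(r) + noise_sd * rng.standard_normal(m)
        if not np.all(np.isfinite(r)):
            raise IntegrationError(
                "Langevin integration overflowed "
                f"(stability factor beta*D*max|V''|*dt = {stiffness:.3g}; "
                "use the 'substepped' or 'exact_ou' integrator)"
            )
        out[i + 1] = r
    return out


def _propagate_ensemble(landscape, config: LangevinConfig, r0: np.ndarray,
                        n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """(n_steps+1, n_molecules) array of distances at the dt clock."""
    name = _resolve_integrator(landscape, config)
    r0 = np.atleast_1d(np.asarray(r0, dtype=float))
    if not np.all(np.isfinite(r0)):
        raise ValueError("r0 must be finite")
    if name == "exact_ou":
        return _ou_ensemble(landscape, config, r0, n_steps, rng)
    return _em_ensemble(landscape, config, r0, n_steps, rng,
                        substep=(name == "substepped"))


def propagate_langevin(landscape: FreeEnergyLandscape, config: LangevinConfig,
                       r0: float, n_steps: int,
                       rng: np.random.Generator | None = None) -> DistanceTrajectory:
    """Propagate one molecule for ``n_steps`` steps of ``config.dt`` ns.

    Samples are retained at the dt clock; any stiffness substeps are internal.
    Deterministic given (seed, parameters).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ens = _propagate_ensemble(landscape, config, np.array([r0]), n_steps, rng)
    times = np.arange(n_steps + 1) * (config.dt * NS_TO_S)
    # times are strictly increasing by construction; molecule_id set by caller
    return DistanceTrajectory(times=times, distances=ens[:, 0])


def sample_initial_distance(landscape: FreeEnergyLandscape, thermo: ThermoState,
                            seed: int | np.random.Generator | None = None,
                            size: int | None = None):
    """Draw initial distances from the Boltzmann density via inverse-CDF on a
    dense grid."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = landscape.support(thermo)
    lo = max(lo, 0.0)
    grid = np.linspace(lo, hi, 8193)
    dens = np.exp(-thermo.beta * (landscape.potential(grid) - landscape.potential(grid).min()))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
    if cdf[-1] <= 0 or not np.isfinite(cdf[-1]):
        raise ArithmeticError("landscape is not normalizable on its support")
    cdf /= cdf[-1]
    u = rng.random(size if size is not None else 1)
    draws = np.interp(u, cdf, grid)
    return draws if size is not None else float(draws[0])


# ---------------------------------------------------------------------------
# discrete-state models
# ---------------------------------------------------------------------------

def generate_switching_trajectory(efficiencies, mean_residence: float,
                                  duration: float,
                                  seed: int | np.random.Generator | None = None,
                                  molecule_id: int = 0,
                                  initial_state: int | None = None) -> StateTrajectory:
    """Alternating two-state step function with exponential residence times.

    ``efficiencies`` is the (E_state0, E_state1) pair, ``mean_residence`` the
    exponential mean in ms, ``duration`` the covered span in seconds.
    """
    e = np.asarray(efficiencies, dtype=float)
    if e.shape != (2,):
        raise ValueError("efficiencies must be a pair")
    if np.any((e < 0) | (e > 1)):
        raise ValueError("efficiencies must lie in [0, 1]")
    if not mean_residence > 0:
        raise ValueError("mean_residence must be > 0")
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_s = mean_residence * 1e-3
    # draw in blocks until the trajectory covers [0, duration]
    times = [0.0]
    total = 0.0
    chunks = []
    while total < duration:
        block = rng.exponential(mean_s, size=max(16, int(1.5 * duration / mean_s) + 1))
        chunks.append(block)
        total += block.sum()
    res = np.concatenate(chunks)
    edges = np.cumsum(res)
    n_seg = int(np.searchsorted(edges, duration)) + 1
    switch_times = np.concatenate([[0.0], edges[: n_seg - 1]])
    first = int(rng.integers(0, 2)) if initial_state is None else int(initial_state)
    states = (first + np.arange(n_seg)) % 2  # strict alternation
    return StateTrajectory(switch_times=switch_times, state_efficiencies=e[states],
                           duration=duration, molecule_id=molecule_id)


def constant_trajectory(efficiency: float, duration: float,
                        molecule_id: int = 0) -> StateTrajectory:
    """Single fixed-efficiency segment; E = 0 models a donor-only molecule."""
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    if not duration > 0:
        raise ValueError("duration must be > 0 (empty trajectory)")
    return StateTrajectory(switch_times=np.array([0.0]),
                           state_efficiencies=np.array([float(efficiency)]),
                           duration=duration, molecule_id=molecule_id)


# ---------------------------------------------------------------------------
# external (MD-derived) trajectories
# ---------------------------------------------------------------------------

def _parse_two_column(path):
    """Strict two-column numeric parser (whitespace or comma delimited) that
    reports offending line numbers."""
    col1, col2 = [], []
    n_data = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                if n_data == 0 and lineno == 1:
                    continue  # tolerate a single header line
                raise ValueError(f"{path}: line {lineno}: expected two columns, got {len(parts)}")
            try:
                a, b = float(parts[0]), float(parts[1])
            except ValueError:
                if n_data == 0:
                    continue  # header line with labels
                raise ValueError(f"{path}: line {lineno}: non-numeric row {line!r}") from None
            col1.append(a)
            col2.append(b)
            n_data += 1
    if n_data == 0:
        raise ValueError(f"{path}: no numeric data rows")
    return np.asarray(col1), np.asarray(col2)


def import_distance_trajectory(path, time_rescale: float = 1.0,
                               molecule_id: int = 0) -> DistanceTrajectory:
    """Read a two-column (time, distance A) table and rescale its time axis.

    ``time_rescale`` multiplies the time column (e.g. mapping a 320 ns MD
    trace onto 60 s of simulated wall time).  Distances are unchanged.
    """
    if not time_rescale > 0:
        raise ValueError("time_rescale must be > 0")
    t, r = _parse_two_column(path)
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise ValueError(f"{path}: times not strictly increasing at data row {bad}")
    return DistanceTrajectory(times=t * time_rescale, distances=r,
                              molecule_id=molecule_id)


def resample_to_clock(traj: DistanceTrajectory, dt: float, duration: float) -> np.ndarray:
    """Sample a distance trajectory on a uniform clock (dt, duration in s) by
    nearest-previous-sample lookup."""
    n = int(round(duration / dt))
    clock = np.arange(n) * dt
    if traj.times[0] > 0:
        clock = np.clip(clock, traj.times[0], None)
    return np.asarray(traj.value_at(clock), dtype=float)
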