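"""Scenario configuration: populations, engine parameters, analysis settings.

A scenario fully determines a simulated smFRET experiment: the molecule
populations with their conformational models, the diffusion box / PSF /
emission parameters, the duration and the root seed.  Scenarios serialize to
YAML/JSON-friendly dicts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DistanceTrajectory
from .efficiency import EfficiencyModel
from .landscapes import FreeEnergyLandscape, ThermoState, landscape_from_dict

__all__ = [
    "FixedModel",
    "SwitchingModel",
    "LangevinModel",
    "ImportedModel",
    "Population",
    "AnalysisParams",
    "ScenarioConfig",
]


@dataclass(frozen=True)
class FixedModel:
    """Constant FRET efficiency (E = 0 models donor-only molecules)."""

    efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"type": "fixed", "efficiency": self.efficiency}


@dataclass(frozen=True)
class SwitchingModel:
    """Two-state step-function efficiencies with exponential residence times."""

    efficiencies: tuple[float, float]
    mean_residence_ms: float

    def __post_init__(self) -> None:
        if len(self.efficiencies) != 2:
            raise ValueError("efficiencies must be a pair")
        if not self.mean_residence_ms > 0:
            raise ValueError("mean_residence_ms must be > 0")

    def to_dict(self) -> dict:
        return {"type": "switching", "efficiencies": list(self.efficiencies),
                "mean_residence_ms": self.mean_residence_ms}


@dataclass(frozen=True)
class LangevinModel:
    """Overdamped Langevin dye–dye distance dynamics plus an efficiency model.

    ``D_conf`` in A^2/ns; ``dt_ns`` is the conformational step used when the
    engine needs substepping (the engine clock itself may be coarser).
    """

    landscape: FreeEnergyLandscape
    thermo: ThermoState
    D_conf: float
    efficiency_model: EfficiencyModel
    integrator: str = "auto"
    dt_ns: float = 50.0

    def to_dict(self) -> dict:
        return {"type": "langevin", "landscape": self.landscape.to_dict(),
                "beta": self.thermo.beta, "D_conf": self.D_conf,
                "efficiency_model": self.efficiency_model.to_dict(),
                "integrator": self.integrator, "dt_ns": self.dt_ns}


@dataclass(frozen=True)
class ImportedModel:
    """Externally supplied distance trajectories (one per molecule), e.g. from
    MD, with an efficiency model for the conversion."""

    trajectories: tuple[DistanceTrajectory, ...]
    efficiency_model: EfficiencyModel
    paths: tuple[str, ...] | None = None
    time_rescale: float = 1.0

    def to_dict(self) -> dict:
        if self.paths is None:
            raise ValueError("cannot serialize in-memory imported trajectories; "
                             "construct the model from file paths")
        return {"type": "imported", "paths": list(self.paths),
                "efficiency_model": self.efficiency_model.to_dict(),
                "time_rescale": self.time_rescale}


ConformationalModel = FixedModel | SwitchingModel | LangevinModel | ImportedModel


def _model_from_dict(d: dict) -> ConformationalModel:
    t = d["type"]
    if t == "fixed":
        return FixedModel(efficiency=d["efficiency"])
    if t == "switching":
        return SwitchingModel(efficiencies=tuple(d["efficiencies"]),
                              mean_residence_ms=d["mean_residence_ms"])
    if t == "langevin":
        return LangevinModel(landscape=landscape_from_dict(d["landscape"]),
                             thermo=ThermoState(beta=d["beta"]),
                             D_conf=d["D_conf"],
                             efficiency_model=EfficiencyModel.from_dict(d["efficiency_model"]),
                             integrator=d.get("integrator", "auto"),
                             dt_ns=d.get("dt_ns", 50.0))
    if t == "imported":
        from .dynamics import import_distance_trajectory

        paths = tuple(d["paths"])
        trajs = tuple(import_distance_trajectory(p, d.get("time_rescale", 1.0), i)
                      for i, p in enumerate(paths))
        return ImportedModel(trajectories=trajs,
                             efficiency_model=EfficiencyModel.from_dict(d["efficiency_model"]),
                             paths=paths, time_rescale=d.get("time_rescale", 1.0))
    raise ValueError(f"unknown conformational model type {t!r}")


@dataclass(frozen=True)
class Population:
    n: int
    model: ConformationalModel
    label: str = ""

    def __post_init__(self) -> None:
        if not self.n > 0:
            raise ValueError("population count must be > 0")

    def to_dict(self) -> dict:
        return {"n": self.n, "model": self.model.to_dict(), "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "Population":
        return cls(n=d["n"], model=_model_from_dict(d["model"]), label=d.get("label", ""))


@dataclass(frozen=True)
class AnalysisParams:
    """Defaults follow the standard freely-diffusing smFRET analysis settings:
    1-ms bins, >40-photon threshold, 200-photon sliding window at 40,000 cps,
    >=100-photon burst selection, 10-photon BVA sub-bursts."""

    bin_width: float = 1e-3
    bin_threshold: int = 40
    burst_window: int = 200
    burst_rate_threshold: float = 40_000.0
    burst_min_photons: int = 100
    bva_n: int = 10
    gmm_components: int = 2
    skew_components: int = 3
    hmm_states: int = 2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisParams":
        return cls(**d)


@dataclass
class ScenarioConfig:
    name: str
    populations: list[Population]
    box: "SimulationBox"
    psf: "PSFModel"
    emission: "EmissionConfig"
    duration: float                      # seconds
    seed: int = 0
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    initial_positions: np.ndarray | None = None   # (n_molecules, 3) um, else uniform
    store_truth: bool = True

    @property
    def n_molecules(self) -> int:
        return sum(p.n for p in self.populations)

    def scaled(self, duration_scale: float = 1.0, engine_dt: float | None = None,
               seed: int | None = None) -> "ScenarioConfig":
        """Desk-scale copy: shrink the duration and/or coarsen the engine step
        without touching any physics parameter."""
        em = self.emission
        if engine_dt is not None:
            em = dataclasses.replace(em, dt=engine_dt)
        return dataclasses.replace(
            self,
            emission=em,
            duration=self.duration * duration_scale,
            seed=self.seed if seed is None else seed,
        )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "populations": [p.to_dict() for p in self.populations],
            "box": self.box.to_dict(),
            "psf": self.psf.to_dict(),
            "emission": self.emission.to_dict(),
            "duration": self.duration,
            "seed": self.seed,
            "analysis": self.analysis.to_dict(),
            "store_truth": self.store_truth,
        }
        if self.initial_positions is not None:
            d["initial_positions"] = np.asarray(self.initial_positions).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        from .engine import EmissionConfig, PSFModel, SimulationBox

        init = d.get("initial_positions")
        return cls(
            name=d["name"],
            populations=[Population.from_dict(p) for p in d["populations"]],
            box=SimulationBox.from_dict(d["box"]),
            psf=PSFModel.from_dict(d["psf"]),
            emission=EmissionConfig.from_dict(d["emission"]),
            duration=d["duration"],
            seed=d.get("seed", 0),
            analysis=AnalysisParams.from_dict(d.get("analysis", {})),
            initial_positions=None if init is None else np.asarray(init, dtype=float),
            store_truth=d.get("store_truth", True),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
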