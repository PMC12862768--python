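"""Built-in simulation scenarios, deterministic test fixtures and the
simulate-then-analyze pipeline.

The two flagship scenarios are a single-state system (harmonic landscapes or
the matching fixed efficiencies, efficiencies 0.71/0.41 from the inverse-2.65
model at 40/65 A) and a two-state interconverting system (symmetric bistable
landscape or exponential-residence switching between the Forster-model
efficiencies 0.944/0.290 at 35/65 A), both observed through the same
diffusion/PSF/emission setup: an 8x8x12 um box, D_B = 30 um^2/s, PSF sigmas
0.3/0.3/0.5 um, 200,000 cps peak emission and 1800/1200 cps donor/acceptor
background.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from . import analysis as ana
from .config import (
    AnalysisParams,
    FixedModel,
    ImportedModel,
    LangevinModel,
    Population,
    ScenarioConfig,
    SwitchingModel,
)
from .dynamics import DistanceTrajectory
from .efficiency import EfficiencyModel
from .engine import (
    EmissionConfig,
    PSFModel,
    SimulationBox,
    SimulationResult,
    simulate_experiment,
)
from .landscapes import (
    BistableLandscape,
    HarmonicLandscape,
    ThermoState,
    bs_transition_rate,
    symmetric_rate_matrix,
    transition_matrix,
)
from .photons import write_photons

__all__ = ["builtin_scenario", "generate_fixture", "run_pipeline",
           "SCENARIO_NAMES", "synthetic_md_trajectory"]

SCENARIO_NAMES = ("example1_langevin", "example1_fixed", "example2_langevin",
                  "example2_switching", "md_adapter_demo")

_BOX = SimulationBox(Lx=8.0, Ly=8.0, Lz=12.0)
_PSF = PSFModel(sigma_x=0.3, sigma_y=0.3, sigma_z=0.5)


def _emission(dt: float = 50e-9) -> EmissionConfig:
    return EmissionConfig(max_rate=200_000.0, bg_donor=1800.0, bg_acceptor=1200.0,
                          dt=dt, D_B=30.0)


def builtin_scenario(name: str, include_donor_only: bool | None = None,
                     seed: int = 0) -> ScenarioConfig:
    """Return a fully parameterized built-in scenario.

    ``include_donor_only`` overrides the default donor-only handling of the
    two-state scenarios (included for the Langevin variant, excluded for the
    switching variant); it is ignored by the single-state scenarios.
    Scale a scenario for desk-size runs with :meth:`ScenarioConfig.scaled`.
    """
    e265 = EfficiencyModel.restricted_dye(R0=56.0)
    e6 = EfficiencyModel.forster(R0=56.0)

    if name == "example1_langevin":
        thermo = ThermoState(beta=1.339, temperature_label=378.0)
        pops = [
            Population(50, LangevinModel(HarmonicLandscape(0.025, 40.0), thermo,
                                         D_conf=1300.0, efficiency_model=e265),
                       label="harmonic 40 A"),
            Population(50, LangevinModel(HarmonicLandscape(0.025, 65.0), thermo,
                                         D_conf=1300.0, efficiency_model=e265),
                       label="harmonic 65 A"),
        ]
        return ScenarioConfig(name=name, populations=pops, box=_BOX, psf=_PSF,
                              emission=_emission(), duration=10.0, seed=seed)

    if name == "example1_fixed":
        pops = [
            Population(50, FixedModel(e265.efficiency(40.0)), label="E=0.71"),
            Population(50, FixedModel(e265.efficiency(65.0)), label="E=0.41"),
        ]
        return ScenarioConfig(name=name, populations=pops, box=_BOX, psf=_PSF,
                              emission=_emission(), duration=10.0, seed=seed)

    if name == "example2_langevin":
        thermo = ThermoState(beta=1.679, temperature_label=300.0)
        pops = [
            Population(90, LangevinModel(BistableLandscape(1e-4, 50.0, 15.0),
                                         thermo, D_conf=0.002,
                                         efficiency_model=e6),
                       label="bistable"),
        ]
        if include_donor_only is None or include_donor_only:
            pops.append(Population(10, FixedModel(0.0), label="donor-only"))
        return ScenarioConfig(name=name, populations=pops, box=_BOX, psf=_PSF,
                              emission=_emission(), duration=1200.0, seed=seed,
                              analysis=AnalysisParams(skew_components=3))

    if name == "example2_switching":
        pops = [
            Population(90, SwitchingModel(efficiencies=(e6.efficiency(35.0),
                                                        e6.efficiency(65.0)),
                                          mean_residence_ms=31.126),
                       label="two-state switching"),
        ]
        if include_donor_only:
            pops.append(Population(10, FixedModel(0.0), label="donor-only"))
        return ScenarioConfig(name=name, populations=pops, box=_BOX, psf=_PSF,
                              emission=_emission(), duration=1200.0, seed=seed)

    if name == "md_adapter_demo":
        model = EfficiencyModel.restricted_dye(R0=57.0)
        rescale = 60.0 / 320e-9  # maps a 320 ns trace onto 60 s
        trajs = tuple(synthetic_md_trajectory(seed=seed + j, molecule_id=j,
                                              time_rescale=rescale)
                      for j in range(16))
        pops = [Population(16, ImportedModel(trajectories=trajs,
                                             efficiency_model=model,
                                             time_rescale=rescale),
                           label="synthetic MD stand-in")]
        return ScenarioConfig(name=name, populations=pops, box=_BOX, psf=_PSF,
                              emission=_emission(), duration=60.0, seed=seed,
                              analysis=AnalysisParams(bin_threshold=20))

    raise KeyError(f"unknown scenario {name!r}; options: {', '.join(SCENARIO_NAMES)}")


def synthetic_md_trajectory(seed: int = 0, molecule_id: int = 0,
                            n_samples: int = 3200, span: float = 320e-9,
                            time_rescale: float = 1.0) -> DistanceTrajectory:
    """Synthetic stand-in for an MD-derived dye–dye distance trace.

    This is *not* molecular-dynamics output: it is a mean-reverting random
    walk with two preferred distances, generated so that the MD-ingestion
    code path (two-column trace, time rescaling, clock resampling) can be
    exercised without external data.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, span, n_samples)
    r = np.empty(n_samples)
    centers = (45.0, 62.0)
    state = rng.integers(0, 2)
    r[0] = centers[state] + rng.normal(0, 3.0)
    for i in range(1, n_samples):
        if rng.random() < 0.002:
            state = 1 - state
        r[i] = r[i - 1] + 0.05 * (centers[state] - r[i - 1]) + rng.normal(0, 0.8)
    return DistanceTrajectory(times=t * time_rescale, distances=np.clip(r, 5.0, 120.0),
                              molecule_id=molecule_id)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("background_only", "pinned_fixed_e", "switching_short")


def generate_fixture(name: str, seed: int = 0):
    """Small deterministic photon streams for fast unit tests.

    Returns ``(SimulationResult, expected)`` where ``expected`` records the
    analytic summary statistics of the fixture.
    """
    em = EmissionConfig(max_rate=200_000.0, bg_donor=1800.0, bg_acceptor=1200.0,
                        dt=1e-6, D_B=30.0)
    small_box = SimulationBox(2.0, 2.0, 3.0)
    if name == "background_only":
        # zero-molecule streams are exercised via an always-dark molecule
        sc = ScenarioConfig(name=name,
                            populations=[Population(1, FixedModel(0.5))],
                            box=small_box, psf=_PSF,
                            emission=EmissionConfig(max_rate=0.0, bg_donor=1800.0,
                                                    bg_acceptor=1200.0, dt=1e-6,
                                                    D_B=30.0),
                            duration=0.5, seed=seed)
        expected = {"mean_donor": 1800.0 * sc.duration,
                    "mean_acceptor": 1200.0 * sc.duration}
    elif name == "pinned_fixed_e":
        sc = ScenarioConfig(name=name,
                            populations=[Population(1, FixedModel(0.75))],
                            box=small_box, psf=_PSF,
                            emission=EmissionConfig(max_rate=200_000.0, bg_donor=0.0,
                                                    bg_acceptor=0.0, dt=1e-6,
                                                    D_B=1e-9),
                            duration=0.5, seed=seed,
                            initial_positions=np.array([small_box.center]))
        expected = {"mean_total": 200_000.0 * sc.duration, "efficiency": 0.75}
    elif name == "switching_short":
        sc = ScenarioConfig(name=name,
                            populations=[Population(3, SwitchingModel((0.944, 0.290), 31.126))],
                            box=small_box, psf=_PSF, emission=em,
                            duration=0.5, seed=seed)
        expected = {"efficiencies": (0.944, 0.290), "mean_residence_ms": 31.126}
    else:
        raise KeyError(f"unknown fixture {name!r}; options: {', '.join(FIXTURE_NAMES)}")
    return simulate_experiment(sc), expected


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _scenario_kinds(scenario: ScenarioConfig) -> set[str]:
    kinds = set()
    for p in scenario.populations:
        if isinstance(p.model, SwitchingModel):
            kinds.add("switching")
        elif isinstance(p.model, LangevinModel):
            kinds.add("bistable" if isinstance(p.model.landscape, BistableLandscape)
                      else "harmonic")
        elif isinstance(p.model, FixedModel):
            kinds.add("donor_only" if p.model.efficiency == 0.0 else "fixed")
        else:
            kinds.add("imported")
    return kinds


def run_pipeline(scenario: ScenarioConfig, output_dir, seed: int | None = None,
                 make_plots: bool = True) -> dict:
    """Simulate a scenario and run the analysis suite on the photon stream.

    Writes the photon file, a YAML echo of the configuration, JSON fit
    reports and (optionally) PNG figures into ``output_dir``; returns the
    report dictionary.  Stage failures are re-raised with the stage name;
    outputs written before the failure are retained.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario.to_yaml(out / "scenario.yaml")

    result = simulate_experiment(scenario, seed=seed)
    write_photons(result.photons, out / "photons.csv")
    report: dict = {
        "scenario": scenario.name,
        "seed": scenario.seed if seed is None else seed,
        "n_photons": len(result.photons),
        "n_molecules": scenario.n_molecules,
        "duration_s": scenario.duration,
    }
    kinds = _scenario_kinds(scenario)
    p = scenario.analysis

    def _stage(name, fn):
        try:
            report[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"analysis stage {name!r} failed: {exc}") from exc

    trace = ana.bin_photons(result.photons, p.bin_width, duration=scenario.duration)
    mask = ana.threshold_bins(trace, p.bin_threshold)
    e_vals = trace.apparent_efficiency[mask]
    report["binning"] = {"bin_width_s": p.bin_width, "threshold": p.bin_threshold,
                         "n_bins_above_threshold": int(mask.sum())}

    def _gmm():
        fit = ana.fit_gaussian_mixture(e_vals, p.gmm_components, seed=0)
        return {"means": fit.means.tolist(), "stds": fit.scales.tolist(),
                "weights": fit.weights.tolist(), "converged": fit.converged}

    if e_vals.size > 10 * p.gmm_components:
        _stage("gmm", _gmm)

    if kinds & {"switching", "bistable", "donor_only"}:
        def _skew():
            fit = ana.fit_skew_mixture(e_vals, p.skew_components, seed=0)
            return {"locations": fit.locations.tolist(),
                    "scales": fit.scales.tolist(),
                    "shapes": fit.shapes.tolist(),
                    "weights": fit.weights.tolist(),
                    "component_means": fit.means.tolist(),
                    "converged": fit.converged}

        if e_vals.size > 20 * p.skew_components:
            _stage("skew_gmm", _skew)

        def _bursts_bva():
            bursts = ana.sliding_window_burst_search(result.photons, p.burst_window,
                                                     p.burst_rate_threshold)
            selected = ana.select_bursts(bursts, p.burst_min_photons)
            d: dict = {"n_bursts": len(bursts), "n_selected": len(selected)}
            if len(selected):
                bva = ana.burst_variance_analysis(selected, result.photons, p.bva_n)
                d["bva"] = {"n_bursts": int(bva.sigma.size),
                            "mean_sigma": float(np.mean(bva.sigma)) if bva.sigma.size else None,
                            "n_excluded": bva.n_excluded}
                if make_plots:
                    _plot_bva(bva, out / "bva.png")
            return d

        _stage("bursts", _bursts_bva)

        def _hmm():
            regions = ana.burst_regions(trace, p.bin_threshold)
            seqs = ana.region_efficiency_sequences(trace, regions)
            d = {"n_regions": len(regions),
                 "mean_region_length_bins": ana.mean_region_length(regions)}
            if len(seqs) >= 10:
                fit = ana.fit_hmm(seqs, p.hmm_states, seed=0)
                d["transition_matrix"] = fit.transmat.tolist()
                d["state_means"] = fit.means.tolist()
                d["state_variances"] = fit.variances.tolist()
                d["converged"] = fit.converged
            return d

        _stage("hmm", _hmm)

    if "bistable" in kinds:
        def _rates():
            pop = next(q for q in scenario.populations
                       if isinstance(q.model, LangevinModel)
                       and isinstance(q.model.landscape, BistableLandscape))
            lm = pop.model
            lo, hi = lm.landscape.minima
            q_rate = bs_transition_rate(lm.landscape, lm.thermo, lm.D_conf,
                                        lm.landscape.center, lo, hi)
            tau = p.bin_width * 1e3  # report at the analysis bin width, in ms
            rr = transition_matrix(symmetric_rate_matrix(q_rate), tau=tau,
                                   barrier_location=lm.landscape.center)
            return {"rate_per_ms": q_rate, "tau_ms": tau,
                    "transition_matrix": rr.T.tolist()}

        _stage("rates", _rates)

    if make_plots and e_vals.size:
        _plot_efficiency_hist(e_vals, report, out / "efficiency_hist.png")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _plot_efficiency_hist(e_vals, report, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(e_vals, bins=60, range=(0, 1), density=True, alpha=0.6,
            color="steelblue", label="apparent efficiency")
    grid = np.linspace(1e-3, 1 - 1e-3, 400)
    for key, kind in (("gmm", "gaussian"), ("skew_gmm", "skew")):
        if key not in report:
            continue
        d = report[key]
        dens = np.zeros_like(grid)
        if kind == "gaussian":
            for w, m, s in zip(d["weights"], d["means"], d["stds"]):
                dens += w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        else:
            for w, xi, om, al in zip(d["weights"], d["locations"], d["scales"], d["shapes"]):
                dens += w * ana.skew_normal_pdf(grid, xi, om, al)
        ax.plot(grid, dens, label=key)
    ax.set_xlabel("apparent efficiency")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_bva(bva, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(bva.mean_efficiency, bva.sigma, s=4, alpha=0.3, label="bursts")
    grid = np.linspace(0, 1, 200)
    ax.plot(grid, bva.reference_curve(grid), "k--", label="static (binomial)")
    ax.set_xlabel("burst mean efficiency")
    ax.set_ylabel("sub-burst efficiency std")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
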