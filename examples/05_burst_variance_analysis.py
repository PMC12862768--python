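"""Burst variance analysis: static molecules sit on the binomial curve,
interconverting molecules rise above it.

Simulates one static fixed-efficiency population and one switching
population under identical diffusion/emission conditions, finds bursts with
the 200-photon sliding window at 40,000 cps, keeps bursts with at least 100
photons and compares the sub-burst (n = 10) efficiency standard deviations
with the static expectation sqrt(E(1-E)/10).
"""

import numpy as np

import smfretsim as sm
import smfretsim.analysis as ana
from smfretsim.config import FixedModel, Population, ScenarioConfig, SwitchingModel
from smfretsim.engine import EmissionConfig

base = sm.builtin_scenario("example2_switching")
em = EmissionConfig(max_rate=200_000.0, bg_donor=1800.0, bg_acceptor=1200.0,
                    dt=5e-6, D_B=30.0)


def bva_for(populations, seed):
    sc = ScenarioConfig(name="bva", populations=populations, box=base.box,
                        psf=base.psf, emission=em, duration=8.0, seed=seed)
    res = sm.simulate_experiment(sc)
    bursts = ana.select_bursts(
        ana.sliding_window_burst_search(res.photons, 200, 40_000.0), 100)
    return ana.burst_variance_analysis(bursts, res.photons, n=10)


static = bva_for([Population(90, FixedModel(0.5))], seed=1)
dynamic = bva_for([Population(90, SwitchingModel((0.944, 0.290), 31.126))], seed=2)

ref_static = ana.static_bva_std(0.5, 10)
print(f"static E=0.5:  {static.sigma.size} bursts, "
      f"mean sigma {static.sigma.mean():.4f}  (binomial curve {ref_static:.4f})")
ref_dyn = ana.static_bva_std(dynamic.mean_efficiency, 10)
print(f"switching:     {dynamic.sigma.size} bursts, "
      f"mean sigma {dynamic.sigma.mean():.4f}  (curve at burst means "
      f"{ref_dyn.mean():.4f})")
print(f"fraction of switching bursts above the curve: "
      f"{np.mean(dynamic.sigma > ref_dyn):.2f}")
print("\nStatic bursts scatter on the binomial line (shot noise only, plus a")
print("small upward shift from background mixing); within-burst state")
print("switching adds conformational variance and lifts bursts above it.")
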