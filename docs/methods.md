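# Methods

This note records the models implemented in `smfretsim`, the numerical
choices behind them, and the limits of what the simulations demonstrate.

## Conformational dynamics

The dye–dye distance r(t) evolves by overdamped Langevin dynamics on a 1D
free-energy landscape V(r):

    r(t + δt) = r(t) − β D_L V′(r) δt + ξ,   ξ ~ N(0, 2 D_L δt),

with distances in Å, δt in ns, β in (kcal/mol)⁻¹ and D_L in Å²/ns.  The
model assumes an inertialess (high-friction) regime, a distance-independent
diffusion coefficient, and that all conformational information relevant to
FRET is carried by the scalar distance.  Multidimensional coordinates,
position-dependent D, dye rotational/linker dynamics and κ² fluctuations are
out of scope.

**Stiffness.**  The explicit update is stable only when
s = β·D_L·|V″|·δt ≲ 1.  The single-state scenario (β = 1.339, D_L = 1300
Å²/ns, k_H = 0.025 kcal/(mol Å²), δt = 50 ns) has s ≈ 2176, so a naive step
diverges.  The package therefore defaults to:

* **exact OU** for harmonic landscapes — the exact discretisation
  r′ = r_c + (r − r_c)ρ + N(0, (1 − ρ²)/(βk)) with ρ = e^{−βDkδt}, valid at
  any step size.  At the parameters above ρ ≈ e^{−2176}: successive samples
  are effectively independent Boltzmann draws, which is also the only
  observable consequence of these parameters at any analysis time scale.
* **substepped Euler–Maruyama** otherwise, with the substep chosen so that
  s ≤ `max_stability` (default 0.1).  Euler–Maruyama carries a
  O(s/2) *relative* bias in the stationary within-well variance; the default
  bound keeps it below ~5%, which is invisible to the photon-level analyses.
  Tests that compare distributions at 10⁵-sample resolution tighten the
  bound to 0.02.

**Initial conditions.**  Initial distances are drawn from the Boltzmann
density by inverse-CDF sampling on a dense grid (the quadrature-normalised
e^{−βV}/Z); initial switching states are drawn uniformly.  Stationarity
tests exploit this: an ensemble started from exact Boltzmann draws must
remain Boltzmann under the propagator, so a final-state Kolmogorov–Smirnov
test with 10⁵ independent walkers checks the propagator at full KS
sensitivity without requiring ergodic well-hopping times.

**Interconversion kinetics.**  Well-to-well rates are computed from the
Berezhkovskii–Szabo expression

    k(R→P) = [ (∫_{−∞}^{x*} e^{−βV} dx) (∫_R^P e^{βV}/D dx) ]⁻¹,

by adaptive quadrature; the −∞ limit is truncated where e^{−βV} falls below
10⁻¹² of its maximum (the physical coordinate is a distance, and the
truncation error is far below quadrature tolerance for any well bounded away
from 0).  Rates are reported per millisecond.  The finite-lag transition
matrix is T(τ) = exp(τQ).  **τ is a required argument and never
defaulted**: for the two-state example landscape (k_B = 10⁻⁴, W = 15 Å,
β = 1.679, D_L = 0.002 Å²/ns) the computed rate is ≈ 1.6/ms, i.e. a mean
residence of ≈ 0.6 ms — orders of magnitude faster than the 31.126 ms
residence used by the matching discrete-state generator — so no lag choice
can be privileged as "the" analytical transition matrix, and the package
does not bake one in.

**Discrete-state and external models.**  The switching generator draws
i.i.d. exponential residence times (mean in ms) and strictly alternates two
efficiencies; donor-only molecules are constant E = 0 trajectories.
External distance trajectories are two-column (time, distance) tables whose
time axis may be rescaled by a constant factor (for accelerated-sampling
traces whose physical time scale is unknown, the factor is an explicit user
choice); lookups are nearest-previous-sample.  The shipped MD-adapter demo
uses a synthetic stand-in trace generated by a two-preferred-distance
mean-reverting walk — it exercises the code path, not MD physics.

## Diffusion and photon generation

Molecules diffuse with per-axis Gaussian increments N(0, 2 D_B δt) in a box
(default 8×8×12 μm, reflecting walls; periodic optional).  Reflection is
implemented by folding the free path with the triangle-wave map of period
2L, which has the same law as stepwise reflection and vectorises; chunks
restart from the folded endpoint (valid by the Markov property).

The confocal detection profile is the square of a 3D Gaussian PSF
(excitation × collection efficiency, each with σ = 0.3/0.3/0.5 μm), so the
photon intensity of a molecule at position x is
λ(x) = max_rate · PSF(x)² with max_rate = 200,000 cps at the centre.  The
`detection_exponent` is configurable; the squared profile is the convention
of the established freely-diffusing simulators and is required to reproduce
burst-region statistics (a bare Gaussian profile more than doubles the
effective detection volume).  Counts per engine step are Poisson; each
photon is routed to the acceptor channel with probability E(t) of the
emitting molecule at that step, and timestamps sit on the engine clock tick
(no sub-step jitter — the tick is 3–5 orders of magnitude below the 1-ms
analysis bin).  Entries with λδt below e^{−40} of the peak are skipped;
the expected number of photons lost is ≪ 1 per run.  Background is two
independent homogeneous Poisson processes (1800 cps donor, 1200 cps
acceptor) with uniform tick-quantised arrival times.  Equal quantum yields
and detection efficiencies are assumed throughout, so no γ-factor, leakage
or direct-excitation corrections apply.

Determinism: one root seed spawns independent child generators for initial
positions, conformational dynamics (one per population), diffusion,
emission and background; a (scenario, seed, chunk size) triple reproduces
the photon stream bit for bit.

## Analysis stack

* **Binning**: half-open 1-ms bins anchored at t = 0; apparent efficiency
  Ê = I_A/(I_A + I_D) where the combined count is positive, flagged NaN
  otherwise.  Thresholding keeps bins with combined count **strictly
  greater** than the threshold (default 40).  Burst regions are maximal
  runs of above-threshold bins.
* **Gaussian mixture EM**: in-package EM with k-means initialisation,
  5 restarts, tolerance 10⁻⁶ on the log-likelihood, at most 1000
  iterations; components reported sorted by mean.  A per-iteration
  log-likelihood trace is kept and is non-decreasing by construction.
  Degenerate components (collapsing variance/weight) trigger a restart and
  eventually an error.
* **Skew-Gaussian mixture**: the skew-normal density
  (2/ω)φ(z)Φ(αz), z = (x−ξ)/ω, fitted by ECM using the half-normal latent
  representation X = ξ + Δt + e (t half-normal, e ~ N(0, Γ)); the E-step
  needs only truncated-normal moments and the CM-steps are closed-form.
  Initialisation partitions the sorted sample into quantile blocks with
  moment-matched skewness; exactly symmetric blocks are nudged off the
  α = 0 stationary point.  α = 0 reduces exactly to the Gaussian component.
* **Burst search**: sliding-window rate (m−1)/(t_{i+m−1} − t_i) over m
  consecutive timestamps (default m = 200) against a cps threshold (default
  40,000); a photon is in a burst if any window containing it passes;
  maximal runs form bursts; selection keeps bursts with ≥ 100 photons.
  Zero-span windows (m photons on one tick) count as passing.
* **BVA**: bursts are cut into consecutive non-overlapping n = 10-photon
  sub-bursts (trailing remainder discarded; bursts with < 2 complete
  windows excluded and counted); σ_i is the Bessel-corrected (ddof = 1)
  standard deviation of sub-burst acceptor fractions, compared against the
  static curve √(E(1−E)/n).  With ≥ 10 sub-bursts the residual estimator
  bias (c₄ ≈ 0.97) stays inside the 5% comparison band, which ddof = 0
  would not.  Note that experiment-level background shifts static bursts
  *above* the curve by an amount growing as (E − 0.4)² (background photons
  arrive with acceptor fraction 1200/3000 = 0.4): at E = 0.8 the measured
  mean σ_i sits ~10% high.  The binomial-curve property is therefore
  verified on background-free static simulations, while the
  static-vs-switching contrast is demonstrated at full experimental
  conditions.
* **HMM**: two-state Gaussian HMM fitted by Baum–Welch (hmmlearn) jointly
  across all burst-region apparent-efficiency sequences with shared
  parameters; means initialised at the interior quantiles, sticky-uniform
  transitions, min_covar 10⁻⁴; states reported sorted by ascending mean.
  An all-constant input short-circuits to the single-occupied-state
  solution, which Baum–Welch cannot identify.

## Study sizes

The shipped scenarios default to the full experiment definitions
(single-state: 100 molecules, 10 s, 50-ns step; two-state: 90 molecules,
20 min).  All statistics quoted in the README, the examples and the
acceptance script are computed at desk scale via the `scaled()` knob, which
shortens the duration and coarsens the engine step without touching any
physics parameter:

* single-state mixture analyses: 100 molecules × 2 s at a 2 μs step
  (200 molecule-seconds; component-mean standard errors ≈ 0.01);
* two-state burst-region/HMM analyses: 90 molecules × 120 s at a 10 μs
  step (~1000 burst regions);
* BVA: 90 molecules × 18 s at a 5 μs step (the finer step keeps
  multi-photon ticks rare, so the deterministic within-tick photon
  ordering cannot structure sub-bursts).

The step coarsening is valid because the r.m.s. diffusion step (≤ 50 nm)
stays far below the PSF width and the photon rate per step stays ≪ or ≈ 1.

## What the synthetic data does and does not show

The generator reproduces the coupling of conformational motion,
translational diffusion, shot noise and background that dominates freely
diffusing smFRET statistics.  It does **not** model photophysics
(blinking, bleaching, saturation), detector artefacts (dead time,
afterpulsing, IRF), κ² or linker dynamics, γ-factor asymmetries, or
multi-molecule coincidence beyond what Poisson positioning produces.
Passing analyses here therefore validate the statistical machinery under
ideal photophysics, not robustness to those error sources.  Donor-only
molecules are a static E = 0 population — a labelling defect proxy that
does not stand in for dynamic artefacts like blinking.

## Known limitations

* The Langevin layer is 1D with constant D_L; the Euler–Maruyama stationary
  bias (≈ max_stability/2, relative) is a deliberate speed/accuracy trade.
* Reported HMM state means are biased toward the background acceptor
  fraction for bright-but-not-dominant bursts; this is physics of the
  apparent-efficiency estimator, not a fitting artefact.
* The sliding-window burst search uses one specific local-rate definition
  (stated above); other published variants differ at burst edges.
* Photon-HDF5 output covers the core layout (timestamps + unit +
  detectors) plus a custom molecule-id vector; it is not a complete
  metadata-bearing Photon-HDF5 file.
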