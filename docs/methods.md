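# Methods

This note documents the models, conventions, and numerical choices behind
`cortexval`, and what its synthetic tests do and do not establish.

## Scope and data model

The package grades spiking-network models of local cortical circuits
against the statistics of persistently depolarized network states.  Its
inputs are spike rasters (per-neuron sorted spike times in ms with
excitatory/inhibitory labels) and analog traces: membrane potentials
sampled at 0.1 ms and synaptic currents at 0.05 ms, matching the
resolutions of the intracellular recordings the criteria derive from.
External recordings on other grids are accepted with an explicit
override.

## Spike-train statistics

**Segmentation.** All spike statistics are computed per analysis window —
5 s fixed segments for ongoing activity, or detected Up states — averaged
first across neurons within a window and then across windows with equal
weights.  Only neurons with at least five spikes in a window enter the
irregularity averages (three are needed for the statistics to exist at
all).

**Irregularity.** CV(ISI) uses the sample standard deviation (n−1
denominator) over the mean interval.  The local variation
L_V = ⟨3(T_i − T_{i+1})²/(T_i + T_{i+1})²⟩ over consecutive interval
pairs is less sensitive to rate drift; for a gamma-renewal train of shape
k the two converge to 1/√k and 3/(2k+1), which the test suite verifies at
k = 1 and 4.

**Correlations.** Spike counts are binned in half-open 10 ms bins
anchored at the window start, with a trailing partial bin discarded.  140
neurons are sampled at an 85:15 excitatory:inhibitory ratio (one seeded
draw per analysis; rasters with at most 140 neurons are used whole), and
the mean Pearson coefficient over all sampled pairs is reported.  Pairs
containing a zero-variance count vector are excluded pairwise and
counted.  This measures population co-fluctuation on the 10 ms scale, not
millisecond spike synchrony.

**Burstiness.** The qualitative "no prominent ISI peak below 10 ms" is
operationalized as: a neuron is bursty when the global mode of its ISI
histogram (2 ms bins, 0–200 ms) lies below 10 ms; the population is
bursty when more than half of the neurons with at least 20 intervals are.
Only neurons with enough intervals vote, to keep the mode estimate
meaningful.

## Subthreshold statistics

**Up-state detection.** The membrane-potential distribution in Up-Down
regimes is bimodal.  The detector thresholds at the midpoint between the
two dominant modes of a Gaussian kernel-density estimate (1 mV
bandwidth; a second mode must reach 10% of the main one and lie at least
3 mV away, otherwise the trace is reported as unimodal with no Up
states).  An Up state must stay above threshold for ≥ 400 ms, be flanked
by ≥ 150 ms below it, and show no substantial trend: the fitted linear
slope times the interval length must stay below 20% of the mean
depolarization.  The 400/150 ms durations are part of the criteria; the
trend bound and KDE parameters are package choices where only the
qualitative rule is specified.

**Spike excision.** Statistics of the subthreshold potential exclude
10 ms centered on each spike peak; the mask is inclusive of both grid
endpoints (101 samples at 0.1 ms), and overlapping windows merge.

**CV(V_m).** σ(V_m)/(μ(V_m) − V_rest) within an Up state (or analysis
window), *signed*: strongly fluctuating networks can sit below rest on
average, and the sign carries that information.  For recordings, V_rest
is the mean potential 50–100 ms before the Up transition (falling back to
the global Down-state mean with a warning); for simulations the model's
resting potential is ground truth and is used directly.

**Input fluctuations and drift correction.** The detrended current CV
removes an ordinary-least-squares linear fit before taking
σ(residual)/μ(raw).  When only pooled (undetrended) statistics are
available, the drift model applies: a current with local Gaussian width σ
around a mean decaying linearly from I₁ to I₂ pools to an erf-difference
density whose variance decomposes exactly as σ² + (I₂−I₁)²/12.
`solve_local_sigma` root-finds σ from the pooled standard deviation using
quadrature and cross-checks the closed form; the σ = 0 limit is the
uniform density, and the time-averaged CV is σ/(I₂−I₁)·ln(I₂/I₁) with
the continuous limit σ/I₁ as I₂ → I₁.

**Balance.** Both currents are averaged in non-overlapping 10 ms bins;
the slope and Pearson r of |inhibitory| against |excitatory| bin means
quantify proportionality (magnitudes, so balance gives a positive slope).
The qualitative criterion passes when slope > 0 and r > 0.5.  In a
stationary asynchronous state the dynamic range is small; a gradual drive
ramp (θ from 1.5 to 0.9 in 0.1 steps by default) exposes the
proportionality over a range of activity levels, and the harness accepts
a ramp-derived balance result in place of the stationary one.

## Structural calculators

The PSP of an exponential current J·e^{−t/τ_syn} on a leaky
integrate-and-fire membrane is the β function
(J/C_m)[e^{−t/τ_syn} − e^{−t/τ_m}]/(1/τ_m − 1/τ_syn), with the α-function
limit (J/C_m)·t·e^{−t/τ} at τ_syn = τ_m.  `psp_max` evaluates the peak at
the analytic argmax t* = ln(τ_m/τ_syn)·τ_mτ_syn/(τ_m−τ_syn); this is
validated against dense-grid maximization and against the benchmark
PSC↔PSP pairs (6.3 pA ↔ 0.2 mV at τ_m = 20 ms; 4.7 pA ↔ 0.1 mV and
28.4 pA ↔ 0.6 mV at τ_m = 6.7 ms, all at C_m = 100 pF, τ_syn = 5 ms).

Effective synaptic strength in active networks combines three
multiplicative reductions: the driving-force factor
(E_syn − V_dep)/(E_syn − V_rest) (≈ 0.79 for E_syn = 0 mV, V_rest =
−70 mV, 15 mV depolarization), the shunting factor — the PSP-peak ratio
when τ_m drops, ≈ 0.68 for 21 → 7 ms at τ_syn = 5 ms — and a low-calcium
release factor of 0.31 (the mean of reported 12–50% reductions at in-vivo
calcium).  The combined product is ≈ 0.17 of the resting-slice control.

The volume-averaged connection probability assumes a Gaussian distance
dependence P(d) = P⁰·e^{−d²/2λ²} inside a sphere of radius R with radial
densities ∝ r² and the inter-somatic angle α drawn uniformly on [0, π]
(density 1/π).  The normalized average is
⟨P⟩ = 9P⁰/(πR⁶)·∫₀^R∫₀^R∫₀^π e^{−(r_i²+r_j²−2cosα·r_ir_j)/2λ²} r_i²r_j²,
evaluated by 64-point Gauss–Legendre cubature in all three variables and
cross-checked by Monte Carlo sampling of the same densities.  At R =
270 μm (a ~6,000-neuron column at 70,000 neurons/mm³) and λ = 160 μm
this gives ⟨P⟩ = 0.34 P⁰, hence benchmark probabilities 0.07 (e←e, P⁰ =
0.2) and 0.24 (other types, P⁰ = 0.7).  Note the uniform angle density
is an assumption of this averaging model: for two points placed uniformly
in the sphere the angle density would be sin(α)/2 and the average would
be ≈ 0.29 P⁰ instead.  The calculators implement the 1/π model, which is
the convention the benchmark probabilities are defined under.

## The balanced random network simulator

Leaky integrate-and-fire neurons (V_th = 20 mV above rest, V_r = 10 mV,
τ_m = 20 ms, C_m = 100 pF in the classic configuration) with
exponential-current synapses (τ_syn = 5 ms) on a fixed grid, dt =
0.05 ms.  The subthreshold system (V, I_e, I_i) is linear, so each step
applies its exact propagator: V ← V_rest + e^{−dt/τ_m}(V − V_rest) +
p·(I_e + I_i), I ← e^{−dt/τ_syn}·I with p the exact one-step
current-to-voltage kernel.  A single injected PSC therefore reproduces
the analytic β-function peak to better than 10⁻⁴ relative (a test
asserts this), and spike times are limited to the grid: threshold is
checked once per step, the potential resets to V_r and is clamped for
τ_ref, giving a minimum ISI of exactly τ_ref + dt.

**Wiring.** Every neuron draws a fixed number of presynaptic partners
without replacement, excluding itself — C_e = N_e·p excitatory and C_i =
N_i·p inhibitory in the uniform configurations (800 and 200 for N_e =
8000, N_i = 2000, p = 0.1) — so there are no autapses and no multapses.
The per-type configurations use in-degree round(N_source·p_type).
Inhibitory weights are −g·J with g = 5; the three non-e←e weights can be
scaled by factors k_e←i, k_i←e, k_i←i for parameter scans.

**External drive.** Each neuron receives an independent Poisson stream of
excitatory PSCs of amplitude J at rate θ·ν, where ν = (V_th −
V_rest)·C_m/(J·τ_syn·τ_m) is the rate at which the stationary mean
potential of an isolated passive neuron equals threshold (each event
deposits charge J·τ_syn, and mean potential is current × τ_m/C_m).  For
the classic configuration ν ≈ 3.17 events/ms; a test drives passive
neurons at exactly ν and verifies the stationary mean reaches the nominal
threshold.  Modeling the drive as one aggregate Poisson process per
neuron matches the first two moments of a population of independent
sources and is the standard construction.

**Protocols.** `excitability_test` switches the drive off after a warmup
(≥ 500 ms) and reports the survival time — the time until the population
rate first stays below 0.1 spikes/s for 50 ms (both numbers are package
choices for the qualitative "activity dies out").  `self_sustained_test`
stimulates a resting network with 50 ms of drive at θ = 2, then runs
drive-free and reports the mean excitatory rate over the following
1000 ms.  `ramp_drive` applies a piecewise-constant θ schedule.
`parameter_scan` sweeps the k-factors over a grid with several seeds and
tabulates all activity metrics per cell, flagging diverged cells.

**Initial conditions and warmup.** Membrane potentials start uniformly in
[V_rest, V_th) (seeded) for driven runs and at rest for stimulation
protocols.  Analyses discard a 500 ms warmup by default; this removes the
partially synchronous startup transient, and slightly lowers measured
correlations relative to analyses that include it.

**Recordings.** Membrane potentials of a configurable subset (50
excitatory neurons by default) are decimated to 0.1 ms; excitatory and
inhibitory current components are kept at 0.05 ms, matching the analyzer
dialects.

**Problem sizes in the shipped tests and acceptance script.** The
acceptance script analyzes three 5 s trials of the classic network and
three 4 s trials of the strong-synapse network (whose chaotic rate
dynamics fluctuate slowly, making short windows noisy); the test suite
analyzes 2 s per trial.  These windows are the package's chosen
trade-off between estimator variance and run time.

## Grading

Quantitative criteria grade green when the deviation from the target does
not exceed 20%, yellow up to 60%, red beyond.  For ranges, deviation is
the relative distance to the nearest boundary (inside is green); for the
correlation upper bound, values below the bound are green regardless of
distance; point targets ("≈" criteria) use the relative distance to the
target.  Qualitative criteria (balance, burstiness) pass green or fail
red.  "Sustained for hundreds of milliseconds" grades green at ≥ 300 ms
survival and yellow at ≥ 100 ms; "V_th − V_rest ≫ PSP_e←e" grades green
at a ratio ≥ 20 and yellow at ≥ 10.  Composite criteria take the worst
sub-grade.  Criteria whose inputs are absent (no membrane-potential
recording, no excitability run) are reported `not_applicable` rather than
guessed.

## Synthetic data

The fixtures module generates inputs with exact ground truth:
gamma-renewal rasters (known CV, L_V, rate), trains thinned from a common
Poisson mother train (pairwise count correlation exactly p at any bin
width), telegraph Up/Down membrane potentials with Ornstein–Uhlenbeck
noise (10 ms correlation time — white noise at 0.1 ms sampling would
inflate sample CVs beyond anything physiological), and linearly drifting
noisy currents (known local σ).  These establish that the analyzers
recover known statistics; they do not emulate the full structure of real
recordings — no spike-sorting artifacts, no electrode correlations, no
non-stationarity beyond the modeled drift — so passing tests validate
the estimators, not the biology.

## Known limitations

- Conductance-based synapses are out of scope; the balance criterion is
  current-based.
- The simulator has no spatial wiring; distance dependence is handled
  analytically in the structural calculators.
- The drive-free state of the strong-synapse network is metastable in
  this implementation: after brief stimulation, activity persists for a
  few hundred milliseconds before dying out, so the reported
  self-sustained rate depends on the (fixed, documented) 1 s observation
  window.  Lifetimes of such fluctuation-driven states are known to be
  stochastic and sensitive to network size and parameters.
- Up-state detection assumes a bimodal potential distribution; regimes
  with blurred Down states are reported as unimodal rather than
  segmented.
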