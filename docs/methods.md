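# Methods

This note documents the models implemented in `holotus`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Acoustic holography

**Array.** The transducer is modelled as N point monopoles on a spherical
cap (default N = 512, 150° angular coverage, 40 mm radius of curvature,
3 MHz). The radius of curvature is a configurable default: at fixed
angular coverage the focal dimensions depend on the f-number, i.e. on the
coverage angle, and only weakly on the radius itself. Elements are laid
out on an equal-area Fibonacci spiral, which is deterministic and
quasi-uniform (nearest-neighbour spacing CV < 0.3). Elements are ideal
point sources: no directivity, no skull aberration. Calibration is a
single scalar applied to the whole field so the focal peak matches a
requested pressure — the computational stand-in for a hydrophone
measurement through the skull.

**Delay laws and holograms.** Focusing a (sub)array at a target uses
time-of-flight delays `(max_j d_j − d_i)/c`. Multi-focus holograms split
the element set into equal random subsets (remainder elements stay
silent, giving the 170/102 per-focus counts for triangle/pentagon
patterns), one subset per focus. Random interleaved subsets keep each
focus at the full-aperture resolution at the cost of an incoherent
background pedestal — both effects are captured by the synthesis.

**Field synthesis.** Continuous-wave monochromatic superposition
`p(x) = Σ A e^{(ik−α)r_i}/r_i · e^{iωτ_i}` with particle velocity from the
analytic monopole gradient. A frequency-domain solver is equivalent to
time-domain stepping for linear CW fields and is used throughout. Grid
spacing must satisfy λ/6 (default 40 µm at 3 MHz).

**Focal widths.** `measure_fwhm` interpolates the half-maximum crossings
of the 1-D profile through the global maximum, on the pressure amplitude
by default or on the intensity. The simulated free-field focus measures
331/814 µm (pressure) and 243/598 µm (intensity) lateral/axial; since the
experimental characterization reports ~250/~560 µm, the intensity-based
convention evidently matches the instrument and is used for comparisons
with those figures.

**Intensity, power and radiation force.** `I_SPPA = |p|²/(2Z)`; acoustic
power integrates the axial intensity `½Re(p v_z*)` over the focal plane,
optionally windowed. Radiation force comes in three forms:

* *absorption*: density `f = 2αI/c` along the local intensity vector —
  the plane-progressive limit, appropriate inside absorbing tissue;
* *momentum flux*: `f = −∇·Π` with the time-averaged Brillouin tensor
  `Π_ij = (⟨p²⟩/2ρc² − ρ⟨v²⟩/2)δ_ij + ρ⟨v_i v_j⟩`, by central
  differences; it reduces to the absorption form for an attenuated plane
  wave (tested at 5%) and integrates to ~0 over a lossless source-free
  region;
* *beam momentum budget*: `F = P_ac/c`, the rate of momentum carried
  through the focal plane. For a beam ultimately absorbed in tissue this
  is the total force it exerts. The grid integral of the absorption
  density captures only the fraction of the beam absorbed inside the
  grid (~16 % over a 6 mm brain path at 3 MHz), so total-force
  comparisons use the momentum budget.

For the threshold-force comparison the fields are synthesized in
hydrophone-calibration water (ρ = 1000 kg/m³, c = 1500 m/s) — mirroring
calibrated linear simulations — with brain absorption
(0.6 dB·cm⁻¹·MHz⁻¹) entering only the momentum conversion. At the
experimental detection thresholds (single focus 2.5 MPa; 0.5 mm triangle
0.9 MPa per focus) both configurations carry ~0.1 W of acoustic power and
a beam force of 0.08–0.13 mN: threshold pressures differ by almost 3×,
total radiation force by less than 2× — the "unified force threshold".

Within the excitation model, beam power/force are windowed to the same
3 × 3 mm² focal region as the excitability integral, so the two
descriptions of a configuration remain mutually consistent (the random-
subset pedestal otherwise leaks power out of the window for holographic
patterns only).

## Thermal models and the fluorothermal correction

The Pennes bioheat solver is an explicit FTCS scheme (stability bound
`dt ≤ dx²/6κ`, checked) with the absorbed intensity `q = 2αI` as source,
Dirichlet (arterial, 37 °C) boundaries, and brain defaults ρ = 1040 kg/m³,
c_p = 3650 J/(kg·K), k = 0.527 W/(m·K), perfusion coefficient
3.6 × 10⁴ W/(m³·K).

The reduced model `τ dΔT/dt = γ I_SPPA(t) − ΔT` (exact per piecewise-
constant intensity; one time constant for heating and decay; τ = 100 ms
default) reproduces the PDE's focal transient within 15 % once (γ, τ) are
calibrated against it. Neither model predicts absolute in vivo
temperature; the default gain is anchored so a 150 ms pulse at 2.2 MPa
ends at ΔT = 0.4 K, consistent with the ~0.5 % fluorothermal quenching
dip observed at threshold pressures and a GCaMP thermal sensitivity of
1–2 %/K. This anchor also keeps the thermal influence on network
excitability small (<10 % threshold shift), as observed experimentally.

The FTT correction scales the temperature transient affinely so it equals
the measured ΔF/F at the pulse onset and end, inverts its sign, and adds
it to the trace; the anchor points are restored exactly and the correction
is applied before temporal smoothing, never after.

## Ultrasound excitation model (USEM)

The excitability transfer is threshold-linear `E(D) = max(D − θ, 0)` by
default (a power-law option is provided); its exact published functional
form is not available, so this is an explicit reconstruction. The APD map
is E applied to the focal-plane descriptor; `X` integrates it over a
centred 3 × 3 mm² window (the window covers `round(3 mm / pixel)` pixels,
so it is exact on 40/50/60 µm grids). Descriptor maps scale linearly (|p|)
or quadratically (force, intensity) with the focal calibration pressure,
so per-configuration unit maps make fitting cheap.

The fit is bounded nonlinear least squares (threshold θ, log-midpoint,
log-steepness, ceiling; floor fixed at 0) with 10 seeded random restarts,
on responses normalized to [0, 1] by the dataset maximum. On synthetic
dose–response data (σ = 0.05 of the response scale) the generating
midpoint is recovered within 10 %; a force-descriptor fit beats a
pressure-descriptor fit on force-generated data. With the force
descriptor, the configurations' predicted 50 %-probability pressures map
to total (windowed) beam forces that collapse within 20 %, while the
pressures themselves differ by >1.5× — the model's account of why peak
pressure alone cannot unify single-focus and holographic thresholds.

The experimental dose–response points are not published as numbers; the
shipped datasets are synthetic (from `holotus.synthdata`, with ground
truth), and a user CSV with columns
`configuration, pressure_mpa, response[, sem]` drops in directly.

## Cortical network model (sCNM)

Each node is a cortical regular-spiking conductance-based point neuron:
C_m = 1 µF/cm²; g_Na = 56, g_Kd = 6, g_M = 0.075, g_Leak = 0.0205 mS/cm²;
E_Na = 50, E_K = −90, E_Leak = −70.3 mV; rate-law threshold shift
V_T = −56.2 mV; M-current τ_max = 608 ms. These are the canonical
regular-spiking values; the study's exact table is not available, so they
are documented reconstructions, all exposed in `NodeParams`.

**Stimulus.** `I_TUS = −k·P` (constant, depolarizing) during the 150 ms
pulse on sonicated nodes — a deliberately mechanism-agnostic
transduction. k is calibrated by bisection so an isolated node's
detectable-response threshold (≥3 evoked spikes, 50 noise realizations)
is 2.2 MPa; the default k = 0.521 µA·cm⁻²·MPa⁻¹ is the seed-averaged
calibration. "Evoked" spikes are counted in
[pulse start, pulse end + 50 ms] minus a matched no-stimulus run with
identical noise, so spontaneous activity cancels in expectation.

**Temperature.** The reduced thermal model drives Q10 scalings of gating
rates (Q10 = 3.0) and of Na/K maximal conductances (1.40/1.50), plus a
thermally activated K⁺ conductance g_KT = 0.01 mS/cm² per K (E_K
reversal), all confined to sonicated (heated) nodes.

**Noise.** An Ornstein–Uhlenbeck current with stationary std 2 µA/cm² and
0.25 ms correlation time. The correlation time is the one genuinely free
choice here: it sets how the stated amplitude translates into membrane-
voltage fluctuation. 0.25 ms yields a few-mV fluctuation with rare
spontaneous spikes, which is the regime in which the model reproduces the
observed phenomenology — the network's single-focus threshold stays near
the isolated-node calibration while holographic co-stimulation still
halves it; a substantially longer correlation time makes resting nodes
spike spontaneously and erodes the single-focus threshold through
noise-synaptic facilitation.

**Synapses.** AMPA-like: presynaptic upward crossing of 0 mV (2 ms
refractory) increments the postsynaptic activation, which decays with
τ = 5 ms; E = 0 mV. The weight (0.05 mS/cm²) was tuned once to satisfy,
simultaneously: a single stimulated node does not fire its silent
neighbours (deterministically exact); co-stimulating all three nodes
yields more than 3× the single-node spike count; and the all-node
threshold falls below half the single-focus one. Under noise,
non-sonicated neighbours of a strongly driven node do show occasional
evoked spikes (~2 per pulse), but remain below the 3-spike detection
level.

**Integration.** Exponential Euler for gates, forward Euler for voltage,
dt = 25 µs (refined-dt agreement within 5 % on firing rate), compiled
with numba; realizations are integrated in batch. Identical seeds give
bit-identical trajectories. Threshold bisection (0.02 MPa bracket) reuses
one seed across probe pressures (common random numbers); the
50-realization threshold estimator has a seed-to-seed std of ~0.1 MPa, so
sub-0.05 MPa statements are meaningful only under matched realizations,
which is how calibration round-trips are defined.

## Imaging pipeline

The stage order is fixed: Kalman → baseline → cycle average → spatial
Gaussian → trace extraction → FTT correction → Savitzky–Golay. The
"Kalman" stage is the fixed-gain recursion
`x̂_t = g·x̂_{t−1} + (1−g)·x_t` (g = 0.5, seeded with frame 0) — a
documented approximation of the stack-filter behaviour, reducing white
temporal variance to (1−g)/(1+g) = 1/3. The baseline is the per-pixel
10th percentile of non-overlapping 500-frame segments, linearly
interpolated between segment centres (non-overlapping and linear are
choices; a percentile baseline leaves a small positive bias
≈ 0.4·W/τ_bleach on monotone drifts). ΔF/F is expressed in percent
throughout. Cycle averaging aligns to stimulus onsets (onset = frame 0 of
the averaged stack). The activated area uses 4-connected flood fill from
the seed; a sub-threshold seed returns an empty area by convention. AUC
uses trapezoidal integration with interpolated window edges.

## Synthetic data

Movies are generated as
`F = F₀·bleach(t)·(1 + (rest + evoked − dip)/100) + noise` with every
component returned as ground truth. The evoked kernel is a
difference-of-exponentials (0.3 s rise, 1 s decay) mimicking GCaMP6f;
the footprint σ = 400 µm matches the ~1–2 mm² activated areas seen in
widefield data (the calcium response is wider than the acoustic focus);
the dip follows the reduced thermal transient (τ = 100 ms, σ = 300 µm,
0.5 % depth); the resting background is spatially smoothed, 0.15 Hz
low-passed Gaussian noise at 0.8 % amplitude — it emulates the slow
anaesthesia-related activity's second-order statistics only, not its
spatial topography, travelling waves, or hemodynamic coupling. Passing
recovery tests therefore demonstrates pipeline correctness under
realistic amplitude/noise/drift conditions, not robustness to every
structure in real recordings. End-to-end, the pipeline recovers a 2 %
evoked peak within 15 % and localizes it within 2 px.

## Problem sizes and determinism

Default analysis sizes: acoustic grids of 1–1.5 M voxels at 40 µm
(single-CPU synthesis in ~1 min), network thresholds from 50 noise
realizations with 0.02 MPa bisection tolerance, synthetic movies of
64 × 64 × 4040 frames. All stochastic paths take explicit integer seeds;
every CLI run records its resolved configuration in a manifest.

## Known limitations

* Linear acoustics only; no skull aberration, nonlinearity, or element
  directivity — absolute pressures rest on the single-scalar focal
  calibration.
* The momentum-flux force density is the standard inviscid Brillouin
  form; the exact published tensor expression was not reproducible from
  the available text.
* Thermal and excitability parameters (τ, γ, Q10s, g_KT, synaptic weight,
  noise correlation time) are reconstructions calibrated to reported
  behaviour, not fitted to the study's unavailable parameter tables.
* The three-node network abstracts local populations to single points and
  omits inhibition; it reproduces threshold phenomenology, not cortical
  dynamics at large.
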