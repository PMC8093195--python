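# Methods

This note documents the models, estimators and numerical choices behind
`ephyskit`, and what the synthetic-data experiments do and do not show
about real recordings.

## Scope and data model

The package analyzes whole-cell patch-clamp sweeps: paired voltage (mV)
and current (pA, or command mV in voltage clamp) series sampled at
10–20 kHz with an annotated stimulus epoch. Sweeps travel in a plain-text
format (a `# key: value` header plus two data columns, one file per
sweep, a CSV manifest per cell) chosen for diffability and language
neutrality; an NWB reader is optional and feature-flagged behind the
`pynwb` extra. Voltages are never junction-corrected anywhere in the
pipeline; the junction potential is computed and reported only.

## Liquid junction potential

`junction.henderson_junction_potential` evaluates the Henderson equation
with a built-in table of relative ionic mobilities (limiting molar
conductivities at 25 °C scaled to K⁺ = 1; gluconate 0.33, HEPES⁻ 0.30,
ATP²⁻ 0.24), overridable per species. The default temperature is 33 °C,
the midpoint of a 32–34 °C recording bath. HEPES is treated as
half-anionic at pH 7.4 (its pKa); salts are taken as fully dissociated.
For the K-gluconate internal (K-gluconate 135, NaCl 10, HEPES 10, MgCl₂
1, Na₂ATP 2, GTP 0.3 mM) against standard aCSF the computation gives
**−14.6 mV** (pipette relative to bath). Published calculators give −14
to −16 mV for comparable K-gluconate internals; values near −11 mV are
only obtained with a much faster (acetate-like, ≈0.55) gluconate
mobility, which no standard table supports. The implementation was
checked against an independent scalar evaluation and the classic
150 mM KCl | 150 mM NaCl worked example (+4.3 mV bath-positive at
25 °C). The Henderson result is antisymmetric under solution exchange
and invariant to a common concentration rescaling; both are asserted as
properties.

## Stimulus protocols

Three generators provide the stimuli for both real-data analysis and
simulation, as pure functions of their parameters:

* **Current steps** — rectangular, default 600 ms, −400…+400 pA in 50 pA
  increments with 100 ms pre- and 300 ms post-baseline.
* **ZAP / chirp** — constant-amplitude sine with linearly swept
  frequency, default 1→20 Hz over 20 s at 10 kHz, zero initial phase.
  Linear sweep is the convention of the impedance literature; an
  exponential sweep is available by option.
* **Frozen filtered noise** — Gaussian white noise convolved with a
  unit-sum 3-ms boxcar, plus a DC offset; 2.5 s per trial, 30 trials.
  "Frozen" means bit-identical output for an identical seed. Because the
  kernel has unit sum, the `noise_sd` parameter is the *pre-filter* sd;
  the post-filter sd is `noise_sd / sqrt(M)` with `M` the kernel length
  in samples (≈ `noise_sd`/5.5 at 10 kHz).

## Synthetic neuron

`sim.ModelParams` defines a single-compartment conductance model:

    C dV/dt = −gL (V − EL) − gh m (V − Eh) − w + gL ΔT e^{(V−VT)/ΔT} + I(t) + ξ(t)
    dm/dt   = (m∞(V) − m)/τ_h,  m∞(V) = 1/(1 + exp((V − V50h)/k_h))
    dw/dt   = (a (V − EL) − w)/τ_w

i.e. leak + HCN current (first-order gating that activates with
hyperpolarization) + adaptive exponential spike initiation. When the
voltage crosses the numerical spike cut (VT + 5ΔT) a stereotyped action
potential — piecewise-linear rise/fall plus an after-hyperpolarization
descent, peaking above 0 mV so overshoot detection applies — is pasted
into the trace, `w` jumps by `b`, and integration resumes from the AHP
trough. Pasting keeps ground-truth spike times exact (the waveform peak
sample), which the detector tests rely on. Integration is fixed-step
forward Euler at the stimulus sampling interval with optional substeps
(default 2); intrinsic current noise is drawn per *sample*, so halving
the substep does not change the noise realization and a convergence
check (subthreshold voltage changing < 0.1% under step halving) is
meaningful. Defaults describe a human L5-like regular-spiking pyramid:
C 200 pF, gL 10 nS, EL −70 mV, gh 4 nS, Eh −30 mV, V50h −90 mV, k_h
9 mV, τ_h 50 ms, VT −55 mV, ΔT 2 mV, b 100 pA, τ_w 150 ms, AP half-width
1.8 ms. These give RMP ≈ −68 mV, rheobase 150 pA, sag ≈ 5 mV at
−400 pA, adaptation index ≈ 0.1–0.2.

An ideal voltage-clamp mode integrates the gating equation along the
command and returns `gL(V−EL) + gh·m·(V−Eh)` plus a one-sample
capacitive transient at command transitions (leak + Ih only, emulating
pharmacological isolation).

`sim.linearized_impedance` is the quasi-active small-signal oracle:

    Z(f) = [ gL + gh m∞(V*) + i2πfC + gh (V*−Eh) m∞′(V*) / (1 + i2πf τ_h) ]⁻¹

whose argmax provides the analytic resonance frequency against which the
empirical ZAP pipeline is checked. With gh = 0 it reduces exactly to the
RC closed form.

**Cohorts.** `make_cohort` samples cells from archetype distributions
(normal jitter on C, gL, EL, gh, truncated to stay physical) and runs
the chosen protocols. The layer archetypes encode only the *direction*
of the laminar contrasts — mean gh L5 (5 nS) > L3c (3) > L2&3 (1.5),
more depolarized EL and slower τ_m in deeper layers — never exact group
means. The classification archetypes are constructed so their defining
labels hold by mechanism: bursting pyramids reset near the spike cut
(AHP depth 1.5 mV → a rheobase doublet at ≈190 Hz), regular pyramids
carry strong spike-triggered adaptation (b = 100 pA; first ISI at
rheobase + 50 pA ≈ 50 Hz, safely under the 75 Hz criterion), and
fast-spiking interneurons combine a 0.6 ms pasted AP, 15 mV AHP and a
large-but-fast adaptation increment (b = 120 pA, τ_w = 10 ms) so their
onset rate stays below 75 Hz while the steady maximal rate exceeds
110 Hz. Subthreshold ZAP amplitudes are found by a descending
acquisition-style search for the largest non-spiking amplitude; noise DC
offsets are stepped up until the mean rate exceeds the >5 Hz criterion.

## Feature extraction

* **Passive/sag/rebound** — baseline and steady-state windows are the
  final 100 ms before onset and of the step (window lengths are
  configurable; they are analysis choices, not measurements). Sag
  amplitude = V_ss − V_min, sag ratio = (V_ss − V_min)/(V_base − V_min),
  measured by default on the −400 pA sweep. Rebound amplitude references
  the pre-stimulus baseline (referencing the in-step steady state would
  make it degenerate with the deflection size); rebound spikes are
  detected by overshoot and masked ±5 ms before the post-step maximum is
  taken. Input resistance is the least-squares slope of steady ΔV vs
  current over sweeps in [−200, −50] pA; τ_m is a single-exponential fit
  from onset to the first in-step extremum (stopping there keeps the sag
  rebound out of the fit), averaged over qualifying sweeps.
* **Spikes** — overshoot mode (peaks > 0 mV, 2 ms refractory margin) is
  the default everywhere and mandatory for gain/resonance; dV/dt mode
  (20 mV/ms criterion, configurable) is available. AP features come from
  the first spike of the rheobase sweep: threshold at the dV/dt
  criterion (walking back from the peak), half-width at
  threshold + amplitude/2 with linear interpolation at the crossings,
  upstroke–downstroke ratio from the dV/dt extrema, AHP relative to
  threshold within 50 ms. The hero sweep is the sweep closest to
  rheobase + 50 pA within [+39, +61] pA, ties toward the smaller
  amplitude; firing rate is count ÷ step duration. The adaptation index
  is the mean of (ISI_{i+1} − ISI_i)/(ISI_{i+1} + ISI_i).
* **Classification** — bursting iff the instantaneous frequency of the
  first ISI exceeds 75 Hz at rheobase (else evaluated at rheobase +
  50 pA); putative interneuron iff half-width < 1 ms AND AHP > 10 mV AND
  maximal rate > 75 Hz, where the maximal rate is taken over the
  recorded step family.

## Impedance and spike-probability analysis

The impedance profile is |V̂(f)/Î(f)| (MΩ) over the ZAP band, voltage
averaged over up to five non-spiking trials, smoothed by a centered
moving average of 0.5 Hz width ("window averaging"); fR is the smoothed
argmax searched from 0.5 Hz, and a cell is resonant when fR > 0.5 Hz
*and* the peak is interior to the band (an edge maximum is reported but
non-resonant). The cutoff frequency uses |Z| = |Z(fR)|/√2 by default;
the half-magnitude convention (0.5) is available because the two
conventions disagree (half amplitude is −6 dB) and the field uses both.
Sweeps should include a short rest period before and after the chirp
(the simulator records 0.5 s): capturing the response tail keeps the
band-edge bins accurate (edge error 0.4% with rest vs 2% without on the
RC benchmark). Suprathreshold densities assign each spike the
instantaneous stimulus frequency at its time (relative to stimulus
onset); group comparisons use the two-sample KS test on the pooled
per-spike samples, never on the binned histograms.

## Frequency-dependent gain

The rate signal is 1/Δt at spike samples and 0 elsewhere (its integral
is the spike count, asserted as a property). Correlations c_sr and c_ss
are estimated per trial on a ±1 s lag grid, normalized by the overlap
count at each lag (the unbiased estimate of the expectation — a
taper-biased estimator visibly attenuates low-frequency gain on 2.5-s
trials), and averaged over trials so no estimate crosses a trial
boundary. For each analysis frequency (2–100 Hz in 0.2 Hz steps, 491
points) both correlations are multiplied by a zero-centered Gaussian
window with σ = 1/f and transformed at f; G(f) = |C_sr|/|C_ss| and
φ(f) = arg C_sr − arg C_ss (four-quadrant — a two-quadrant arctangent
cannot represent the phase), with a delay-corrected variant
φ + 2πf·τ_delay wrapped to (−π, π], τ_delay being the c_sr peak lag, so
a pure transmission delay maps to zero corrected phase. Group comparison:
one pooled G(f) per cell, cells with mean rate > 5 Hz, two-sided
rank-sum per frequency, Benjamini–Hochberg step-up FDR at α = 0.01.

**Validation regime.** The sinusoidal-perturbation oracle measures the
rate-modulation amplitude per unit probe amplitude using *paired*
+sine/−sine trials on a shared noise background; half the difference of
the complex rate components cancels every stimulus-independent
contribution exactly (the trial-onset transient is phase-locked to the
stimulus clock and otherwise produces a spurious 1/ε term). Probe
frequencies get separate trial sets because harmonically related probes
(5/10/20 Hz) cross-contaminate through rate-rectification harmonics.
The comparison runs in a fluctuation-driven regime — sub-rheobase DC,
intrinsic noise dominant, ISI CV ≈ 0.8 — because a tonically firing
(supra-rheobase) model is a noisy oscillator whose small-signal
susceptibility near its firing rate genuinely exceeds the noise-probe
gain through partial entrainment; that mismatch is a property of the
neuron, not of either estimator. The in-silico ZD7288 analogue (gh = 8
vs 0 nS, same frozen stimuli) uses a non-adapting cell with HCN1-like
depolarized activation (V50 −70 mV, k 4 mV, τ_h 80 ms) so the gating
feedback is engaged at the inter-spike potential and its low-frequency
gain elevation (peak over 3–8 Hz relative to the 2–2.5 Hz floor) is
read out in isolation from spike-frequency adaptation, which otherwise
dominates that band's shape in both conditions.

## Voltage-clamp Ih

Windows: 10 ms capacitive blanking after each transition, instantaneous
current at 10–30 ms, steady state over the final 50 ms, tail search
within 150 ms of the return to holding. Ih amplitude is |steady −
instantaneous| per step (−60…−140 mV from −60 mV holding); the tail
amplitude is the residual-current extremum relative to the settled
holding current. The activation curve fits base + amp·Boltzmann(V; V50,
k) — fitting the scale explicitly instead of min–max normalizing keeps
V50 and k unbiased when the protocol does not span the full activation
range, makes refitting the fitted curve exactly idempotent, and the
reported activation is (tail − base)/amp clipped to [0, 1]. Kinetics
fits single and double exponentials and selects the double model only
when its small-sample-corrected AIC improves by more than 2.

## Cohort assembly and embedding

The per-cell vector holds exactly 14 features (RMP, input resistance,
τ_m, sag ratio, sag amplitude; AP threshold, amplitude, half-width,
upstroke–downstroke ratio, AHP amplitude, rheobase, latency; f–I slope,
hero-sweep rate) with an explicit completeness mask; adaptation and ISI
statistics are carried in the cohort table but stay outside the vector.
For embedding, cells missing more than 2 features are dropped (and
reported), the rest median-imputed, features standardized to zero mean
and unit variance, and UMAP run with default parameters and a fixed
`random_state`, which makes the embedding deterministic per seed.
Group statistics: two-sided rank-sum for independent groups,
matched-pairs signed-rank for paired designs (identical pairs return
p = 1 by convention, since no nonzero differences exist).

## Pipeline

`pipeline.run_cohort_analysis` walks a cohort directory, applies every
analysis its protocols support, isolates per-cell failures
(skip-and-report — heterogeneous real recordings should not abort a
cohort), and writes CSV tables plus a JSON provenance record (package
version, seed, parameters). Reruns with identical config and seed are
bit-identical, including the embedding.

## Problem sizes in the validation suite

The shipped experiments use: one 20-s ZAP per impedance check; three
quasi-active parameter sets; 30 frozen-noise trials for each
correlation-method gain (the protocol's trial count) and 240 paired
oracle trials per probe frequency at ε = 8 pA; 3 paired seeds for the
ZD analogue; 100 noise seeds for Boltzmann recovery; 300 null
replicates for type-I calibration and 10 for the FDR null; 60 cells
(20 per archetype) for classification fidelity; 12 cells for the
determinism check.

## Limitations

The simulator is a single compartment: no dendritic Ih gradients,
morphology or space-clamp artifacts, so voltage-clamp quantification is
exact in a way real somatic clamp is not, and resonance lacks dendritic
contributions. Pasted AP waveforms make spike shape features inputs
rather than emergent properties — classification fidelity demonstrates
the *rules*, not biophysical discriminability. Synthetic cohorts encode
direction-of-effect contrasts, not the study's group means, so passing
tests certify the estimators and rules, not population-level
reproduction. The junction-potential module reproduces the Henderson
equation with standard mobilities; its output for the study's solutions
(−14.6 mV) is a calculation, subject to the usual Henderson-equation
approximations (no activity corrections, free diffusion boundary).
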