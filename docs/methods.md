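# Methods

`navkit` studies how a mixed gain/loss-of-function NaV1.1 (SCN1A) variant
— L1624Q, which increases persistent current, accelerates fast-inactivation
onset, and reduces current density at physiological temperature — shapes
both whole-cell channel behavior and cortical neuron excitability.  It has
four parts: a synthetic voltage-clamp generator with known ground truth, a
whole-cell analysis suite, the genotype x temperature statistical plan, and
a conductance-based neuron model.

## Synthetic voltage-clamp generator

Real recordings of this kind are not publicly archived, so every analysis
stage is exercised against generated sweeps whose ground truth is known
exactly.  The generator is deliberately *phenomenological*: a sweep is a
stylized pulse, not the output of an m^3h kinetic scheme.  For a step to
voltage V:

- peak amplitude `I_pk(V) = -density * C_m * a_inf(V)(V - V_rev) /
  (a_inf(0)(0 - V_rev))`, so the 0 mV sweep peaks at exactly
  `density * C_m` (inward-negative), with `a_inf` an ascending Boltzmann
  (V1/2 = -22 mV, k = 7 mV by default);
- a 0.1 ms normalized-exponential rising ramp (the analyses never fit the
  rising phase; it exists so the peak is well defined on the sample grid);
- after the peak, single-exponential decay with the phenotype's tau(V)
  toward the plateau `f_persistent * I_pk`.

Steady-state fast-inactivation (SSFI) sweeps scale the 0 mV test-pulse
peak by a descending Boltzmann of the prepulse voltage; recovery sweeps
scale it by `1 - A_f e^(-t/tau_f) - (1-A_f) e^(-t/tau_s)`.  This gives the
analysis stage an invertible contract: on noise-free input every measured
quantity equals its generative parameter to machine precision, which the
round-trip tests assert at 1e-3 relative tolerance.

Packaged phenotypes install the measured values of the study system:
persistent fractions 0.95% / 3.20% (22 degC) and 2.27% / 4.58% (37 degC)
for WT / L1624Q, current densities 72.82 / 45.42 pA/pF at 37 degC, and
onset time constants for L1624Q at 37 degC equal to the WT table divided
by 1.485.  Quantities reported only graphically in that system carry
representative NaV1.1 defaults, all overridable and none asserted in
tests: activation V1/2 -22 mV / k 7 mV, reversal +65 mV, SSFI V1/2 -60 mV
(right-shifted +4 mV at 37 degC; the shift direction is an observed
temperature effect, its magnitude is our choice) / k 6 mV, WT tau(0 mV)
0.8 ms at 22 degC and 0.35 ms at 37 degC, recovery tau 2 / 50 ms with 90%
fast fraction, 22 degC density 60 pA/pF for both genotypes (no genotype
difference at room temperature).

Cohorts perturb density, the tau table, and the persistent fraction by
independent mean-1 log-normal factors with a chosen fractional SD
(default 15%), and draw capacitance the same way around 15 pF; recording
noise is i.i.d. Gaussian per sample.  What the generator does *not*
emulate: series-resistance and leak-subtraction artifacts, amplifier
filtering, rundown, space-clamp error, or genuine kinetic coupling between
activation and inactivation.  Passing tests therefore certify the analysis
code's correctness on idealized sweeps, not robustness to instrument
pathology.

## Whole-cell analysis

Peaks are signed extrema after baseline subtraction, excluding the first
0.05 ms of each step (the stylized rising region).  Conductance is
`G(V) = I_pk/(V - V_rev)` with V_rev estimated from the zero crossing of
the peak I-V by linear interpolation (an override is available),
max-normalized and fitted with an ascending Boltzmann.  Onset time
constants come from single-exponential-plus-offset fits from the peak to
the end of the step, reported on the -30..+20 mV grid.  The persistent
fraction divides the mean |current| over the final 2 ms of the 50 ms pulse
by the peak ("end of pulse" is not otherwise defined; 2 ms is our
operationalization), with the 25-30 ms window recomputed as a
stabilization check that warns above 20% relative disagreement.  Recovery
fractions (test/conditioning peak per sweep) are fitted with the
double-exponential form; when the two time constants collapse within 5%
the fit falls back to a single exponential and is flagged degenerate.

All fits are deterministic by construction: Boltzmann fits initialize at
the interpolated half-maximum voltage with k0 = 7 mV; exponential fits take
tau0 from the log-linear slope of the first decade of decay.  SSFI curves
are normalized per-cell to the maximum test-pulse peak (whether the source
analyses normalized to the fitted asymptote instead is unstated; per-cell
max is used).  Reported tau curves are per-cell fits, aggregated afterward.

## Statistics

The plan is a fixed-effects two-way ANOVA with the genotype x temperature
interaction as the test of differential temperature sensitivity; when the
interaction is not significant at alpha = 0.05 the model is refit
additively and main effects are evaluated independently (Type-II sums of
squares, which matter for the unbalanced 37 degC cohorts).  Onset time
constants are log10-transformed first.  Per-voltage genotype contrasts use
Welch's unequal-variance t-test with no multiplicity correction, mirroring
the per-voltage reporting style of the source analyses; whether those were
within-model contrasts or separate tests is unstated, so the conservative
separate-test reading is used.  Degenerate zero-variance designs are
defined explicitly (no evidence -> F = 0, p = 1) rather than left NaN.
The suite checks the machinery against a from-scratch sum-of-squares
oracle, a permutation oracle for the interaction, and a 1000-replicate
null simulation whose rejection rate must sit in [0.035, 0.065].

## Neuron model

A single-compartment Hodgkin-Huxley-type cortical pyramidal neuron with
transient Na+ (m^3 h), persistent Na+ (NaP), delayed-rectifier K+ (n^4), a
slow M-type K+ current, and leak, using the classic Traub-lineage
regular-spiking rate functions (V_T = -56.2 mV), at 37 degC only (no Q10
scaling).  Variant effects:

- inactivation acceleration: both h-gate rates x 1.485 (scales 1/tau_h
  uniformly, h_inf unchanged);
- persistent current: `g_NaP = 0.10 * g_Na * fraction` with fraction 1.8%
  (WT) or 4.6% (L1624Q), the NaP gate using the fast-Na activation rates
  x 1000 and no inactivation gate.  An alternative calibration that
  matches the NaP current at 0 mV to the measured persistent fraction of
  the peak transient current is available (`nap_mode="current_matched"`).

The NaP gate enters the current *linearly* (one first-order activation
gate, the standard INaP form), not cubed.  This choice is load-bearing:
with the gate cubed under these kinetics the persistent current is
negligible below -50 mV and none of the variant's subthreshold phenotypes
can express.  With the linear gate the L1624Q persistent current at
-60..-50 mV is of the same order as the leak restoring current, which is
what produces the reported behavior.  The exponent is a parameter
(`nap_gate_exponent`).

Base conductances were calibrated, once, as model construction: g_Kdr 3,
g_KM 0.02, g_leak 0.03 mS/cm^2, E_Na +50 / E_K -90 / E_leak -63 mV.
Relative to the textbook regular-spiking set this reduces the K+ reserve
and adaptation and depolarizes the leak reversal, placing the model in the
regime where (a) the WT resting state is a stable fixed point, (b) the
L1624Q persistent current outweighs the subthreshold restoring currents —
the variant has no subthreshold fixed point and keeps firing once
depolarized, a slow intrinsic pacemaker, which is the mechanism behind its
persistent post-stimulus firing — and (c) depolarization block falls
inside the 0.002-400 pA ramp.  The compartment area (1.8e-5 cm^2) maps
current densities to injected pA such that WT rheobase for a 1 s step is
~1.8 pA, in the intended 1-5 pA design window.  With these choices the
L1624Q model's peak Na+ current under a -120 -> 0 mV clamp step is reduced
by ~25% relative to WT, emerging from the rate scaling rather than being
set directly.

Numerics: gates update by exponential Euler (exact for frozen voltage and
unconditionally stable, which tames the 1000x NaP rates); the voltage
updates by forward Euler with dt = 0.005 ms.  The integrator is first
order: halving dt preserves spike counts and moves early spike times by
<0.1 ms, but phase drift accumulates linearly along long trains (~0.25 ms
by the 11th spike of a 400 ms train) — comparisons of absolute late-spike
times across dt values are not meaningful.  Simulations start from the
zero-stimulus fixed point (found by root-bracketing the steady-state I-V
between E_K and -40 mV) or, when none exists, from the leak reversal.
Spikes are upward 0 mV crossings with a 1 ms refractory; depolarization
block is a terminal spike-free period of >= 100 ms with V sustained above
-30 mV, and the block onset current is the injected current at the last
spike.  The voltage-clamp test pulse is evaluated in closed form (each
gate relaxes mono-exponentially under a commanded step), so that
measurement has no integration error.  The ramp stimulus is exponential in
amplitude from 0.002 to 400 pA over 10 s ("slowly increasing" is otherwise
unquantified; a linear shape is available).

## Problem sizes and defaults

Defaults used by the pipeline and the reported quantities: 50 kHz sampling
(20 kHz in bulk cohort tests), cohort sizes 28/28/28/41 mirroring the
current-density experiment, 15% cell variability, 1 s steps for f-I and
rheobase (bisection to 0.25 pA), 10 s ramps, 1000-replicate null
calibration for the interaction test with n = 8 per cell.

## Known limitations

- The base neuron constants are this package's calibration, not values
  from the variant study or its antecedent models; only the orderings and
  the ~25% peak-reduction anchor are comparable quantities.
- The L1624Q model fires spontaneously once depolarized (no stable rest);
  data on whether the original simulations shared this property are not
  available, and the behavior is consistent with the reported persistent
  firing.
- Experimental p-values and figure-only quantities (V1/2s, absolute tau
  magnitudes, recovery constants) are not reproducible without the raw
  recordings; they are covered by property tests on synthetic data, not by
  numeric comparisons.
- The generator's idealizations mean analysis robustness to real-world
  recording artifacts is untested by design.
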