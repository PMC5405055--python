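# Methods

## The cell model

The backend is a native implementation of the Shannon-type rabbit
ventricular epicardial action-potential model: 40 ODE states covering
membrane potential, Luo–Rudy-type fast Na⁺ gating (m, h, j), rapid and
slow delayed-rectifier K⁺ currents, fast and slow transient outward
currents, the inward rectifier, Ca²⁺-activated and background Cl⁻
currents, a GHK-flux L-type Ca²⁺ current with voltage- and
Ca²⁺-dependent inactivation in junctional-cleft and subsarcolemmal
compartments, Na⁺/Ca²⁺ exchange, Na⁺/K⁺ and sarcolemmal/SR Ca²⁺ pumps,
a four-state ryanodine-receptor release model with luminal regulation,
and the full complement of cytosolic, sarcolemmal, SR and Na⁺ buffers.
The L-type permeabilities carry the 0.45 correction factor of the
corrected model formulation on all four flux components; without it the
plateau Ca²⁺ current is several-fold too large and the cell fails to
repolarise.

Two adaptations serve the ischemia application:

* **Unclamped intracellular K⁺.** [K⁺]ᵢ is a dynamic state driven by
  the sum of all K⁺ fluxes, so E_K and the resting potential respond to
  hyperkalemia and to I_K,ATP self-consistently.
* **Stimulus as K⁺ flux.** The stimulus current enters both the
  membrane equation and the [K⁺]ᵢ balance. Every transmembrane current
  is book-kept against its carrier ion, so the membrane potential
  tracks the total intracellular charge exactly (verified to ~10⁻⁶
  relative per cycle; the clamped Cl⁻ background is the only
  non-book-kept carrier and its per-cycle charge is ~10⁻¹⁰ of the
  intracellular store).

**ATP-sensitive K⁺ current.** I_K,ATP = f_KATP · g_KATP ·
(K_o/5.4)^0.24 · (V − E_K), a time-independent conductance with weak
extracellular-K⁺ rectification. g_KATP = 2.61 mS/µF so that the
estimated activation after 10 min of ischemia, f_KATP = 0.8%, gives a
total channel conductance of 0.02088 mS/µF and roughly a 45% APD₉₀
reduction. The exponent 0.24 is configurable; the formulation is an
assumption in the sense that only the product f·g and the target
behaviour are fixed by the study design.

**Initial conditions.** The default state is literature-style resting
values with fast states and buffers settled by 20 s of quiescence
(rtol 10⁻⁹), which keeps the slow ionic milieu at its paced level
(Na_i ≈ 8.3 mM, K_i ≈ 135 mM). A fully relaxed quiescent steady state
is deliberately not used: tens of minutes of quiescence drain Na_i to
~5.5 mM, far from the paced milieu the protocol assumes. Each
simulation is 10 stimulated beats from this state with no additional
pre-pacing.

## Population members and ischemia

Six maximal conductances are scalable per member: g_to (both fast and
slow components), g_CaL (all four L-type permeabilities), g_Kr, g_Ks,
g_K1, g_NaK. Scaling is always applied to the pristine baseline — a
member cannot be double-applied. The control member is the published
combination (+30% g_to, −15% g_Ks, −30% g_K1, +15% g_NaK).

An ischemic condition is five numbers: f_KATP (I_K,ATP activation),
f_inhib (fractional reduction of I_Na and I_CaL conductance, the
acidosis surrogate), f_NaK (fractional reduction of the Na⁺/K⁺ pump),
[K⁺]_o, and an additive initial [Na⁺]ᵢ offset. The severity schedule is
linear in nominal ischemia time over 0–10 min, with endpoints
f_KATP = 0.8%, f_inhib = 25%, f_NaK = 30% and [K⁺]_o = 12/15/17 mM
(presets K12/K15/K17). Severity "time" is a label: each time point is
a quasi-static parameter set simulated as its own 10-beat run.

**[Na⁺]ᵢ offset magnitude.** The size of the ischemic Na⁺ rise is not
fixed by the study design; the default endpoint is +3 mM at 10 min,
linear like the other parameters. This matters for the single-factor
analysis: over a 10-beat quasi-static run, reducing the pump alone
*lengthens* the AP (an outward current is removed) because the slow
Na⁺ accumulation that shortens APD in real ischemia cannot develop.
The pump-impairment axis in the single-factor analysis therefore pairs
f_NaK with its Na⁺-offset companion; with that pairing the mean APD₉₀
shortening ordering I_K,ATP ≥ pump axis ≥ I_Na/I_CaL inhibition holds.

## Protocol and numerics

Pacing: cycle length 600 ms (calibration also 400 and 1000 ms), 3 ms
pulses, amplitude 1.5× the member's excitation threshold measured in
control and reused unchanged at every severity. The threshold is found
per member by bracketed bisection ([0, 80] µA/µF with doubling, 1%
relative tolerance) on the 44 mV amplitude criterion over the final
beat of a short 3-beat train; per-member thresholds keep every member
at the same physiological stimulus margin.

Integration uses LSODA (adaptive stiff) at rtol 10⁻⁷ / atol 10⁻⁹ with
a compiled forward-difference Jacobian; traces are resampled onto a
uniform 0.05 ms grid. Tightening the tolerances tenfold moves the
final-beat APD₉₀ by well under 0.5 ms. Removable singularities in rate
expressions (V = −47.13, −14.5, −7, −10, −30 mV and the GHK flux at
V = 0) are guarded by their analytic limits.

## Biomarkers

All biomarkers are computed on the last stimulated beat:

* **Excitation**: the beat counts as an AP iff max(V) − V(onset) ≥
  44 mV; smaller responses are failed excitations and excluded.
* **V_rest** is V at the stimulus onset of the analysed beat (the
  diastolic value immediately pre-stimulus).
* **dV/dt_max** by central differences on the 0.05 ms grid; halving
  the grid changes it by < 1%.
* **APD₉₀**: from the sample of dV/dt_max to the first crossing of
  V ≤ V_rest + 0.1 (V_max − V_rest), linearly interpolated between
  samples (checked against 10×-denser resampling to 0.01 ms). Beats
  that never reach the level are flagged unrepolarised and treated
  like failed excitation in population statistics.
* **ERP**: recovery of the Na⁺-channel inactivation product — the
  first instant after post-upstroke inactivation at which h·j > 0.012,
  measured from the stimulus onset (also reported relative to the
  upstroke). If h·j never recovers within the cycle the ERP is
  censored at ≥ cycle length and the member is a failed-excitation
  candidate for the next beat.

## Synthetic populations and calibration

Candidates are drawn uniformly and independently on [0, 2] per
conductance factor and filtered to members whose control APD₉₀ lies in
an acceptance window at all three cycle lengths. The shipped windows
are **illustrative**: ±20% around the control member's own APD₉₀ under
the study protocol (244 / 230 / 205 ms at CL 400 / 600 / 1000 ms).
Because the control combination is by definition the member closest to
the experimental means, its behaviour is the best available anchor
when the original experimental calibration ranges are not published;
it also guarantees the control member is itself a valid population
member. Real applications should substitute experimental ranges. The
control-selection metric is least summed squared APD₉₀ deviation from
the targets over the three cycle lengths, ties broken by member index.

What the generator does *not* emulate: correlated conductance
variation, kinetic (gating) variability, beat-to-beat variability, and
any direct use of experimental recordings. Passing population-level
tests therefore demonstrates internal consistency of the pipeline and
qualitative mechanism reproduction, not agreement with any specific
experimental population.

## Analysis

Variability is summarised per condition by population variance
(ddof = 0), range, and Freedman–Diaconis histograms over non-excluded
members, with exclusion counts reported alongside. Column plots order
members by control APD₉₀ (ascending), one column per severity point,
min–max normalised globally per metric, excluded cells as a sentinel.

Clutter-based dimension reordering projects 1-based factorial-grid
coordinates by x′ = Σᵢ (xᵢ − 1) Π_{j<i} N_j + 1, a bijection onto
{1..N}; 2-D images apply it independently to disjoint x- and y-subsets
of the dimensions. CBDR needs a full-factorial sweep, which is a
separate run mode from the random population (default 4 levels per
dimension, configurable); the dimension order is user-specified by
default, with an optional variance-based automatic ordering.

## Severity presets and late-ischemia excitation failure

With Luo–Rudy-type Na⁺ gates, steady-state availability h∞·j∞ at the
resting potential falls below the 0.012 re-excitability threshold only
for V_rest ≳ −57 mV, i.e. [K⁺]_o ≳ 15 mM. Loss of excitability with
ERP ≥ cycle length at the 10-min point — and the attendant rebound in
APD₉₀ variance as members diverge near the failure boundary — is
therefore a feature of the severe presets (K15/K17), not of K12, in
this backend. The variance-trajectory and exclusion analyses are run
at K17, with the K12 trajectory (monotone decline after the 2-min dip)
reported alongside.

## Problem sizes

Default study sizes used by the tests and the reproduction script: 50
calibrated members (drawn from a few hundred uniform candidates), 10
beats per condition, severity points {0, 2, 6, 8, 10} min, presets K12
and K17. These are the package's desk-scale study conditions; all
sizes are configurable through `RunConfig`.

## Known limitations

* Only the Shannon-type backend is implemented; the architecture
  (parameter vector + state vector + RHS contract) admits a second
  backend, which is not required here.
* No tissue coupling, no pH/proton–Ca²⁺ buffering dynamics, no
  metabolic ATP model (f_KATP is an imposed schedule).
* The ischemic [Na⁺]ᵢ rise magnitude is an assumption (+3 mM at
  10 min); conclusions that hinge on the pump axis should vary it.
* The model was written fresh from the published formulation; no
  independent reference implementation was available for cross-checks,
  so correctness rests on the physical invariants (charge
  conservation, Nernst behaviour, gate bounds), the published
  conductance arithmetic, and regression guards, not on trace-level
  agreement with an external implementation.
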