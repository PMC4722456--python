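# Methods

## Models

**ATP-induced dissociation of acto·S1 (scheme 2).** Rigor acto·S1 binds ATP
through a rapid association equilibrium (K′₁) followed by a rate-limiting
isomerization (k′₊₂) after which the complex separates irreversibly on the
measurement timescale. With ligand in large excess over protein
(pseudo-first-order; experimentally 1–3 μM S1 against tens to hundreds of
μM nucleotide), the light-scattering decay is single-exponential with
k_obs = K′₁k′₊₂[ATP]/(1 + [ADP]/K_AD). ADP acts as a competitive ligand
for the rigor complex; the generators model the ADP-scavenging systems as
ideal, so [ADP] is exactly the nominal value. Rebinding of detached heads
within a trace is neglected (step 2 irreversible), matching the
single-exponential analysis convention.

**ATP binding and hydrolysis by S1 (scheme 1).** The three-step subset
M + T ⇌ M·T → M\*·T ⇌ M\*\*·D·Pᵢ is used: rapid binding equilibrium,
fast quasi-irreversible isomerization (composite second-order constant
K₁k₊₂), then the reversible hydrolysis/recovery-stroke step with forward
and reverse constants k₊₃, k₋₃. With tryptophan fluorescence reporting the
post-hydrolysis state, the observed rate is approximated by the hyperbola
k_obs = (k₊₃+k₋₃)[ATP]/(K₀.₅+[ATP]) with K₀.₅ = (k₊₃+k₋₃)/(K₁k₊₂): at low
[ATP] binding rate-limits (k_obs → K₁k₊₂[ATP]), at high [ATP] the
hydrolysis step does (k_obs → k₊₃+k₋₃). Only the sum k₊₃+k₋₃ is
observable; the individual split is not identifiable from these data.

**ADP release from S1.** Displacement of a fluorescent ADP analogue by an
ATP chase is rate-limited by ADP release, so the coumarin decay is a
single exponential at k₋D.

**Steady state.** Basal Mg²⁺-ATPase (no actin) is subtracted per
preparation from the actin-activated points; the activated rates follow
v = V_max[A]/(K_m+[A]). Catalytic efficiency is V_max/K_m. Genotype
comparisons use two-sided equal-variance Student's t tests with tiers at
p < 0.05/0.01/0.001 and no multiple-testing correction, matching the
conventional reporting for these assays. A Welch option exists but is off
by default.

## Elementary-rate construction and the ODE oracle

The experiments constrain only composite constants, so the simulator's
elementary rates are explicit constructions (`micro_from_preset`): the
rate-limiting step is set `stiffness_factor` (default 100) times faster
than the largest observed rate in the design range (1000 μM ATP for
scheme 2; the hydrolysis sum for scheme 1), and the preceding binding
equilibration another factor of `stiffness_factor` faster, with k₊₁/k₋₁
chosen so the composites reproduce the preset exactly. The hydrolysis sum
is split with an equilibrium constant K₃ (default 3), consistent with the
near-balanced energetics of the recovery stroke in muscle myosin II
(overall equilibrium constants below ~10). Construction fails loudly if a
rate would exceed 10⁹ s⁻¹.

The linear ODE systems are solved exactly by eigendecomposition (matrix
exponential fallback for near-defective rate matrices), so stiffness costs
nothing. For scheme 2 the slow eigenvalue deviates from the closed form by
about 1/stiffness + [ATP]/(stiffness·1000 μM) — ≤ 1.5% at 500 μM with the
defaults — which is why the simulator can serve as a ≤ 2% oracle for the
dissociation model.

For scheme 1 the oracle statement is deliberately weaker. The true
transient of the strictly sequential scheme is biexponential with a lag,
and its best single-exponential fit deviates from the hyperbola by up to
~13% near and above K₀.₅ (the hyperbola is itself an approximation, exact
only in the two limbs). Refitting the hyperbola to such rates inflates the
apparent plateau by 15–20% regardless of the fitting window. The property
tests therefore assert the two limits the model actually predicts — the
linear limb and the plateau, each within 5% — plus invariance of the
fitted rate to the k₊₃/k₋₃ split. Quantitative tryptophan-titration
generation defaults to `closed_form` (ideal exponentials at the hyperbola
rate); `ode` mode exists for structural checks.

## Synthetic data

Noise is i.i.d. Gaussian on the signal with s.d. = `noise_frac` × total
amplitude (default 2%), the simplest model consistent with displayed
traces. Trace grids are log-spaced over five half-lives of the expected
rate (200 points); durations under three half-lives are refused.
Tryptophan traces start after a 1.5 ms stopped-flow dead time and carry
relative amplitudes drawn uniformly from 2–4%, independent of [ATP];
generating rates above 200 s⁻¹ are flagged as unreliable to evaluate
(instrument limit), configurable. Coumarin traces draw the flash-released
[ATP] uniformly from 15–20 μM. ATPase datasets use ≥ 3 preparations
(default 4), each with independent unit-mean lognormal multipliers
(CV 10%) on V_max, K_m and the basal rates, measurement noise of
`noise_frac` × the preparation's V_max per point (default 10%), and an
actin grid spanning 0–24 μM around the ~4–6 μM K_m. Every generator is
bit-reproducible under a fixed integer seed.

What the generators do *not* emulate: photolysis artifacts, baseline
drift, photobleaching, inner-filter effects, second-order substrate
depletion, and multi-exponential character from off-pathway states.
Passing recovery tests therefore demonstrate that the fitting pipeline is
unbiased and well-conditioned for idealized single-exponential data at
realistic noise — not that real instrument records are free of systematic
error.

## Fitting conventions

Single exponentials are fitted by unweighted nonlinear least squares with
the rate initialized from the time to half signal change, three restarts
from perturbed initializations before declaring failure, and a refusal to
report rates whose fitted half-life is under two sampling intervals. The
reported amplitude is the signed total change (negative = decay). The
acto·S1 titration line is through the origin (the scheme has no reverse
flux at zero ATP); a free intercept is exposed as a diagnostic, and a
lack-of-fit F-test against the saturating hyperbola (α = 0.01) warns when
the grid leaves the linear regime. The binding hyperbola is parameterized
directly in (K₁k₊₂, k₊₃+k₋₃) so K₀.₅ = (k₊₃+k₋₃)/(K₁k₊₂) holds exactly;
it is initialized from the double-reciprocal line, raises an
unsaturated-titration error when the data are statistically consistent
with a straight line or the fitted K₀.₅ exceeds twice the largest
concentration, and warns when the plateau is unsampled. The competition
model is fitted on k_rel with k₀ taken from the zero-ADP anchor.
Replicates enter individually and fits are unweighted throughout, matching
the fit-all-points convention of the source assays; a consequence is that
nominal standard errors are exactly calibrated only where the noise is
homoscedastic (the trace fits — verified at 60–76% empirical coverage of
±1 s.e. over 200 replicates), while titration-level intervals inherit
propagated heteroscedastic noise and should be read qualitatively.

Michaelis–Menten fits follow the fit-each-preparation-then-average
convention (mean ± between-preparation S.D.); a pooled fit over all points
is available. Per-preparation nonlinear fits on seven points with an
extrapolated plateau carry a small upward V_max bias (≈ +5% at the default
design; the pooled fit is nearly unbiased) — a known small-sample property
of the estimator, reported as measured.

## Recovery studies

`run_parameter_recovery` simulates each replicate as an independent
preparation: the preset is perturbed by the lognormal preparation factor
(CV 10%) and a full set of experiments is generated and fitted. Mean,
S.D., bias and RMSE are reported against the registry value, so the
replicate spread stands in for between-preparation spread; interval
coverage is scored against each replicate's own generating parameter.
Child seeds derive from the master seed via
`SeedSequence(entropy=master, spawn_key=counters)`, recorded in the run
manifest, making whole studies bit-reproducible. The default study
reproduces the qualitative genotype pattern: acto·S1 parameters
(K′₁k′₊₂, K_AD) indistinguishable across genotypes, S1 ATP binding and
hydrolysis (K₁k₊₂, k₊₃+k₋₃) depressed in R759E and restored in
R759E/N509K, and the K₀.₅ consistency ratio matching the fitted value for
all three genotypes.

## Problem sizes and numerical choices

Stochastic summaries use 20 replicates; the calibration property uses 200;
traces carry 200 points; mass conservation of simulated trajectories is
enforced at 1e-8. Degenerate inputs fail loudly rather than silently:
constant signals, single-concentration titrations, missing preset fields,
double basal subtraction and unsatisfiable rate constructions all raise
typed errors. Negative basal-subtracted rates are clipped at zero and
counted. Zero-variance equal-mean comparisons return p = 1 by convention.

## Known limitations

Only the three-step binding subset of the full S1 nucleotide mechanism is
modeled; phosphate-release kinetics, load dependence, and temperature or
ionic-strength effects are out of scope. The scheme-1 ODE oracle and the
hyperbolic closed form disagree at intermediate [ATP] as described above —
an intrinsic property of the approximation, not an implementation error.
The measured half-saturating [ATP] of a single wild-type stopped-flow
dataset (85 μM) is known to sit well above the multi-preparation value
(53 ± 12 μM); the package carries the multi-preparation averages in its
registry and exposes the consistency ratio so such discrepancies surface.
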