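# myokin

Transient and steady-state kinetic analysis of the actomyosin cross-bridge
cycle, built around *Drosophila melanogaster* indirect-flight-muscle (IFI)
myosin S1 and its converter/relay-interface mutants R759E and R759E/N509K.

The package is for kineticists who characterize myosin motor domains from
small protein yields: it simulates the reaction schemes behind
flash-photolysis and stopped-flow experiments, generates realistic seeded
synthetic datasets at the published parameter values of each genotype, fits
the standard secondary models, and runs end-to-end parameter-recovery
studies that test whether the analysis pipeline can actually retrieve the
constants it claims to measure.

## The kinetics

Cross-bridge detachment from rigor is measured by light scattering after
flash release of caged ATP. Under pseudo-first-order conditions each trace
is a single exponential whose observed rate follows

```
k_obs = K′₁k′₊₂ [ATP] / (1 + [ADP]/K_AD)
```

so the slope of k_obs vs [ATP] gives the apparent second-order binding
constant K′₁k′₊₂, and titrating ADP at fixed ATP gives the ADP affinity of
acto·S1, K_AD, through k_rel = k_obs/k₀ = 1/(1 + [ADP]/K_AD).

ATP binding to S1 alone is followed by intrinsic tryptophan fluorescence,
which reports the hydrolysis/recovery-stroke step of the two-step scheme
M + T ⇌ M·T → M\*·T ⇌ M\*\*·D·Pᵢ. The observed rate approximates the
hyperbola

```
k_obs = (k₊₃ + k₋₃) [ATP] / ((k₊₃ + k₋₃)/(K₁k₊₂) + [ATP])
```

with initial slope K₁k₊₂, plateau k₊₃ + k₋₃, and half-saturation
K₀.₅ = (k₊₃ + k₋₃)/(K₁k₊₂) — an internal consistency test the package
exposes. ADP release from S1 (k₋D) comes from single-exponential
coumarin-ADP displacement decays. Steady-state actin-activated
Mg²⁺-ATPase data are basal-subtracted and fitted with the
Michaelis–Menten equation for V_max, K_m and the catalytic efficiency
V_max/K_m; genotypes are compared with Student's t tests.

Beneath the closed forms, a linear-ODE simulator (exact, eigendecomposition
based) realizes each scheme from elementary rate constants constructed to
match the measured composites; it serves as a brute-force oracle for the
analytic observed rates.

## Worked example

```python
import myokin as mk

wt = mk.load_preset("wild-type")

# one flash-photolysis light-scattering decay at 100 μM ATP, 2% noise
trace = mk.make_dissociation_trace(wt, atp=100.0, noise_frac=0.02, seed=1)
fit = mk.fit_single_exponential(trace)
print(f"k_obs = {fit.k_obs:.1f} ± {fit.k_obs_se:.1f} s⁻¹")

# five-point ATP titration → second-order dissociation constant
kobs = [mk.fit_single_exponential(
            mk.make_dissociation_trace(wt, atp=a, noise_frac=0.02, seed=i)
        ).k_obs for i, a in enumerate([25, 50, 100, 200, 400])]
series = mk.TitrationSeries(ligand="ATP", conc=[25, 50, 100, 200, 400], kobs=kobs)
lin = mk.fit_linear_titration(series)
print(f"K'1k'+2 = {lin.params['K1k2_acto']:.3f} ± {lin.se['K1k2_acto']:.3f} μM⁻¹s⁻¹")

# ADP competition → ADP affinity of acto-S1
comp = mk.fit_adp_competition(mk.make_competition_series(wt, noise_frac=0.02, seed=2))
print(f"K_AD = {comp.params['K_AD']:.0f} ± {comp.se['K_AD']:.0f} μM")

# four-preparation steady-state ATPase → Vmax, Km, efficiency
ds = mk.subtract_basal(mk.make_atpase_dataset(wt, n_preps=4, noise_frac=0.10, seed=3))
mm = mk.fit_michaelis_menten(ds)
print(f"Vmax = {mm.vmax:.2f} ± {mm.vmax_sd:.2f} s⁻¹, Km = {mm.km:.2f} ± {mm.km_sd:.2f} μM, "
      f"Vmax/Km = {mm.catalytic_efficiency:.2f} μM⁻¹s⁻¹")

print(f"predicted K0.5 = {mk.predicted_K05(wt):.1f} μM (reported {wt.k05:.0f} ± {wt.sd['k05']:.0f})")
```

prints

```
k_obs = 70.0 ± 1.2 s⁻¹
K'1k'+2 = 0.693 ± 0.002 μM⁻¹s⁻¹
K_AD = 392 ± 11 μM
Vmax = 2.85 ± 1.09 s⁻¹, Km = 5.46 ± 3.35 μM, Vmax/Km = 0.52 μM⁻¹s⁻¹
predicted K0.5 = 51.3 μM (reported 53 ± 12)
```

The fitted rate at 100 μM ATP is K′₁k′₊₂ × 100 = 70 s⁻¹; the titration
slope recovers the wild-type 0.70 μM⁻¹s⁻¹; the competition fit recovers
K_AD near the wild-type 406 μM; the four-preparation ATPase fit scatters
around V_max = 2.54 s⁻¹ and K_m = 5.77 μM (the ± values here are
between-preparation S.D.s, which are large for n = 4); and the two-step
binding model's predicted half-saturating [ATP] agrees with the measured
value.

A command-line surface wraps the same functions
(`myokin simulate|fit-trace|fit-titration|fit-atpase|recover|study`), and
`mk.run_full_study(mk.StudyConfig(master_seed=0))` produces the
genotype-by-parameter summary tables with significance tiers.

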