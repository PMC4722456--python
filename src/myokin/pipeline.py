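"""End-to-end seeded recovery studies and study-level reports.

A *study* simulates, per genotype, every experiment type the analysis
consumes — dissociation titrations, ADP competitions, coumarin
displacements, tryptophan titrations and steady-state ATPase datasets —
fits each with the corresponding model, and summarizes how well the
generating parameters are recovered (bias, RMSE, nominal-interval
coverage), plus tables shaped like the study's transient-parameter and
ATPase summaries with pairwise significance tiers.

Each replicate represents one preparation: the preset is perturbed by a
unit-mean lognormal preparation factor (``prep_cv``) before generating, so
between-replicate spread stands in for between-preparation spread.  Child
seeds derive from the master seed through a counter-based
``numpy.random.SeedSequence`` rule, recorded in the run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import KineticsError
from .presets import GenotypePreset, load_registry, perturb_preset
from .schemes import predicted_K05
from .steady_state import compare_genotypes, fit_michaelis_menten, subtract_basal
from .synthetic import (
    make_atpase_dataset,
    make_competition_series,
    make_coumarin_trace,
    make_dissociation_trace,
    make_trp_titration,
)
from .transient import (
    TitrationSeries,
    fit_adp_competition,
    fit_hyperbolic_titration,
    fit_linear_titration,
    fit_single_exponential,
)

__all__ = ["StudyConfig", "RecoveryReport", "run_parameter_recovery", "run_full_study", "child_seed"]

logger = logging.getLogger(__name__)

#: Transient parameters recovered per replicate, with the ATPase block.
TRANSIENT_PARAMS = ("k1k2_acto", "k_ad", "k_minus_d", "k1k2_s1", "k_hyd_sum")
ATPASE_PARAMS = ("vmax", "km", "efficiency", "basal_ca", "basal_mg")


@dataclass(frozen=True)
class StudyConfig:
    """Grids, noise levels and toggles for a seeded recovery study."""

    genotypes: tuple = ("wild-type", "R759E", "R759E/N509K")
    master_seed: int = 0
    n_replicates: int = 20
    # transient experiments
    atp_grid_dissociation: tuple = (25.0, 50.0, 100.0, 200.0, 400.0)
    adp_grid: tuple = (0.0, 100.0, 200.0, 400.0, 800.0, 1600.0)
    competition_atp: float = 100.0
    atp_grid_trp: tuple = (10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0)
    noise_frac: float = 0.02
    trace_n_points: int = 200
    mode: str = "closed_form"        # or "ode"
    # steady state
    actin_grid: tuple = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0)
    n_preps: int = 4
    atpase_noise_frac: float = 0.10
    pooled_mm: bool = False
    # replicate (preparation) structure
    prep_cv: float = 0.10
    # outputs
    out_dir: str | None = None
    presets: dict = field(default_factory=dict)  # optional label -> GenotypePreset overrides

    def resolve_preset(self, genotype: str) -> GenotypePreset:
        if genotype in self.presets:
            preset = self.presets[genotype]
            if not isinstance(preset, GenotypePreset):
                preset = GenotypePreset.from_dict(preset)
            return preset
        return load_registry()[genotype]


def child_seed(master_seed: int, *counters: int) -> int:
    """Counter-based child-seed derivation (documented in the manifest)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(c) for c in counters))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class RecoveryReport:
    """Per-parameter recovery summary for one genotype.

    ``table`` columns: parameter, truth, mean, sd, bias, rmse, coverage,
    n.  Coverage is the fraction of replicates whose nominal ±1 s.e.
    interval covers the generating value (NaN where no per-replicate
    standard error exists).
    """

    genotype: str
    table: pd.DataFrame
    n_replicates: int
    n_failures: int
    estimates: pd.DataFrame  # per-replicate point estimates

    def __post_init__(self) -> None:
        bad = self.table["rmse"] + 1e-12 < self.table["bias"].abs()
        if bool(bad.any()):
            raise ValueError("RMSE cannot be below |bias|")
        cov = self.table["coverage"].dropna()
        if bool(((cov < 0) | (cov > 1)).any()):
            raise ValueError("coverage outside [0, 1]")


def _simulate_and_fit_replicate(
    preset: GenotypePreset, config: StudyConfig, seed_base: tuple
) -> dict:
    """One preparation: generate every experiment, fit, return estimates.

    Returns ``{param: (estimate, se_or_None)}``.
    """
    out: dict = {}
    master = config.master_seed

    # 1. ATP-induced acto-S1 dissociation: traces across the ATP grid, then
    #    the zero-intercept line for K'1k'+2.
    kobs, conc = [], []
    for i, atp in enumerate(config.atp_grid_dissociation):
        trace = make_dissociation_trace(
            preset, atp=atp, noise_frac=config.noise_frac,
            n_points=config.trace_n_points, mode=config.mode,
            seed=child_seed(master, *seed_base, 1, i),
        )
        fit = fit_single_exponential(trace)
        kobs.append(fit.k_obs)
        conc.append(atp)
    series = TitrationSeries(ligand="ATP", conc=np.array(conc), kobs=np.array(kobs),
                             genotype=preset.label)
    linear = fit_linear_titration(series)
    out["k1k2_acto"] = (linear.params["K1k2_acto"], linear.se["K1k2_acto"])

    # 2. ADP competition at fixed ATP for K_AD.
    comp_series = make_competition_series(
        preset, atp=config.competition_atp, adp_grid=config.adp_grid,
        noise_frac=config.noise_frac, seed=child_seed(master, *seed_base, 2),
    )
    comp = fit_adp_competition(comp_series)
    out["k_ad"] = (comp.params["K_AD"], comp.se["K_AD"])

    # 3. Coumarin-ADP displacement for k-D.
    ctrace = make_coumarin_trace(
        preset, noise_frac=config.noise_frac, n_points=config.trace_n_points,
        seed=child_seed(master, *seed_base, 3),
    )
    cfit = fit_single_exponential(ctrace)
    out["k_minus_d"] = (cfit.k_obs, cfit.k_obs_se)

    # 4. Tryptophan titration for K1k+2 and k+3 + k-3.
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # high-rate traces are expected at the top of the grid
        traces = make_trp_titration(
            preset, atp_grid=config.atp_grid_trp, noise_frac=config.noise_frac,
            n_points=config.trace_n_points, mode=config.mode,
            seed=child_seed(master, *seed_base, 4),
        )
        tk, tc = [], []
        for trace in traces:
            fit = fit_single_exponential(trace)
            tk.append(fit.k_obs)
            tc.append(trace.atp)
        tseries = TitrationSeries(ligand="ATP", conc=np.array(tc), kobs=np.array(tk),
                                  genotype=preset.label)
        hyper = fit_hyperbolic_titration(tseries)
    out["k1k2_s1"] = (hyper.params["K1k2_s1"], hyper.se["K1k2_s1"])
    out["k_hyd_sum"] = (hyper.params["k_hyd_sum"], hyper.se["k_hyd_sum"])
    out["k05_fitted"] = (hyper.params["K05"], hyper.se["K05"])

    # 5. Steady-state ATPase.
    dataset = make_atpase_dataset(
        preset, actin_grid=config.actin_grid, n_preps=config.n_preps,
        noise_frac=config.atpase_noise_frac, prep_cv=config.prep_cv,
        seed=child_seed(master, *seed_base, 5),
    )
    mm = fit_michaelis_menten(subtract_basal(dataset), pooled=config.pooled_mm)
    out["vmax"] = (mm.vmax, mm.vmax_sd)
    out["km"] = (mm.km, mm.km_sd)
    out["efficiency"] = (mm.catalytic_efficiency, mm.efficiency_sd)
    out["basal_ca"] = (float(dataset.basal["basal_ca"].mean()),
                       float(dataset.basal["basal_ca"].std(ddof=1)))
    out["basal_mg"] = (float(dataset.basal["basal_mg"].mean()),
                       float(dataset.basal["basal_mg"].std(ddof=1)))
    return out


def run_parameter_recovery(
    config: StudyConfig, genotype: str, n_replicates: int | None = None
) -> RecoveryReport:
    """Simulate → fit → summarize for every recovered parameter.

    Each replicate draws a fresh preparation (lognormal ``prep_cv``
    perturbation of the preset) and a fresh set of experiments.  Stage
    failures are recorded per replicate; more than 20% failures aborts.
    """
    if n_replicates is None:
        n_replicates = config.n_replicates
    base = config.resolve_preset(genotype)
    truth = {p: getattr(base, p) for p in TRANSIENT_PARAMS}
    truth.update({
        "k05_fitted": predicted_K05(base) if base.k1k2_s1 and base.k_hyd_sum else None,
        "vmax": base.vmax, "km": base.km,
        "efficiency": (base.vmax / base.km) if base.vmax and base.km else None,
        "basal_ca": base.basal_ca, "basal_mg": base.basal_mg,
    })

    gidx = list(config.genotypes).index(genotype) if genotype in config.genotypes else 99
    records, failures = [], 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(child_seed(config.master_seed, gidx, rep, 0))
        prep_preset = perturb_preset(base, config.prep_cv, rng)
        try:
            est = _simulate_and_fit_replicate(prep_preset, config, (gidx, rep))
        except KineticsError as err:
            failures += 1
            logger.warning("replicate %d failed for %s: %s", rep, genotype, err)
            continue
        rep_truth = {p: getattr(prep_preset, p) for p in TRANSIENT_PARAMS}
        rep_truth.update({
            "k05_fitted": prep_preset.k_hyd_sum / prep_preset.k1k2_s1
            if prep_preset.k1k2_s1 and prep_preset.k_hyd_sum else None,
            "vmax": prep_preset.vmax, "km": prep_preset.km,
            "efficiency": (prep_preset.vmax / prep_preset.km)
            if prep_preset.vmax and prep_preset.km else None,
            "basal_ca": prep_preset.basal_ca, "basal_mg": prep_preset.basal_mg,
        })
        for param, (value, se) in est.items():
            records.append({
                "replicate": rep, "parameter": param, "estimate": value, "se": se,
                "rep_truth": rep_truth.get(param),
            })
    if failures > 0.2 * n_replicates:
        raise RuntimeError(
            f"{failures}/{n_replicates} replicates failed for {genotype}; aborting"
        )

    estimates = pd.DataFrame(records)
    rows = []
    for param, grp in estimates.groupby("parameter"):
        true = truth.get(param)
        vals = grp["estimate"].to_numpy()
        ses = grp["se"].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if true is None:
            bias = rmse = coverage = np.nan
        else:
            bias = mean - true
            rmse = float(np.sqrt(np.mean((vals - true) ** 2)))
            # coverage of each replicate's nominal ±1 s.e. interval over the
            # parameter of the preparation that generated that replicate
            rep_true = grp["rep_truth"].to_numpy(dtype=float)
            ok = np.isfinite(ses) & (ses > 0) & np.isfinite(rep_true)
            coverage = (
                float(np.mean(np.abs(vals[ok] - rep_true[ok]) <= ses[ok]))
                if ok.any() else np.nan
            )
        rows.append({
            "parameter": param, "truth": true, "mean": mean, "sd": sd,
            "bias": bias, "rmse": rmse, "coverage": coverage, "n": int(vals.size),
        })
    table = pd.DataFrame(rows).set_index("parameter").loc[
        [p for p in (*TRANSIENT_PARAMS, "k05_fitted", *ATPASE_PARAMS) if p in estimates["parameter"].values]
    ].reset_index()
    return RecoveryReport(
        genotype=genotype, table=table, n_replicates=n_replicates,
        n_failures=failures, estimates=estimates,
    )


def run_full_study(config: StudyConfig) -> dict:
    """Full seeded study across genotypes.

    Returns a bundle with the transient-parameter table (mean ± S.D. per
    genotype), the ATPase table with pairwise significance tiers, the
    half-saturation consistency table (predicted vs fitted K0.5), the
    per-genotype recovery reports and a run manifest.  Tables are also
    written to ``config.out_dir`` when set.
    """
    reports = {g: run_parameter_recovery(config, g) for g in config.genotypes}

    def column(report: RecoveryReport, param: str) -> str:
        row = report.table.set_index("parameter").loc[param]
        return f"{row['mean']:.3g} ± {row['sd']:.2g}"

    transient_rows = []
    for param in (*TRANSIENT_PARAMS, "k05_fitted"):
        transient_rows.append(
            {"parameter": param, **{g: column(reports[g], param) for g in config.genotypes}}
        )
    table1 = pd.DataFrame(transient_rows)

    atpase_rows = []
    comparisons = []
    pairs = [
        (a, b)
        for i, a in enumerate(config.genotypes)
        for b in list(config.genotypes)[i + 1:]
    ]
    for param in ATPASE_PARAMS:
        row = {"parameter": param, **{g: column(reports[g], param) for g in config.genotypes}}
        for a, b in pairs:
            sa = reports[a].estimates.query("parameter == @param")["estimate"]
            sb = reports[b].estimates.query("parameter == @param")["estimate"]
            res = compare_genotypes(param, (a, b), sa, sb)
            row[f"{a} vs {b}"] = res.tier
            comparisons.append(res)
        atpase_rows.append(row)
    fig2 = pd.DataFrame(atpase_rows)

    k05_rows = []
    for g in config.genotypes:
        preset = config.resolve_preset(g)
        fitted = reports[g].table.set_index("parameter").loc["k05_fitted"]
        k05_rows.append({
            "genotype": g,
            "predicted_K05_uM": predicted_K05(preset),
            "fitted_K05_mean_uM": fitted["mean"],
            "fitted_K05_sd_uM": fitted["sd"],
            "reported_K05_uM": preset.k05,
        })
    k05_table = pd.DataFrame(k05_rows)

    manifest = {
        "master_seed": config.master_seed,
        "seed_rule": "SeedSequence(entropy=master, spawn_key=counters) & 0x7fffffff",
        "n_replicates": config.n_replicates,
        "genotypes": list(config.genotypes),
        "mode": config.mode,
        "noise_frac": config.noise_frac,
        "prep_cv": config.prep_cv,
        "failures": {g: reports[g].n_failures for g in config.genotypes},
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items() if k != "presets"
        },
    }

    bundle = {
        "table1": table1,
        "fig2": fig2,
        "k05_consistency": k05_table,
        "comparisons": comparisons,
        "reports": reports,
        "manifest": manifest,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table1.to_csv(out / "transient_parameters.csv", index=False)
        fig2.to_csv(out / "atpase_summary.csv", index=False)
        k05_table.to_csv(out / "k05_consistency.csv", index=False)
        for g, report in reports.items():
            safe = g.replace("/", "_")
            report.table.to_csv(out / f"recovery_{safe}.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
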