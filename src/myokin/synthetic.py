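"""Seeded synthetic kinetic experiments per genotype.

Each generator emulates one of the study's experiment types at the preset's
parameter values:

* flash-photolysis light-scattering decays (ATP-induced acto-S1
  dissociation, with or without ADP competition);
* ADP-competition titrations of the observed dissociation rate;
* coumarin-ADP displacement decays (ADP release from S1, rate k-D);
* stopped-flow tryptophan-fluorescence rises (ATP binding/hydrolysis,
  3–4% amplitude, 1.5 ms dead time);
* steady-state actin-activated ATPase datasets with per-preparation
  replicate structure (n ≥ 3 preparations, lognormal between-preparation
  variability) and basal Ca2+/Mg2+ rates.

Noise is i.i.d. Gaussian on the signal with standard deviation
``noise_frac`` × total amplitude (default 2%); every generator is exactly
reproducible under a fixed integer seed.  ``mode="closed_form"`` draws the
ideal single-exponential at the analytic observed rate; ``mode="ode"``
projects the simulated scheme instead, serving as the independent oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PoorConditioningWarning, UndersampledError, UnreliableRateWarning
from .presets import GenotypePreset
from .schemes import (
    analytic_kobs_binding,
    analytic_kobs_dissociation,
    micro_from_preset,
    observable_projection,
    simulate_scheme,
)
from .traces import KineticTrace
from .transient import TitrationSeries

__all__ = [
    "ATPaseDataset",
    "make_dissociation_trace",
    "make_competition_series",
    "make_coumarin_trace",
    "make_trp_titration",
    "make_atpase_dataset",
]

LN2 = math.log(2.0)

#: Stopped-flow dead time excluded from tryptophan traces (s).
DEAD_TIME = 1.5e-3

#: Rates above this are flagged as unreliable to evaluate (s⁻¹).
RATE_RELIABILITY_CAP = 200.0


def _time_grid(k_obs: float, duration: float | None, n_points: int) -> np.ndarray:
    """Log-spaced grid over 5 half-lives (or the requested duration)."""
    t_half = LN2 / k_obs
    if duration is None:
        duration = 5.0 * t_half
    elif duration < 3.0 * t_half:
        raise UndersampledError(
            f"duration {duration:.4g} s is under 3 half-lives of k_obs = {k_obs:.3g} s⁻¹"
        )
    return np.geomspace(duration / 2000.0, duration, n_points)


# ---------------------------------------------------------------------------
# transient traces
# ---------------------------------------------------------------------------

def make_dissociation_trace(
    preset: GenotypePreset,
    atp: float,
    adp: float = 0.0,
    duration: float | None = None,
    n_points: int = 200,
    noise_frac: float = 0.02,
    seed: int = 0,
    mode: str = "closed_form",
    amplitude: float = 1.0,
    floor: float = 0.0,
    stiffness_factor: float = 100.0,
) -> KineticTrace:
    """One flash-photolysis light-scattering decay at fixed [ATP], [ADP]."""
    if not 0.0 <= noise_frac <= 0.2:
        raise ValueError("noise_frac must lie in [0, 0.2]")
    k = analytic_kobs_dissociation(preset, atp, adp)
    times = _time_grid(k, duration, n_points)
    if mode == "closed_form":
        signal = floor + amplitude * np.exp(-k * times)
    elif mode == "ode":
        micro = micro_from_preset(preset, "scheme2", stiffness_factor=stiffness_factor)
        traj = simulate_scheme(micro, atp=atp, adp=adp, times=times)
        trace = observable_projection(
            traj, "light_scattering", amplitude=amplitude, floor=floor
        )
        signal = trace.signal
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    noise_sd = noise_frac * amplitude
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, times.size)
    return KineticTrace(
        time=times, signal=signal, signal_type="light_scattering",
        atp=atp, adp=adp, genotype=preset.label, noise_sd=noise_sd, seed=seed,
    )


def make_coumarin_trace(
    preset: GenotypePreset,
    atp_released: float | None = None,
    duration: float | None = None,
    n_points: int = 200,
    noise_frac: float = 0.02,
    seed: int = 0,
    amplitude: float = 1.0,
    floor: float = 0.0,
) -> KineticTrace:
    """Coumarin-ADP displacement decay; ADP release (k-D) rate-limits.

    A laser flash releases 15–20 μM ATP from the caged precursor, chasing
    the labeled ADP off S1; by default the released [ATP] is drawn
    uniformly from that band.
    """
    preset.require("k_minus_d")
    rng = np.random.default_rng(seed)
    if atp_released is None:
        atp_released = rng.uniform(15.0, 20.0)
    k = preset.k_minus_d
    times = _time_grid(k, duration, n_points)
    signal = floor + amplitude * np.exp(-k * times)
    noise_sd = noise_frac * amplitude
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, times.size)
    return KineticTrace(
        time=times, signal=signal, signal_type="coumarin_fluorescence",
        atp=atp_released, adp=0.0, genotype=preset.label, noise_sd=noise_sd, seed=seed,
    )


def make_trp_titration(
    preset: GenotypePreset,
    atp_grid,
    reps: int = 1,
    noise_frac: float = 0.02,
    seed: int = 0,
    mode: str = "closed_form",
    n_points: int = 200,
    baseline: float = 1.0,
    amplitude_band: tuple = (0.02, 0.04),
    dead_time: float = DEAD_TIME,
    rate_cap: float = RATE_RELIABILITY_CAP,
    stiffness_factor: float = 100.0,
    hydrolysis_equilibrium: float = 3.0,
) -> list[KineticTrace]:
    """Rising tryptophan transients across an [ATP] grid.

    Rates follow the binding/hydrolysis hyperbola; the relative amplitude
    is drawn per trace from ``amplitude_band`` independently of [ATP].  The
    first ``dead_time`` seconds are unobserved (stopped-flow dead time).
    Traces whose generating rate exceeds ``rate_cap`` are emitted with an
    :class:`UnreliableRateWarning` (evaluation above ~200 s⁻¹ is
    instrument-limited).
    """
    rng = np.random.default_rng(seed)
    traces: list[KineticTrace] = []
    micro = None
    if mode == "ode":
        micro = micro_from_preset(
            preset, "scheme1",
            stiffness_factor=stiffness_factor,
            hydrolysis_equilibrium=hydrolysis_equilibrium,
        )
    for atp in atp_grid:
        k = analytic_kobs_binding(preset, atp)
        if k > rate_cap:
            warnings.warn(
                f"generated rate {k:.0f} s⁻¹ at [ATP] = {atp} μM exceeds the "
                f"{rate_cap:.0f} s⁻¹ reliability cap",
                UnreliableRateWarning, stacklevel=2,
            )
        for _ in range(reps):
            rel_amp = rng.uniform(*amplitude_band)
            times = dead_time + _time_grid(k, None, n_points)
            if mode == "closed_form":
                signal = baseline * (1.0 + rel_amp * (1.0 - np.exp(-k * times)))
            elif mode == "ode":
                traj = simulate_scheme(micro, atp=atp, times=times)
                trace = observable_projection(
                    traj, "trp_fluorescence", baseline=baseline, relative_amplitude=rel_amp
                )
                signal = trace.signal
            else:
                raise ValueError(f"unknown mode {mode!r}")
            noise_sd = noise_frac * baseline * rel_amp
            if noise_sd > 0:
                signal = signal + rng.normal(0.0, noise_sd, times.size)
            traces.append(KineticTrace(
                time=times, signal=signal, signal_type="trp_fluorescence",
                atp=atp, adp=0.0, genotype=preset.label, noise_sd=noise_sd, seed=seed,
            ))
    return traces


# ---------------------------------------------------------------------------
# titration series
# ---------------------------------------------------------------------------

def make_competition_series(
    preset: GenotypePreset,
    atp: float = 100.0,
    adp_grid=(0.0, 100.0, 200.0, 400.0, 800.0, 1600.0),
    reps: int = 1,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> TitrationSeries:
    """Observed dissociation rates vs [ADP] at fixed [ATP].

    Rates scatter around the competition model with s.d. proportional to
    the rate.  The [ADP] = 0 anchor k0 (needed to form k_rel = k_obs/k0)
    is the mean of the generated zero-ADP observations.
    """
    preset.require("k1k2_acto", "k_ad")
    adp_grid = np.asarray(list(adp_grid), dtype=float)
    if adp_grid.size > 1 and adp_grid.max() < 2.0 * preset.k_ad:
        warnings.warn(
            f"[ADP] grid tops out at {adp_grid.max():.0f} μM < 2×K_AD = "
            f"{2 * preset.k_ad:.0f} μM; the competition fit will be poorly conditioned",
            PoorConditioningWarning, stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    conc, kobs, rep_ids = [], [], []
    for adp in adp_grid:
        k_true = analytic_kobs_dissociation(preset, atp, adp)
        for r in range(reps):
            k = k_true * (1.0 + noise_frac * rng.standard_normal()) if noise_frac > 0 else k_true
            conc.append(adp)
            kobs.append(k)
            rep_ids.append(r)
    conc = np.asarray(conc)
    kobs = np.asarray(kobs)
    at_zero = kobs[conc == 0]
    k0 = float(at_zero.mean()) if at_zero.size else None
    return TitrationSeries(
        ligand="ADP", conc=conc, kobs=kobs, rep=np.asarray(rep_ids),
        fixed_atp=atp, k0=k0, genotype=preset.label, seed=seed,
    )


# ---------------------------------------------------------------------------
# steady-state ATPase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ATPaseDataset:
    """Per-preparation steady-state ATPase measurements for one genotype.

    ``rates`` columns: prep_id, actin_uM, rate_per_s (total Mg2+-ATPase
    until basal subtraction).  ``basal`` columns: prep_id, basal_ca,
    basal_mg.  ``basal_subtracted`` flags whether the matching
    preparation's basal Mg2+ rate has been removed from the activated
    points; ``clipped`` counts rates clipped at zero by the subtraction.
    """

    genotype: str
    rates: pd.DataFrame
    basal: pd.DataFrame
    basal_subtracted: bool = False
    seed: int | None = None
    clipped: int = 0

    def __post_init__(self) -> None:
        if self.n_preps < 3:
            raise ValueError("need at least three preparations")
        if (self.rates["rate_per_s"] < 0).any() and self.basal_subtracted:
            raise ValueError("subtracted rates must be non-negative")

    @property
    def n_preps(self) -> int:
        return int(self.rates["prep_id"].nunique())

    def to_csv(self, path_or_buf) -> None:
        merged = self.rates.merge(self.basal, on="prep_id")
        merged.insert(0, "genotype", self.genotype)
        merged["basal_subtracted"] = self.basal_subtracted
        merged.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ATPaseDataset":
        frame = pd.read_csv(path_or_buf)
        basal = frame[["prep_id", "basal_ca", "basal_mg"]].drop_duplicates("prep_id")
        rates = frame[["prep_id", "actin_uM", "rate_per_s"]].copy()
        return cls(
            genotype=str(frame["genotype"].iloc[0]),
            rates=rates.reset_index(drop=True),
            basal=basal.reset_index(drop=True),
            basal_subtracted=bool(frame["basal_subtracted"].iloc[0]),
        )


def make_atpase_dataset(
    preset: GenotypePreset,
    actin_grid=(0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0),
    n_preps: int = 4,
    noise_frac: float = 0.10,
    seed: int = 0,
    prep_cv: float = 0.10,
) -> ATPaseDataset:
    """Steady-state ATPase dataset with replicate preparation structure.

    Each preparation carries unit-mean lognormal multipliers (coefficient
    of variation ``prep_cv``) on Vmax, Km and the basal rates; measured
    activated rates are Gaussian around that preparation's
    Michaelis–Menten curve plus its basal Mg2+ rate, with s.d.
    ``noise_frac`` × the preparation's Vmax.  Rates are raw (basal not yet
    subtracted).
    """
    preset.require("vmax", "km", "basal_ca", "basal_mg")
    if n_preps < 3:
        raise ValueError("the replicate design uses a minimum of three preparations")
    actin_grid = np.asarray(list(actin_grid), dtype=float)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(prep_cv * prep_cv)) if prep_cv > 0 else 0.0

    def draw() -> float:
        return rng.lognormal(-0.5 * sigma * sigma, sigma) if sigma > 0 else 1.0

    rate_rows, basal_rows = [], []
    for prep in range(n_preps):
        vmax_p = preset.vmax * draw()
        km_p = preset.km * draw()
        bca_p = preset.basal_ca * draw()
        bmg_p = preset.basal_mg * draw()
        noise_sd = noise_frac * vmax_p
        for actin in actin_grid:
            rate = vmax_p * actin / (km_p + actin) + bmg_p
            if noise_sd > 0:
                rate += rng.normal(0.0, noise_sd)
            rate_rows.append((prep, actin, max(rate, 0.0)))
        basal_rows.append((
            prep,
            max(bca_p + (rng.normal(0.0, noise_frac * bca_p) if noise_frac > 0 else 0.0), 0.0),
            max(bmg_p + (rng.normal(0.0, noise_frac * bmg_p) if noise_frac > 0 else 0.0), 0.0),
        ))
    rates = pd.DataFrame(rate_rows, columns=["prep_id", "actin_uM", "rate_per_s"])
    basal = pd.DataFrame(basal_rows, columns=["prep_id", "basal_ca", "basal_mg"])
    return ATPaseDataset(
        genotype=preset.label, rates=rates, basal=basal,
        basal_subtracted=False, seed=seed,
    )
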