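"""Kinetic schemes of the actomyosin cross-bridge cycle.

Two linear reaction schemes cover the transient experiments:

* **scheme2** — ATP-induced dissociation of the rigor complex, with ADP
  competition::

      A·M·D  ⇌  A·M + D
      A·M + T  ⇌  A·M·T  →  A·M‡·T  →  A + M·T   (detachment, irreversible)

  Under pseudo-first-order conditions the light-scattering decay is a single
  exponential with observed rate

      k_obs = K'1·k'+2 · [ATP] / (1 + [ADP]/K_AD)

  where K'1k'+2 is the apparent second-order ATP-binding constant to acto-S1
  and K_AD the ADP dissociation constant of acto-S1.

* **scheme1** — two-step ATP binding to S1 followed by the reversible
  hydrolysis/recovery-stroke step::

      M + T  ⇌(K1)  M·T  →(k+2)  M*·T  ⇌(k+3/k-3)  M**·D·Pi

  With the tryptophan signal reporting the post-hydrolysis state, the
  observed rate follows the saturation hyperbola

      k_obs = (k+3 + k-3) · [ATP] / ((k+3 + k-3)/(K1k+2) + [ATP])

  whose initial slope is K1k+2 and whose plateau is k+3 + k-3.  The
  half-saturating concentration is K0.5 = (k+3 + k-3)/(K1k+2).

A third, trivial scheme (**displacement**) realizes the coumarin-ADP
displacement experiment: M·D* → M + D* at rate k-D under an ATP chase.

Only the composite constants above are measured; :func:`micro_from_preset`
constructs a set of elementary rate constants consistent with them (fast
pre-equilibria, configurable hydrolysis split), and :func:`simulate_scheme`
integrates the resulting linear ODE system exactly.  The simulator is the
brute-force oracle against which the closed forms are checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import (
    ConstructionError,
    IncompletePresetError,
    InvalidConditionError,
    SignalSchemeMismatchError,
)
from .presets import GenotypePreset
from .traces import KineticTrace

__all__ = [
    "MicroRates",
    "StateTrajectory",
    "SCHEME_STATES",
    "analytic_kobs_dissociation",
    "analytic_kobs_binding",
    "predicted_K05",
    "micro_from_preset",
    "simulate_scheme",
    "observable_projection",
]

SCHEME_STATES = {
    "scheme1": ("M", "M.T", "M*.T", "M**.D.Pi"),
    "scheme2": ("A.M.D", "A.M", "A.M.T", "detached"),
    "displacement": ("M.D*", "M"),
}

#: Largest elementary rate constant the ODE construction will accept (s⁻¹).
RATE_CAP = 1e9


# ---------------------------------------------------------------------------
# closed-form observed-rate models
# ---------------------------------------------------------------------------

def analytic_kobs_dissociation(preset: GenotypePreset, atp: float, adp: float = 0.0) -> float:
    """Observed rate of ATP-induced acto-S1 dissociation with ADP competition.

    k_obs = K'1k'+2 · [ATP] / (1 + [ADP]/K_AD), in s⁻¹.  Linear in [ATP] at
    fixed [ADP]; halves at [ADP] = K_AD.
    """
    if not np.isfinite(atp) or atp <= 0:
        raise InvalidConditionError(f"[ATP] must be positive, got {atp}")
    if adp < 0:
        raise InvalidConditionError(f"[ADP] must be non-negative, got {adp}")
    preset.require("k1k2_acto")
    if adp > 0:
        preset.require("k_ad")
        return preset.k1k2_acto * atp / (1.0 + adp / preset.k_ad)
    return preset.k1k2_acto * atp


def analytic_kobs_binding(preset: GenotypePreset, atp: float) -> float:
    """Observed rate of the tryptophan transient for ATP binding to S1.

    The two-step binding/hydrolysis hyperbola
    k_obs = (k+3+k-3)·[ATP] / ((k+3+k-3)/(K1k+2) + [ATP]); initial slope
    K1k+2, plateau k+3 + k-3.
    """
    if not np.isfinite(atp) or atp < 0:
        raise InvalidConditionError(f"[ATP] must be non-negative, got {atp}")
    preset.require("k1k2_s1", "k_hyd_sum")
    if not (np.isfinite(preset.k1k2_s1) and np.isfinite(preset.k_hyd_sum)):
        raise IncompletePresetError("non-finite binding/hydrolysis constants")
    if atp == 0:
        return 0.0
    return preset.k_hyd_sum * atp / (preset.k_hyd_sum / preset.k1k2_s1 + atp)


def predicted_K05(preset: GenotypePreset) -> float:
    """Half-saturating [ATP] implied by the two-step model: (k+3+k-3)/(K1k+2).

    The consistency test of the standard assignment: the measured K0.5
    should match this ratio for every genotype.
    """
    preset.require("k1k2_s1", "k_hyd_sum")
    if preset.k1k2_s1 == 0:
        raise ConstructionError("degenerate preset: K1k+2 = 0")
    return preset.k_hyd_sum / preset.k1k2_s1


# ---------------------------------------------------------------------------
# elementary rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicroRates:
    """Elementary rate constants realizing one scheme.

    Composite consistency (checked by construction): for scheme2,
    (k+1/k-1)·k+2 equals the preset's K'1k'+2 and adp_off/adp_on = K_AD;
    for scheme1, (k+1/k-1)·k+2 = K1k+2 and k+3 + k-3 = k_hyd_sum with
    k+3/k-3 the chosen hydrolysis equilibrium constant.
    """

    scheme: str
    k_plus1: float = 0.0    # μM⁻¹s⁻¹ ATP association
    k_minus1: float = 0.0   # s⁻¹ ATP dissociation
    k_plus2: float = 0.0    # s⁻¹ isomerization (scheme1) / dissociation (scheme2)
    k_minus2: float = 0.0   # s⁻¹ reverse isomerization (scheme1 only; 0 here)
    k_plus3: float = 0.0    # s⁻¹ hydrolysis forward (scheme1)
    k_minus3: float = 0.0   # s⁻¹ hydrolysis reverse (scheme1)
    adp_on: float = 0.0     # μM⁻¹s⁻¹ ADP association to acto-S1 (scheme2)
    adp_off: float = 0.0    # s⁻¹ ADP dissociation from acto-S1 (scheme2)
    k_release: float = 0.0  # s⁻¹ labeled-ADP release (displacement)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_STATES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name in ("k_plus1", "k_minus1", "k_plus2", "k_minus2",
                     "k_plus3", "k_minus3", "adp_on", "adp_off", "k_release"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def micro_from_preset(
    preset: GenotypePreset,
    scheme: str,
    stiffness_factor: float = 100.0,
    hydrolysis_equilibrium: float = 3.0,
    atp_max: float = 1000.0,
) -> MicroRates:
    """Construct elementary rates whose composites reproduce the preset.

    The measurements constrain only composite constants, so the fast
    pre-equilibria are free choices: the rate-limiting step is set
    ``stiffness_factor`` times faster than the largest observed rate in the
    design range (``atp_max`` μM of ATP), and the preceding equilibration
    another factor faster.  For scheme1 the hydrolysis sum is split as
    k+3/k-3 = ``hydrolysis_equilibrium`` (small, consistent with the
    near-balanced recovery-stroke energetics of muscle myosin II).

    Raises :class:`ConstructionError` when the constraints cannot be met
    (zero composite constants, or rates forced beyond ``RATE_CAP``).
    """
    if stiffness_factor < 10:
        raise ValueError("stiffness_factor must be >= 10")
    if hydrolysis_equilibrium <= 0:
        raise ValueError("hydrolysis_equilibrium must be positive")

    if scheme == "scheme2":
        preset.require("k1k2_acto")
        if preset.k1k2_acto == 0:
            raise ConstructionError("degenerate preset: K'1k'+2 = 0")
        kobs_cap = preset.k1k2_acto * atp_max
        k_plus2 = stiffness_factor * kobs_cap
        k_minus1 = stiffness_factor * k_plus2
        if k_minus1 > RATE_CAP:
            raise ConstructionError(
                f"stiffness_factor {stiffness_factor} forces k-1 = {k_minus1:.3g} s⁻¹ "
                f"beyond the cap {RATE_CAP:.0e}"
            )
        k_plus1 = preset.k1k2_acto * k_minus1 / k_plus2
        adp_off = adp_on = 0.0
        if preset.k_ad is not None:
            adp_off = stiffness_factor * kobs_cap
            adp_on = adp_off / preset.k_ad
        return MicroRates(
            scheme="scheme2", k_plus1=k_plus1, k_minus1=k_minus1,
            k_plus2=k_plus2, adp_on=adp_on, adp_off=adp_off,
        )

    if scheme == "scheme1":
        preset.require("k1k2_s1", "k_hyd_sum")
        if preset.k1k2_s1 == 0:
            raise ConstructionError("degenerate preset: K1k+2 = 0")
        k_plus2 = stiffness_factor * preset.k_hyd_sum
        k_minus1 = stiffness_factor * k_plus2
        if k_minus1 > RATE_CAP:
            raise ConstructionError(
                f"stiffness_factor {stiffness_factor} forces k-1 = {k_minus1:.3g} s⁻¹ "
                f"beyond the cap {RATE_CAP:.0e}"
            )
        k_plus1 = preset.k1k2_s1 * k_minus1 / k_plus2
        eq = hydrolysis_equilibrium
        k_plus3 = preset.k_hyd_sum * eq / (1.0 + eq)
        k_minus3 = preset.k_hyd_sum / (1.0 + eq)
        return MicroRates(
            scheme="scheme1", k_plus1=k_plus1, k_minus1=k_minus1,
            k_plus2=k_plus2, k_plus3=k_plus3, k_minus3=k_minus3,
        )

    if scheme == "displacement":
        preset.require("k_minus_d")
        return MicroRates(scheme="displacement", k_release=preset.k_minus_d)

    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# ODE simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateTrajectory:
    """Occupancy fractions of every scheme state on a time grid."""

    time: np.ndarray
    occupancies: np.ndarray  # (n_time, n_states)
    scheme: str
    atp: float
    adp: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "occupancies", np.asarray(self.occupancies, dtype=float))
        states = SCHEME_STATES[self.scheme]
        if self.occupancies.shape != (self.time.size, len(states)):
            raise ValueError("occupancy array shape mismatch")
        if np.any(self.occupancies < -1e-8) or np.any(self.occupancies > 1 + 1e-8):
            raise ValueError("occupancies outside [0, 1]")
        if np.max(np.abs(self.occupancies.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("occupancies do not sum to 1")

    @property
    def states(self) -> tuple:
        return SCHEME_STATES[self.scheme]

    def occupancy(self, state: str) -> np.ndarray:
        return self.occupancies[:, self.states.index(state)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.occupancies, columns=list(self.states))
        frame.insert(0, "time_s", self.time)
        return frame

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


def _rate_matrix(micro: MicroRates, atp: float, adp: float) -> np.ndarray:
    """Generator matrix Q with dp/dt = Q p (columns: source states)."""
    n = len(SCHEME_STATES[micro.scheme])
    q = np.zeros((n, n))

    def flow(src: int, dst: int, rate: float) -> None:
        q[dst, src] += rate
        q[src, src] -= rate

    if micro.scheme == "scheme1":
        # M(0) ⇌ M.T(1) → M*.T(2) ⇌ M**.D.Pi(3)
        flow(0, 1, micro.k_plus1 * atp)
        flow(1, 0, micro.k_minus1)
        flow(1, 2, micro.k_plus2)
        flow(2, 1, micro.k_minus2)
        flow(2, 3, micro.k_plus3)
        flow(3, 2, micro.k_minus3)
    elif micro.scheme == "scheme2":
        # A.M.D(0) ⇌ A.M(1) ⇌ A.M.T(2) → detached(3)
        flow(1, 0, micro.adp_on * adp)
        flow(0, 1, micro.adp_off)
        flow(1, 2, micro.k_plus1 * atp)
        flow(2, 1, micro.k_minus1)
        flow(2, 3, micro.k_plus2)
    else:  # displacement: M.D*(0) → M(1), ATP chase makes rebinding negligible
        if atp > 0:
            flow(0, 1, micro.k_release)
    return q


def simulate_scheme(
    micro: MicroRates,
    atp: float,
    adp: float = 0.0,
    duration: float = 0.1,
    n_points: int = 200,
    times: np.ndarray | None = None,
) -> StateTrajectory:
    """Exact solution of the pseudo-first-order linear ODE system.

    Ligand concentrations are held constant (ligand ≫ protein).  The system
    starts 100% in the initial state (M for scheme1, rigor A·M for scheme2,
    M·D* for displacement) and relaxes monotonically to its unique steady
    state.  Solved by eigendecomposition of the rate matrix, with a matrix
    exponential fallback for (near-)defective cases, so arbitrarily stiff
    elementary rates are handled without integration error.
    """
    if times is None:
        if duration <= 0:
            raise ValueError("duration must be positive")
        times = np.linspace(0.0, duration, n_points)
    else:
        times = np.asarray(times, dtype=float)
    states = SCHEME_STATES[micro.scheme]
    start = {"scheme1": "M", "scheme2": "A.M", "displacement": "M.D*"}[micro.scheme]
    p0 = np.zeros(len(states))
    p0[states.index(start)] = 1.0

    q = _rate_matrix(micro, atp, adp)
    bad = ~np.isfinite(q)
    if bad.any():
        raise ConstructionError(f"non-finite rate matrix entries: {q[bad]}")

    occ = _propagate(q, p0, times)
    # clip eigen-solver roundoff at the 1e-10 level, then renormalize
    occ = np.clip(occ, 0.0, 1.0)
    occ /= occ.sum(axis=1, keepdims=True)
    return StateTrajectory(time=times, occupancies=occ, scheme=micro.scheme, atp=atp, adp=adp)


def _propagate(q: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    try:
        lam, vec = np.linalg.eig(q)
        coef = np.linalg.solve(vec, p0)
        occ = np.real((vec * coef) @ np.exp(np.outer(lam, times))).T
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) < 1e-9:
            return occ
    except np.linalg.LinAlgError:
        pass
    # defective or ill-conditioned eigenbasis: exact matrix exponentials
    occ = np.empty((times.size, p0.size))
    for i, t in enumerate(times):
        occ[i] = expm(q * t) @ p0
    return occ


# ---------------------------------------------------------------------------
# optical observables
# ---------------------------------------------------------------------------

def observable_projection(
    traj: StateTrajectory,
    signal_type: str,
    amplitude: float = 1.0,
    floor: float = 0.0,
    baseline: float = 1.0,
    relative_amplitude: float = 0.035,
    genotype: str = "",
) -> KineticTrace:
    """Project state occupancies onto an optical signal (noise free).

    * ``light_scattering`` (scheme2): proportional to the actin-attached
      fraction; decreases on dissociation.  signal = floor + amplitude ×
      (1 − detached fraction).
    * ``trp_fluorescence`` (scheme1): rises on hydrolysis; signal =
      baseline × (1 + relative_amplitude × occupancy(M**·D·Pi) / f∞), with
      f∞ = k+3/(k+3+k-3) the equilibrium occupancy, so the total fractional
      change equals ``relative_amplitude`` (3–4% band by default).
    * ``coumarin_fluorescence`` (displacement): decreases as the labeled
      ADP leaves; signal = floor + amplitude × occupancy(M·D*).

    Amplitudes are instrument configuration, not physics.
    """
    want = {"light_scattering": "scheme2", "trp_fluorescence": "scheme1",
            "coumarin_fluorescence": "displacement"}
    if signal_type not in want:
        raise SignalSchemeMismatchError(f"unknown signal_type {signal_type!r}")
    if want[signal_type] != traj.scheme:
        raise SignalSchemeMismatchError(
            f"{signal_type} is not an observable of {traj.scheme}"
        )

    if signal_type == "light_scattering":
        bound = 1.0 - traj.occupancy("detached")
        signal = floor + amplitude * bound
    elif signal_type == "trp_fluorescence":
        occ = traj.occupancy("M**.D.Pi")
        f_inf = occ[-1] if occ[-1] > 0 else 1.0
        signal = baseline * (1.0 + relative_amplitude * occ / f_inf)
    else:
        signal = floor + amplitude * traj.occupancy("M.D*")

    return KineticTrace(
        time=traj.time, signal=signal, signal_type=signal_type,
        atp=traj.atp, adp=traj.adp, genotype=genotype, noise_sd=0.0,
    )
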