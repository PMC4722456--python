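"""Genotype parameter presets.

A :class:`GenotypePreset` collects every composite kinetic constant measured
for one myosin S1 genotype — the apparent second-order ATP-binding constants
to acto-S1 (K'1k'+2) and to S1 alone (K1k+2), the ADP affinity of acto-S1
(K_AD), the ADP release rate from S1 (k-D), the maximum observed rate of the
hydrolysis/recovery-stroke step (k+3 + k-3), the half-saturating ATP
concentration (K0.5), and the steady-state ATPase parameters (Vmax, Km,
basal Ca2+ and Mg2+ rates).  These are the ground truth used by the
synthetic-data generators and the target of every recovery experiment.

Units are μM and s throughout: second-order constants in μM⁻¹s⁻¹,
first-order constants in s⁻¹, concentrations in μM.

The shipped registry carries one preset per genotype (wild-type indirect
flight muscle S1, the converter mutant R759E, and the converter/relay double
mutant R759E/N509K), each value with its between-preparation standard
deviation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .errors import IncompletePresetError

__all__ = ["GenotypePreset", "load_preset", "load_registry", "perturb_preset", "PARAM_NAMES"]

#: Kinetic parameters a preset may carry (all optional except the label).
PARAM_NAMES = (
    "k1k2_acto",   # μM⁻¹s⁻¹, ATP-induced acto-S1 dissociation (K'1k'+2)
    "k_ad",        # μM, ADP dissociation constant of acto-S1
    "k_minus_d",   # s⁻¹, ADP release from S1
    "k1k2_s1",     # μM⁻¹s⁻¹, ATP binding to S1 (K1k+2)
    "k_hyd_sum",   # s⁻¹, hydrolysis step (k+3 + k-3)
    "k05",         # μM, half-saturating [ATP] (1/K0.5 of the hyperbola)
    "vmax",        # s⁻¹, actin-activated Mg2+-ATPase maximum
    "km",          # μM, actin concentration at Vmax/2
    "basal_ca",    # s⁻¹, basal Ca2+-ATPase
    "basal_mg",    # s⁻¹, basal Mg2+-ATPase
)


@dataclass(frozen=True)
class GenotypePreset:
    """Composite kinetic constants for one genotype.

    All rate/concentration fields are optional; operations that need a
    missing field raise :class:`~myokin.errors.IncompletePresetError`.
    ``sd`` maps field names to standard deviations where reported.
    """

    label: str
    k1k2_acto: float | None = None
    k_ad: float | None = None
    k_minus_d: float | None = None
    k1k2_s1: float | None = None
    k_hyd_sum: float | None = None
    k05: float | None = None
    vmax: float | None = None
    km: float | None = None
    basal_ca: float | None = None
    basal_mg: float | None = None
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if value is None:
                continue
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{self.label}: {name} must be strictly positive, got {value!r}")
        # Consistency of the two-step binding model: under the standard
        # assignment the half-saturating [ATP] equals (k+3 + k-3)/(K1k+2).
        if self.k05 is not None and self.k_hyd_sum is not None and self.k1k2_s1 is not None:
            predicted = self.k_hyd_sum / self.k1k2_s1
            if abs(self.k05 - predicted) > 0.30 * predicted:
                raise ValueError(
                    f"{self.label}: K0.5 = {self.k05} μM is inconsistent with "
                    f"(k+3+k-3)/(K1k+2) = {predicted:.1f} μM (>30% apart)"
                )

    def require(self, *names: str) -> None:
        """Raise IncompletePresetError unless every named field is present."""
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise IncompletePresetError(f"preset {self.label!r} lacks {', '.join(missing)}")

    def to_dict(self) -> dict:
        out = {"label": self.label}
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if value is not None:
                out[name] = {"value": value, "sd": self.sd.get(name)}
        return out

    @classmethod
    def from_dict(cls, record: dict) -> "GenotypePreset":
        kwargs: dict = {"label": record["label"]}
        sd: dict = {}
        for name in PARAM_NAMES:
            entry = record.get(name)
            if entry is None:
                continue
            if isinstance(entry, dict):
                kwargs[name] = entry["value"]
                if entry.get("sd") is not None:
                    sd[name] = entry["sd"]
            else:
                kwargs[name] = float(entry)
        return cls(sd=sd, **kwargs)


def load_registry() -> dict[str, GenotypePreset]:
    """Load the shipped genotype registry (wild-type, R759E, R759E/N509K)."""
    text = resources.files("myokin.data").joinpath("presets.json").read_text()
    raw = json.loads(text)
    return {name: GenotypePreset.from_dict(rec) for name, rec in raw.items()}


def load_preset(name: str) -> GenotypePreset:
    """Load one genotype preset from the shipped registry by name."""
    registry = load_registry()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(f"unknown genotype {name!r}; available: {sorted(registry)}") from None


def perturb_preset(preset: GenotypePreset, cv: float, rng: np.random.Generator) -> GenotypePreset:
    """Apply an independent lognormal preparation multiplier to every parameter.

    Emulates between-preparation variability: each kinetic constant is
    multiplied by exp(N(-σ²/2, σ)) with σ = sqrt(ln(1 + cv²)), a unit-mean
    lognormal factor.  ``cv = 0`` returns the preset unchanged.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if cv == 0:
        return preset
    sigma = math.sqrt(math.log1p(cv * cv))
    updates: dict = {}
    for name in PARAM_NAMES:
        value = getattr(preset, name)
        if name == "k05":
            continue  # recomputed below to preserve the consistency identity
        if value is not None:
            updates[name] = value * rng.lognormal(-0.5 * sigma * sigma, sigma)
    if preset.k05 is not None:
        if "k_hyd_sum" in updates and "k1k2_s1" in updates:
            updates["k05"] = updates["k_hyd_sum"] / updates["k1k2_s1"]
        else:
            updates["k05"] = preset.k05
    return replace(preset, **updates)
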