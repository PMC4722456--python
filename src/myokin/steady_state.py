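"""Steady-state actin-activated ATPase analysis.

Basal Mg2+-ATPase rates measured without actin are subtracted from every
actin-activated point of the matching preparation; the activated rates are
then fitted with the Michaelis–Menten equation,

    v([A]) = Vmax·[A] / (Km + [A]),

either per preparation with the estimates averaged (mean ± S.D., the
default convention) or pooled across preparations.  Catalytic efficiency is
the ratio Vmax/Km.  Genotype comparisons use two-sided Student's t tests
(equal variance by default) with the conventional significance tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DoubleSubtractionError, WideIntervalWarning
from .synthetic import ATPaseDataset

import warnings

__all__ = [
    "MichaelisFit",
    "ComparisonResult",
    "subtract_basal",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "compare_genotypes",
]

logger = logging.getLogger(__name__)

SIGNIFICANCE_TIERS = ((0.001, "p<0.001"), (0.01, "p<0.01"), (0.05, "p<0.05"))


@dataclass(frozen=True)
class MichaelisFit:
    """Michaelis–Menten fit summary for one genotype.

    ``catalytic_efficiency`` is the literal ratio vmax/km of the reported
    values; ``per_prep`` holds the per-preparation estimates when the
    fit-then-average convention was used.
    """

    genotype: str
    vmax: float
    vmax_sd: float
    km: float
    km_sd: float
    catalytic_efficiency: float
    efficiency_sd: float
    n_preps: int
    pooled: bool
    per_prep: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("Vmax and Km must be positive")
        if abs(self.catalytic_efficiency - self.vmax / self.km) > 1e-9 * abs(self.vmax / self.km):
            raise ValueError("catalytic_efficiency must equal Vmax/Km")


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample Student's t comparison of one quantity between genotypes."""

    quantity: str
    pair: tuple
    t_stat: float
    p_value: float
    tier: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p value outside [0, 1]")
        if self.tier != assign_tier(self.p_value):
            raise ValueError("tier inconsistent with p value")


def assign_tier(p: float) -> str:
    for threshold, tier in SIGNIFICANCE_TIERS:
        if p < threshold:
            return tier
    return "ns"


def subtract_basal(dataset: ATPaseDataset) -> ATPaseDataset:
    """Subtract each preparation's basal Mg2+ rate from its activated points.

    Negative results are clipped to zero and counted (``clipped``).
    Subtracting twice raises :class:`DoubleSubtractionError`.
    """
    if dataset.basal_subtracted:
        raise DoubleSubtractionError("basal rates were already subtracted")
    basal_mg = dataset.basal.set_index("prep_id")["basal_mg"]
    rates = dataset.rates.copy()
    adjusted = rates["rate_per_s"] - rates["prep_id"].map(basal_mg)
    clipped = int((adjusted < 0).sum())
    if clipped:
        logger.info("basal subtraction clipped %d negative rates to zero", clipped)
    rates["rate_per_s"] = adjusted.clip(lower=0.0)
    return replace(dataset, rates=rates, basal_subtracted=True,
                   clipped=dataset.clipped + clipped)


def _fit_mm(actin: np.ndarray, rate: np.ndarray) -> tuple[float, float, np.ndarray]:
    vmax0 = float(rate.max()) if rate.max() > 0 else 1.0
    km0 = float(np.median(actin[actin > 0])) if (actin > 0).any() else 1.0

    def model(a, vmax, km):
        return vmax * a / (km + a)

    popt, pcov = optimize.curve_fit(
        model, actin, rate, p0=[vmax0, km0], bounds=(0.0, np.inf), maxfev=20000
    )
    return float(popt[0]), float(popt[1]), pcov


def fit_michaelis_menten(dataset: ATPaseDataset, pooled: bool = False) -> MichaelisFit:
    """Fit Vmax and Km of the actin-activated Mg2+-ATPase.

    Default convention: fit each preparation separately, then average the
    estimates (mean ± S.D.).  ``pooled=True`` fits all points at once, with
    standard errors from the fit covariance.  Requires basal-subtracted
    data and at least four distinct actin concentrations.
    """
    if not dataset.basal_subtracted:
        raise ValueError("subtract basal rates before fitting")
    actin_all = dataset.rates["actin_uM"].to_numpy()
    if np.unique(actin_all).size < 4:
        raise ValueError("need at least four distinct actin concentrations")

    if pooled:
        rate_all = dataset.rates["rate_per_s"].to_numpy()
        vmax, km, pcov = _fit_mm(actin_all, rate_all)
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        vmax_sd, km_sd = float(perr[0]), float(perr[1])
        per_prep = None
    else:
        rows = []
        for prep, grp in dataset.rates.groupby("prep_id"):
            v, k, _ = _fit_mm(grp["actin_uM"].to_numpy(), grp["rate_per_s"].to_numpy())
            rows.append((prep, v, k, v / k))
        per_prep = pd.DataFrame(rows, columns=["prep_id", "vmax", "km", "efficiency"])
        vmax = float(per_prep["vmax"].mean())
        km = float(per_prep["km"].mean())
        vmax_sd = float(per_prep["vmax"].std(ddof=1)) if len(per_prep) > 1 else 0.0
        km_sd = float(per_prep["km"].std(ddof=1)) if len(per_prep) > 1 else 0.0

    if actin_all.max() < km:
        warnings.warn(
            f"no actin concentration above the Km estimate ({km:.1f} μM); "
            "Vmax is extrapolated",
            WideIntervalWarning, stacklevel=2,
        )
    efficiency = vmax / km
    efficiency_sd = _ratio_sd(vmax, vmax_sd, km, km_sd)
    return MichaelisFit(
        genotype=dataset.genotype, vmax=vmax, vmax_sd=vmax_sd, km=km, km_sd=km_sd,
        catalytic_efficiency=efficiency, efficiency_sd=efficiency_sd,
        n_preps=dataset.n_preps, pooled=pooled, per_prep=per_prep,
    )


def _ratio_sd(v: float, sv: float, k: float, sk: float) -> float:
    if v == 0 or k == 0:
        return 0.0
    return abs(v / k) * float(np.hypot(sv / v, sk / k))


def catalytic_efficiency(fit: MichaelisFit) -> tuple[float, float]:
    """Vmax/Km with its first-order-propagated standard deviation."""
    return fit.catalytic_efficiency, _ratio_sd(fit.vmax, fit.vmax_sd, fit.km, fit.km_sd)


def compare_genotypes(
    quantity: str,
    pair: tuple,
    sample_a,
    sample_b,
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sided Student's t test between two genotype samples.

    Equal-variance (pooled) by default, matching the conventional
    reporting; ``equal_var=False`` selects Welch's correction.  Two
    zero-variance samples with equal means return t = 0, p = 1 by
    convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return ComparisonResult(quantity, tuple(pair), 0.0, 1.0, "ns")
        raise ValueError("zero-variance samples with unequal means: t undefined")
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        quantity=quantity, pair=tuple(pair),
        t_stat=float(t_stat), p_value=float(p_value), tier=assign_tier(float(p_value)),
    )
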