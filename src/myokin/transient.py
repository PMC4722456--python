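"""Transient-kinetics fitting: single exponentials and secondary models.

Primary analysis: every light-scattering, coumarin or tryptophan transient
is fitted with a single exponential, signal(t) = offset + a·exp(−k_obs·t),
to extract the observed rate constant k_obs.

Secondary analysis, on the resulting titration series:

* ``linear`` — k_obs vs [ATP] for acto-S1 dissociation; the zero-intercept
  slope is the apparent second-order constant K'1k'+2 (μM⁻¹s⁻¹).
* ``competition`` — k_rel = k_obs/k0 vs [ADP] at fixed [ATP]; fitting
  k_rel = 1/(1 + [ADP]/K_AD) gives the ADP affinity of acto-S1.
* ``hyperbola`` — k_obs vs [ATP] for the tryptophan signal; the
  parameterization k_obs = kmax·[ATP]/(kmax/K1k+2 + [ATP]) estimates the
  second-order binding constant K1k+2 (initial slope) and the
  hydrolysis-step sum kmax = k+3 + k-3 (plateau), with K0.5 = kmax/K1k+2
  reported as the derived ratio.

Least squares is unweighted with replicate points entered individually.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    CurvatureWarning,
    FitFailureError,
    PoorConditioningWarning,
    UnreliableRateError,
    UnsaturatedTitrationError,
    WideIntervalWarning,
)
from .traces import KineticTrace

__all__ = [
    "ExponentialFit",
    "TitrationSeries",
    "TitrationFit",
    "fit_single_exponential",
    "fit_linear_titration",
    "fit_adp_competition",
    "fit_hyperbolic_titration",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExponentialFit:
    """Single-exponential fit result.

    ``amplitude`` is the signed total signal change from t = 0 to the
    asymptote (negative for a decay, positive for a rise); ``offset`` is
    the asymptotic signal level.
    """

    k_obs: float
    amplitude: float
    offset: float
    k_obs_se: float
    amplitude_se: float
    offset_se: float
    residual_sd: float
    n_points: int
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and self.k_obs <= 0:
            raise ValueError("a converged fit must report a positive rate")
        for name in ("k_obs_se", "amplitude_se", "offset_se"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """Observed rate constants vs ligand concentration.

    ``k0`` is the [ADP] = 0 anchor used to normalize competition series
    (k_rel = k_obs/k0); ``fixed_atp`` records the constant [ATP] of an ADP
    competition.  Replicate points are stored individually.
    """

    ligand: str                      # "ATP" | "ADP"
    conc: np.ndarray                 # μM
    kobs: np.ndarray                 # s⁻¹
    rep: np.ndarray | None = None
    fixed_atp: float | None = None
    k0: float | None = None
    genotype: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        object.__setattr__(self, "kobs", np.asarray(self.kobs, dtype=float))
        if self.ligand not in ("ATP", "ADP"):
            raise ValueError("ligand must be 'ATP' or 'ADP'")
        if self.conc.size != self.kobs.size or self.conc.size == 0:
            raise ValueError("conc and kobs must be equal-length, non-empty")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.ptp(self.conc) == 0:
            raise ValueError("concentrations must not all be equal")
        if np.any(self.kobs <= 0):
            raise ValueError("observed rates must be positive")

    def to_csv(self, path_or_buf) -> None:
        frame = pd.DataFrame({
            "ligand_uM": self.conc,
            "kobs_per_s": self.kobs,
            "rep": self.rep if self.rep is not None else 0,
        })
        header = (
            f"# ligand: {self.ligand}\n"
            f"# fixed_atp_uM: {'' if self.fixed_atp is None else self.fixed_atp}\n"
            f"# k0_per_s: {'' if self.k0 is None else self.k0}\n"
            f"# genotype: {self.genotype}\n"
        )
        text = header + frame.to_csv(index=False)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TitrationSeries":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta: dict = {}
        body = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            elif line.strip():
                body.append(line)
        frame = pd.read_csv(io.StringIO("\n".join(body)))
        return cls(
            ligand=meta.get("ligand", "ATP"),
            conc=frame["ligand_uM"].to_numpy(),
            kobs=frame["kobs_per_s"].to_numpy(),
            rep=frame["rep"].to_numpy() if "rep" in frame else None,
            fixed_atp=float(meta["fixed_atp_uM"]) if meta.get("fixed_atp_uM") else None,
            k0=float(meta["k0_per_s"]) if meta.get("k0_per_s") else None,
            genotype=meta.get("genotype", ""),
        )


@dataclass(frozen=True)
class TitrationFit:
    """Secondary-model fit: parameter estimates, standard errors, diagnostics."""

    model: str                       # "linear" | "competition" | "hyperbola"
    params: dict
    se: dict
    rss: float
    n_points: int
    notes: tuple = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model == "hyperbola":
            k05 = self.params["K05"]
            ratio = self.params["k_hyd_sum"] / self.params["K1k2_s1"]
            if abs(k05 - ratio) > 1e-6 * abs(ratio):
                raise ValueError("K05 must equal k_hyd_sum/K1k2_s1 by construction")

    def to_json_record(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "se": dict(self.se),
            "rss": self.rss,
            "n_points": self.n_points,
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# single-exponential fitting
# ---------------------------------------------------------------------------

def _exp_model(t, offset, a, k):
    return offset + a * np.exp(-k * t)


def fit_single_exponential(
    trace: KineticTrace,
    window: tuple | None = None,
    max_restarts: int = 3,
) -> ExponentialFit:
    """Least-squares single-exponential fit of one transient.

    ``window`` restricts the fit to time bounds (t_lo, t_hi).  The initial
    rate guess comes from the time to half signal change; on
    non-convergence the fit restarts up to ``max_restarts`` times from
    perturbed initializations.  A fitted half-life shorter than two median
    sampling intervals raises :class:`UnreliableRateError` (the rate is
    not resolvable on this grid).
    """
    t = trace.time
    y = trace.signal
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, y = t[keep], y[keep]
    if t.size < 10:
        raise FitFailureError(f"need >= 10 points in the fit window, got {t.size}")
    span = float(np.ptp(y))
    if span == 0:
        raise FitFailureError("signal is constant; no relaxation to fit")

    # shift the window origin so 'amplitude at t=0' refers to the first sample
    t0 = t[0]
    ts = t - t0
    offset0 = float(y[-1])
    a0 = float(y[0] - y[-1])
    half = y[0] + 0.5 * (y[-1] - y[0])
    idx = int(np.argmin(np.abs(y - half)))
    k0 = np.log(2.0) / max(ts[idx], ts[1] if ts[1] > 0 else 1e-9)

    rng = np.random.default_rng(12345)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            p0 = [offset0, a0, k0]
        else:
            p0 = [
                offset0 + 0.1 * span * rng.standard_normal(),
                a0 * rng.uniform(0.5, 2.0),
                k0 * rng.uniform(0.3, 3.0),
            ]
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model, ts, y, p0=p0,
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            break
        except (RuntimeError, optimize.OptimizeWarning) as err:
            last_err = err
    else:
        raise FitFailureError(
            f"single-exponential fit did not converge after {max_restarts} restarts: {last_err}"
        )

    offset, a, k = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = y - _exp_model(ts, *popt)
    dof = max(t.size - 3, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))

    dt = float(np.median(np.diff(t)))
    if k > 0 and np.log(2.0) / k < 2.0 * dt:
        raise UnreliableRateError(
            f"fitted half-life {np.log(2.0)/k:.2e} s is below two sampling "
            f"intervals ({dt:.2e} s); rate unresolvable"
        )
    if k <= 0:
        raise FitFailureError("fit collapsed to a zero rate")
    return ExponentialFit(
        k_obs=float(k), amplitude=float(-a), offset=float(offset),
        k_obs_se=float(perr[2]), amplitude_se=float(perr[1]), offset_se=float(perr[0]),
        residual_sd=residual_sd, n_points=int(t.size), converged=True,
    )


# ---------------------------------------------------------------------------
# secondary fits
# ---------------------------------------------------------------------------

def fit_linear_titration(
    series: TitrationSeries,
    through_origin: bool = True,
    curvature_alpha: float = 0.01,
) -> TitrationFit:
    """Zero-intercept line through k_obs vs [ATP]: slope = K'1k'+2.

    A free intercept is reported as a diagnostic.  If an origin-constrained
    quadratic term is significant at ``curvature_alpha`` (lack-of-fit
    F-test), a :class:`CurvatureWarning` signals that the grid extends out
    of the linear regime.
    """
    if series.ligand != "ATP":
        raise ValueError("linear titration expects an ATP series")
    x, y = series.conc, series.kobs
    if np.unique(x).size < 3:
        raise ValueError("need at least three distinct concentrations")
    notes = []

    if through_origin:
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        resid = y - slope * x
        dof = max(x.size - 1, 1)
        slope_se = float(np.sqrt(resid @ resid / dof / sxx))
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        dof = max(x.size - 2, 1)
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope_se = float(np.sqrt(resid @ resid / dof / sxx))
    rss = float(resid @ resid)

    # free-intercept diagnostic
    diag_slope, diag_icept = np.polyfit(x, y, 1)

    # lack-of-fit: does the saturating hyperbola fit significantly better?
    if x.size >= 4 and rss > 0:
        try:
            popt, _ = optimize.curve_fit(
                lambda a, k2, kmax: kmax * a / (kmax / k2 + a),
                x, y, p0=[slope if through_origin else max(slope, 1e-6), 2.0 * y.max()],
                bounds=(0.0, np.inf), maxfev=20000,
            )
            resid_h = y - popt[1] * x / (popt[1] / popt[0] + x)
            rss_h = float(resid_h @ resid_h)
        except RuntimeError:
            rss_h = rss
        dof_h = x.size - 2
        if dof_h > 0 and rss_h < rss:
            f_stat = (rss - rss_h) / max(rss_h / dof_h, 1e-300)
            p_curv = float(stats.f.sf(f_stat, 1, dof_h))
            if p_curv < curvature_alpha:
                notes.append("curvature")
                warnings.warn(
                    f"significant curvature in the k_obs vs [ATP] plot (p = {p_curv:.3g}); "
                    "the grid extends beyond the linear regime",
                    CurvatureWarning, stacklevel=2,
                )
    return TitrationFit(
        model="linear",
        params={"K1k2_acto": slope},
        se={"K1k2_acto": slope_se},
        rss=rss, n_points=int(x.size), notes=tuple(notes),
        extras={"free_intercept": {"slope": float(diag_slope), "intercept": float(diag_icept)}},
    )


def fit_adp_competition(series: TitrationSeries) -> TitrationFit:
    """ADP affinity of acto-S1 from normalized competition data.

    Fits k_rel = k_obs/k0 = 1/(1 + [ADP]/K_AD), equivalent to the
    competition form of the observed-rate equation at fixed [ATP].
    """
    if series.ligand != "ADP":
        raise ValueError("competition fit expects an ADP series")
    if series.fixed_atp is None:
        raise ValueError("competition series must record its fixed [ATP]")
    k0 = series.k0
    if k0 is None:
        at_zero = series.kobs[series.conc == 0]
        if at_zero.size == 0:
            raise ValueError("need k0 or an [ADP] = 0 measurement")
        k0 = float(at_zero.mean())

    x = series.conc
    krel = series.kobs / k0

    def model(adp, kad):
        return 1.0 / (1.0 + adp / kad)

    positive = x[x > 0]
    p0 = [float(np.median(positive))] if positive.size else [1.0]
    popt, pcov = optimize.curve_fit(
        model, x, krel, p0=p0, bounds=(0.0, np.inf), maxfev=20000
    )
    kad = float(popt[0])
    kad_se = float(np.sqrt(max(pcov[0, 0], 0.0)))
    resid = krel - model(x, kad)
    rss = float(resid @ resid)
    notes = []
    if x.max() < kad / 2.0:
        notes.append("poorly_constrained")
        warnings.warn(
            f"max [ADP] = {x.max():.0f} μM is below K_AD/2 ≈ {kad/2:.0f} μM; "
            "the affinity is poorly constrained",
            PoorConditioningWarning, stacklevel=2,
        )
    return TitrationFit(
        model="competition",
        params={"K_AD": kad, "k0": float(k0)},
        se={"K_AD": kad_se},
        rss=rss, n_points=int(x.size), notes=tuple(notes),
        extras={"krel": krel, "adp": x},
    )


def fit_hyperbolic_titration(
    series: TitrationSeries,
    alpha: float = 0.01,
) -> TitrationFit:
    """Binding/hydrolysis hyperbola fit of k_obs vs [ATP].

    Parameterized directly in the quantities of interest,
    k_obs = kmax·[ATP]/(kmax/K1k+2 + [ATP]), so K0.5 = kmax/K1k+2 holds
    exactly for every fit.  Raises
    :class:`UnsaturatedTitrationError` when the data are statistically
    consistent with a straight line or the grid never approaches
    half-saturation; warns when the plateau itself is unsampled.
    """
    if series.ligand != "ATP":
        raise ValueError("hyperbolic titration expects an ATP series")
    x, y = series.conc, series.kobs
    if np.unique(x).size < 3:
        raise ValueError("need at least three distinct concentrations")

    def model(atp, k2, kmax):
        return kmax * atp / (kmax / k2 + atp)

    # initialize from the double-reciprocal line: 1/k = (1/k2)(1/[ATP]) + 1/kmax
    pos = (x > 0) & (y > 0)
    inv_slope, inv_icept = np.polyfit(1.0 / x[pos], 1.0 / y[pos], 1)
    k2_0 = 1.0 / inv_slope if inv_slope > 0 else float(np.max(y) / np.max(x))
    kmax_0 = 1.0 / inv_icept if inv_icept > 0 else float(2.0 * np.max(y))
    popt, pcov = optimize.curve_fit(
        model, x, y, p0=[k2_0, kmax_0], bounds=(0.0, np.inf), maxfev=20000
    )
    k2, kmax = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = y - model(x, k2, kmax)
    rss = float(resid @ resid)
    k05 = kmax / k2

    # straight-line comparison (zero intercept, 1 parameter)
    slope = float(x @ y) / float(x @ x)
    rss_line = float(np.sum((y - slope * x) ** 2))
    dof = x.size - 2
    line_ok = False
    if dof > 0:
        if rss == 0.0:
            # noiseless data: the line is adequate only if it interpolates too
            line_ok = rss_line <= 1e-12 * float(y @ y)
        else:
            f_stat = (rss_line - rss) / (rss / dof)
            line_ok = stats.f.sf(f_stat, 1, dof) >= alpha
    if line_ok or k05 > 2.0 * x.max():
        raise UnsaturatedTitrationError(
            f"titration over [ATP] ≤ {x.max():.0f} μM does not constrain the "
            f"plateau (fitted K0.5 = {k05:.0f} μM); extend the grid"
        )
    notes = []
    if x.max() < k05 * 2.0:
        notes.append("plateau_unsampled")
        warnings.warn(
            f"max [ATP] = {x.max():.0f} μM is below 2×K0.5 ≈ {2*k05:.0f} μM; "
            "kmax carries a wide interval",
            WideIntervalWarning, stacklevel=2,
        )
    # the half-maximum consistency check of the standard assignment
    half_check = {
        "K05": k05,
        "kobs_at_K05": model(k05, k2, kmax),
        "half_kmax": kmax / 2.0,
    }
    return TitrationFit(
        model="hyperbola",
        params={"K1k2_s1": k2, "k_hyd_sum": kmax, "K05": k05},
        se={
            "K1k2_s1": float(perr[0]),
            "k_hyd_sum": float(perr[1]),
            "K05": float(k05 * np.hypot(perr[0] / k2, perr[1] / kmax)),
        },
        rss=rss, n_points=int(x.size), notes=tuple(notes),
        extras={"half_maximum_check": half_check},
    )
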