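"""Enzyme-kinetics fitting and censored catalytic-efficiency statistics.

Initial-velocity data (substrate concentration in mM, velocity in M/s at a
known enzyme concentration in M) are fitted to the Michaelis-Menten model

    v = kcat * E0 * S / (KM + S)

or, when velocity declines at high substrate, the substrate-inhibition model

    v = kcat * E0 * S / (KM + S + S^2/Ki),

by nonlinear least squares.  Catalytic efficiency kcat/KM is reported in
M^-1 s^-1 (KM converted mM -> M), with values below a detection limit
(default 0.2 M^-1 s^-1) treated as left-censored.  Fold ratios, rank-based
censored medians and log-scale specificity summaries are derived from the
efficiencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .reporting import round_sigfigs

DETECTION_LIMIT = 0.2  # M^-1 s^-1: efficiencies below this are not determinable

__all__ = [
    "DETECTION_LIMIT",
    "Censored",
    "KineticDataset",
    "KineticConstants",
    "FoldResult",
    "fit_michaelis_menten",
    "fit_substrate_inhibition",
    "efficiency",
    "fold_ratio",
    "censored_median",
    "median_fold",
    "specificity_factor",
    "specificity_improvement",
]


@dataclass(frozen=True)
class Censored:
    """A left-censored efficiency: known only to lie below ``limit``."""

    limit: float = DETECTION_LIMIT


@dataclass(frozen=True)
class KineticDataset:
    """Initial-velocity curve for one enzyme/substrate pair."""

    substrate: str
    concentrations_mM: np.ndarray
    velocities_M_per_s: np.ndarray
    enzyme_conc_M: float

    def __post_init__(self) -> None:
        s = np.asarray(self.concentrations_mM, dtype=float)
        v = np.asarray(self.velocities_M_per_s, dtype=float)
        object.__setattr__(self, "concentrations_mM", s)
        object.__setattr__(self, "velocities_M_per_s", v)
        if s.shape != v.shape:
            raise ValueError("concentration and velocity arrays differ in length")
        if s.size < 5:
            raise ValueError(f"need at least 5 concentration points, got {s.size}")
        if (s <= 0).any():
            raise ValueError("substrate concentrations must be > 0")
        if self.enzyme_conc_M <= 0:
            raise ValueError("enzyme concentration must be > 0")


@dataclass(frozen=True)
class KineticConstants:
    """Fitted constants with standard errors and censoring-aware efficiency."""

    kcat: float
    kcat_se: float
    km_mM: float
    km_se: float
    efficiency_M_per_s: float
    efficiency_se: float
    censored: bool
    detection_limit: float = DETECTION_LIMIT
    ki_mM: float | None = None
    ki_se: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    @property
    def efficiency_2sf(self) -> float:
        return round_sigfigs(self.efficiency_M_per_s, 2)


def _mm_velocity(s_mM, kcat, km_mM, e0):
    return kcat * e0 * s_mM / (km_mM + s_mM)


def _si_velocity(s_mM, kcat, km_mM, ki_mM, e0):
    return kcat * e0 * s_mM / (km_mM + s_mM + s_mM**2 / ki_mM)


def _initial_guesses(data: KineticDataset) -> tuple[float, float]:
    vmax0 = float(data.velocities_M_per_s.max())
    kcat0 = max(vmax0 / data.enzyme_conc_M, 1e-12)
    half = vmax0 / 2.0
    above = data.concentrations_mM[data.velocities_M_per_s >= half]
    km0 = float(above[0]) if above.size else float(data.concentrations_mM[-1])
    return kcat0, max(km0, 1e-6)


def _package_constants(
    popt, pcov, data: KineticDataset, model: str, converged: bool
) -> KineticConstants:
    kcat, km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    cov_kk = float(pcov[0, 1]) if np.all(np.isfinite(pcov)) else 0.0
    eff, eff_se, censored = efficiency(kcat, km, float(perr[0]), float(perr[1]), cov_kk)
    if model == "substrate_inhibition":
        pred = _si_velocity(data.concentrations_mM, *popt, data.enzyme_conc_M)
    else:
        pred = _mm_velocity(data.concentrations_mM, *popt, data.enzyme_conc_M)
    resid = data.velocities_M_per_s - pred
    n = data.concentrations_mM.size
    sse = float(resid @ resid)
    k = len(popt)
    # least-squares AIC up to a constant, for nested-model comparison
    aic = n * math.log(max(sse, 1e-300) / n) + 2 * k
    return KineticConstants(
        kcat=kcat,
        kcat_se=float(perr[0]),
        km_mM=km,
        km_se=float(perr[1]),
        efficiency_M_per_s=eff,
        efficiency_se=eff_se,
        censored=censored,
        ki_mM=float(popt[2]) if len(popt) > 2 else None,
        ki_se=float(perr[2]) if len(popt) > 2 else None,
        diagnostics={
            "model": model,
            "converged": converged,
            "sse": sse,
            "aic": aic,
            "n_points": n,
        },
    )


def fit_michaelis_menten(data: KineticDataset, max_iter: int = 500) -> KineticConstants:
    """Least-squares Michaelis-Menten fit with covariance-based standard errors.

    Non-convergence is flagged in ``diagnostics['converged']`` (parameters
    are NaN), never returned silently.
    """
    kcat0, km0 = _initial_guesses(data)
    # fit the turnover rate v/E0 (s^-1 scale) so the optimizer's relative
    # termination criteria see well-conditioned residuals
    try:
        popt, pcov = curve_fit(
            lambda s, kcat, km: _mm_velocity(s, kcat, km, 1.0),
            data.concentrations_mM,
            data.velocities_M_per_s / data.enzyme_conc_M,
            p0=[kcat0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=max_iter * 10,
        )
        converged = True
    except RuntimeError:
        popt, pcov = np.array([np.nan, np.nan]), np.full((2, 2), np.nan)
        converged = False
    return _package_constants(popt, pcov, data, "michaelis_menten", converged)


def fit_substrate_inhibition(data: KineticDataset, max_iter: int = 500) -> KineticConstants:
    """Fit the substrate-inhibition model; reports AIC against the plain fit.

    ``diagnostics['delta_aic_vs_mm']`` is AIC(substrate inhibition) minus
    AIC(plain Michaelis-Menten); negative values favour inhibition.
    """
    kcat0, km0 = _initial_guesses(data)
    ki0 = float(data.concentrations_mM.max())
    try:
        popt, pcov = curve_fit(
            lambda s, kcat, km, ki: _si_velocity(s, kcat, km, ki, 1.0),
            data.concentrations_mM,
            data.velocities_M_per_s / data.enzyme_conc_M,
            p0=[kcat0, km0, ki0],
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=max_iter * 20,
        )
        converged = True
    except RuntimeError:
        popt, pcov = np.full(3, np.nan), np.full((3, 3), np.nan)
        converged = False
    result = _package_constants(popt, pcov, data, "substrate_inhibition", converged)
    mm = fit_michaelis_menten(data, max_iter=max_iter)
    result.diagnostics["delta_aic_vs_mm"] = result.diagnostics["aic"] - mm.diagnostics["aic"]
    return result


def efficiency(
    kcat: float,
    km_mM: float,
    kcat_se: float = 0.0,
    km_se: float = 0.0,
    cov_kcat_km: float = 0.0,
    detection_limit: float = DETECTION_LIMIT,
) -> tuple[float, float, bool]:
    """Catalytic efficiency kcat/KM in M^-1 s^-1 with delta-method error.

    Returns ``(value, standard_error, censored)``; the censored flag is set
    when the value falls below the detection limit.
    """
    km_M = km_mM * 1e-3
    value = kcat / km_M
    # first-order propagation including the kcat-KM covariance
    if value != 0 and math.isfinite(value):
        rel_var = (
            (kcat_se / kcat) ** 2 if kcat else 0.0
        ) + ((km_se / km_mM) ** 2 if km_mM else 0.0)
        if kcat and km_mM:
            rel_var -= 2.0 * cov_kcat_km / (kcat * km_mM)
        se = abs(value) * math.sqrt(max(rel_var, 0.0))
    else:
        se = float("nan")
    return value, se, value < detection_limit


@dataclass(frozen=True)
class FoldResult:
    """A fold ratio; ``lower_bound`` marks censored-denominator bounds."""

    value: float
    lower_bound: bool = False

    @property
    def value_2sf(self) -> float:
        return round_sigfigs(self.value, 2)


def fold_ratio(
    eff_a: float | Censored,
    eff_b: float | Censored,
    detection_limit: float = DETECTION_LIMIT,
) -> FoldResult:
    """Ratio of two efficiencies; censored denominators give a lower bound."""
    if isinstance(eff_a, Censored):
        raise ValueError("numerator efficiency is censored; fold undefined")
    if isinstance(eff_b, Censored):
        return FoldResult(value=eff_a / eff_b.limit, lower_bound=True)
    if eff_b <= 0:
        raise ValueError("denominator efficiency must be > 0")
    return FoldResult(value=eff_a / eff_b)


def _rank_key(x: float | Censored) -> tuple[int, float]:
    # censored entries sort strictly below every detected value
    if isinstance(x, Censored):
        return (0, x.limit)
    return (1, float(x))


def censored_median(values: Sequence[float | Censored]) -> float | Censored:
    """Rank-based median where censored entries rank below all detected ones.

    Censored values act only through their ordering: replacing a censored
    entry's placeholder magnitude changes nothing.  With an even count the
    two central values are averaged; if either is censored the median itself
    is censored.
    """
    if not values:
        raise ValueError("cannot take the median of an empty set")
    ranked = sorted(values, key=_rank_key)
    n = len(ranked)
    if n % 2 == 1:
        return ranked[n // 2]
    lo, hi = ranked[n // 2 - 1], ranked[n // 2]
    if isinstance(lo, Censored):  # censored entries sort first, so lo censors first
        return lo
    if isinstance(hi, Censored):
        return hi
    return (lo + hi) / 2.0


def median_fold(
    set_a: Sequence[float | Censored],
    set_b: Sequence[float | Censored],
    censor_limit: float = DETECTION_LIMIT,
) -> FoldResult:
    """Ratio of censored medians: median(set_a) / median(set_b).

    A censored denominator median yields a lower bound computed at the
    censoring limit.
    """
    med_a = censored_median(set_a)
    med_b = censored_median(set_b)
    if isinstance(med_a, Censored):
        raise ValueError("median of the numerator set is censored; fold undefined")
    if isinstance(med_b, Censored):
        return FoldResult(value=med_a / censor_limit, lower_bound=True)
    return FoldResult(value=med_a / med_b)


def specificity_factor(
    eff_c8: float | Censored,
    eff_c5: float | Censored,
    eff_c3: float | Censored,
) -> tuple[float, float, float, bool]:
    """Log-scale specificity summary of C8 efficiency against C5 and C3.

    SF = 1/2 [log10(eff_C8/eff_C5) + log10(eff_C8/eff_C3)].  Returns
    ``(sf, log10_c8_over_c5, log10_c8_over_c3, is_bound)``; censored inputs
    are evaluated at their censoring limit and flagged as a bound.
    """
    is_bound = any(isinstance(e, Censored) for e in (eff_c8, eff_c5, eff_c3))
    c8, c5, c3 = (
        e.limit if isinstance(e, Censored) else float(e) for e in (eff_c8, eff_c5, eff_c3)
    )
    if min(c8, c5, c3) <= 0:
        raise ValueError("efficiencies must be > 0")
    l85 = math.log10(c8 / c5)
    l83 = math.log10(c8 / c3)
    return 0.5 * (l85 + l83), l85, l83, is_bound


def specificity_improvement(
    enzyme_eff_num: float,
    enzyme_eff_den: float,
    reference_eff_num: float,
    reference_eff_den: float,
) -> float:
    """Fold improvement in substrate preference relative to a reference.

    [eff_enzyme(num)/eff_enzyme(den)] / [eff_ref(num)/eff_ref(den)].
    """
    for name, v in (
        ("enzyme_eff_num", enzyme_eff_num),
        ("enzyme_eff_den", enzyme_eff_den),
        ("reference_eff_num", reference_eff_num),
        ("reference_eff_den", reference_eff_den),
    ):
        if isinstance(v, Censored) or v <= 0:
            raise ValueError(f"{name} must be an uncensored positive efficiency")
    return (enzyme_eff_num / enzyme_eff_den) / (reference_eff_num / reference_eff_den)
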