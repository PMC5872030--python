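"""Flocculation/sedimentation efficiency, dose selection and flotation kinetics.

Jar tests give sedimentation efficiency (percentage of Chlorophyll a removed
by settling) as a function of flocculant dose. From the measured dose grid
two operating points are selected: SE_max, the cheapest dose that reaches the
curve maximum, and SE_sub-max, a reduced dose near a target efficiency that
trades removal for lower flocculant cost and a gentler ecological footprint.

Time-resolved flotation harvesting is summarised with the standard
first-order rate model E(t) = E_inf * (1 - exp(-k t)); the data are sampled
points, so the curve form is this package's modelling choice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponsePoint",
    "DoseResponseCurve",
    "DoseSelection",
    "FlotationSeries",
    "KineticsFit",
    "removal_efficiency",
    "build_dose_response",
    "select_doses",
    "fit_flotation_kinetics",
    "paired_mean_test",
]

#: percentage points of overshoot tolerated before removal_efficiency errors
DEFAULT_OVERSHOOT_TOL_PP = 0.5
#: efficiencies within this many percentage points of the maximum tie for SE_max
SE_MAX_TIE_TOL_PP = 1.0


@dataclass(frozen=True)
class DoseResponsePoint:
    dose_mg_per_l: float
    efficiency_pct: float
    replicate_sd_pct: float | None = None

    def __post_init__(self) -> None:
        if self.dose_mg_per_l < 0:
            raise ValueError(f"negative dose: {self.dose_mg_per_l}")
        if not 0.0 <= self.efficiency_pct <= 100.0:
            raise ValueError(f"efficiency {self.efficiency_pct} outside [0, 100]")


@dataclass(frozen=True)
class DoseSelection:
    se_max_dose: float
    se_max_efficiency: float
    se_submax_dose: float
    se_submax_efficiency: float

    def __post_init__(self) -> None:
        if self.se_submax_efficiency > self.se_max_efficiency:
            raise ValueError("sub-max efficiency exceeds max efficiency")


@dataclass(frozen=True)
class FlotationSeries:
    """Time (min since bubble introduction) vs harvesting efficiency (%)."""

    time_min: tuple[float, ...]
    efficiency_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        e = np.asarray(self.efficiency_pct, dtype=float)
        if t.size != e.size:
            raise ValueError("time and efficiency lengths differ")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")
        if e.size and (np.any(e < 0) or np.any(e > 100)):
            raise ValueError("efficiencies must lie in [0, 100]")


@dataclass(frozen=True)
class KineticsFit:
    """First-order flotation fit: E(t) = e_inf * (1 - exp(-k t))."""

    e_inf: float
    k: float
    rss: float

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.e_inf * (1.0 - np.exp(-self.k * t))


def removal_efficiency(
    c0: float, ct: float, overshoot_tol_pp: float = DEFAULT_OVERSHOOT_TOL_PP
) -> float:
    """Percentage removal 100*(1 - ct/c0) of a concentration proxy.

    Measurement noise can push ct marginally above c0; an apparent negative
    removal within `overshoot_tol_pp` percentage points is clamped to 0,
    anything larger is an error.
    """
    if c0 <= 0:
        raise ValueError(f"initial concentration must be positive, got {c0}")
    if ct < 0:
        raise ValueError(f"final concentration must be non-negative, got {ct}")
    eff = 100.0 * (1.0 - ct / c0)
    if eff < 0.0:
        if eff < -overshoot_tol_pp:
            raise ValueError(
                f"final concentration {ct} exceeds initial {c0} beyond the "
                f"{overshoot_tol_pp} pp noise tolerance"
            )
        return 0.0
    return min(eff, 100.0)


class DoseResponseCurve:
    """Piecewise-linear dose-response over the measured dose grid.

    No smoothing or extrapolation: jar-test grids are coarse and a monotone
    shape is not guaranteed, so evaluation is linear interpolation strictly
    within the measured range.
    """

    def __init__(self, points: Sequence[DoseResponsePoint]):
        by_dose: dict[float, DoseResponsePoint] = {}
        for p in points:
            prev = by_dose.get(p.dose_mg_per_l)
            if prev is not None and prev.efficiency_pct != p.efficiency_pct:
                raise ValueError(
                    f"duplicate dose {p.dose_mg_per_l} mg/L with conflicting "
                    f"efficiencies {prev.efficiency_pct}% and {p.efficiency_pct}%"
                )
            by_dose[p.dose_mg_per_l] = p
        if len(by_dose) < 2:
            raise ValueError("a dose-response curve needs >= 2 distinct doses")
        self.points: tuple[DoseResponsePoint, ...] = tuple(
            sorted(by_dose.values(), key=lambda p: p.dose_mg_per_l)
        )
        self._doses = np.array([p.dose_mg_per_l for p in self.points])
        self._effs = np.array([p.efficiency_pct for p in self.points])

    @property
    def dose_range(self) -> tuple[float, float]:
        return float(self._doses[0]), float(self._doses[-1])

    def __call__(self, dose: float) -> float:
        lo, hi = self.dose_range
        if not lo <= dose <= hi:
            raise ValueError(
                f"dose {dose} mg/L outside measured range [{lo}, {hi}]; "
                "extrapolation is not supported"
            )
        return float(np.interp(dose, self._doses, self._effs))

    def max_efficiency(self) -> float:
        return float(self._effs.max())


def build_dose_response(points: Sequence[DoseResponsePoint]) -> DoseResponseCurve:
    return DoseResponseCurve(points)


def select_doses(
    curve: DoseResponseCurve,
    submax_target_pct: float,
    tie_tol_pp: float = SE_MAX_TIE_TOL_PP,
) -> DoseSelection:
    """Pick the SE_max and SE_sub-max operating doses from measured points.

    SE_max is the smallest measured dose whose efficiency is within
    `tie_tol_pp` percentage points of the curve maximum (replicate scatter in
    jar tests is of that order, so near-ties go to the cheaper dose).
    SE_sub-max is the measured dose whose efficiency is nearest the target,
    with ties broken toward the lower dose.
    """
    effs = np.array([p.efficiency_pct for p in curve.points])
    if not effs.min() <= submax_target_pct <= effs.max():
        raise ValueError(
            f"sub-max target {submax_target_pct}% outside achievable range "
            f"[{effs.min()}, {effs.max()}]%"
        )
    e_max = effs.max()
    max_point = next(
        p for p in curve.points if p.efficiency_pct >= e_max - tie_tol_pp
    )
    submax_point = min(
        curve.points,
        key=lambda p: (abs(p.efficiency_pct - submax_target_pct), p.dose_mg_per_l),
    )
    return DoseSelection(
        se_max_dose=max_point.dose_mg_per_l,
        se_max_efficiency=max_point.efficiency_pct,
        se_submax_dose=submax_point.dose_mg_per_l,
        se_submax_efficiency=submax_point.efficiency_pct,
    )


def _first_order(t, e_inf, k):
    return e_inf * (1.0 - np.exp(-k * t))


def fit_flotation_kinetics(
    series: FlotationSeries, noise_tol_pp: float = 2.0
) -> KineticsFit:
    """Least-squares fit of the first-order flotation model to a time series.

    With exactly two points the unique interpolating (e_inf, k) is found by a
    1-D root search on k; with more points scipy least squares is used. A
    decrease in measured efficiency larger than `noise_tol_pp` between
    consecutive samples draws a warning but the fit proceeds.
    """
    t = np.asarray(series.time_min, dtype=float)
    e = np.asarray(series.efficiency_pct, dtype=float)
    if t.size < 2:
        raise ValueError("kinetics fit needs >= 2 time points")
    if np.any(np.diff(e) < -noise_tol_pp):
        warnings.warn(
            "flotation efficiencies decrease beyond noise tolerance; "
            "fitting a monotone model anyway",
            stacklevel=2,
        )
    if np.allclose(e, 0.0):
        return KineticsFit(e_inf=0.0, k=0.0, rss=float(np.sum(e**2)))

    if t.size == 2 and t[0] > 0 and e[0] > 0 and e[1] > 0 and e[0] < e[1]:
        # ratio r(k) = (1-exp(-k t0))/(1-exp(-k t1)) rises from t0/t1 to 1
        target = e[0] / e[1]
        if t[0] / t[1] < target < 1.0:
            def g(k):
                return -np.expm1(-k * t[0]) / -np.expm1(-k * t[1]) - target

            k = optimize.brentq(g, 1e-12, 1e3, xtol=1e-14, rtol=1e-15)
            e_inf = e[0] / -np.expm1(-k * t[0])
            resid = e - _first_order(t, e_inf, k)
            return KineticsFit(e_inf=float(e_inf), k=float(k),
                               rss=float(np.sum(resid**2)))

    p0 = (max(e.max(), 1e-6), 1.0)
    popt, _ = optimize.curve_fit(
        _first_order, t, e, p0=p0, bounds=([0.0, 0.0], [100.0, np.inf]),
        maxfev=20000,
    )
    resid = e - _first_order(t, *popt)
    return KineticsFit(e_inf=float(popt[0]), k=float(popt[1]),
                       rss=float(np.sum(resid**2)))


def paired_mean_test(
    before: Sequence[float], after: Sequence[float]
) -> dict[str, float]:
    """Classical paired t-test on matched efficiency measurements.

    Returns {"t", "df", "p_two_sided"}. When every paired difference is zero
    the test is degenerate and p = 1.0 by convention (no evidence of change).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError(f"length mismatch: {b.size} vs {a.size}")
    n = b.size
    if n < 2:
        raise ValueError("paired test needs n >= 2 pairs")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return {"t": 0.0, "df": float(df), "p_two_sided": 1.0}
        return {"t": math.copysign(math.inf, d.mean()), "df": float(df),
                "p_two_sided": 0.0}
    t_stat = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    return {"t": float(t_stat), "df": float(df), "p_two_sided": float(p)}
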