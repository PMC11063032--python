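"""Thermal-time, hydrotime and hydrothermal-time threshold models.

The population-based threshold framework treats germination timing as the
accumulation of driving force above a threshold:

* thermal time (sub-optimal):      theta_T1 = (T - Tb) * tg
* thermal time (supra-optimal):    theta_T2 = (Tc - T) * tg
* hydrotime:                       theta_H  = (psi - psi_b) * tg
* hydrothermal time:               theta_HTT = (psi - psi_b) * (T - Tb) * tg

with tg the time for seed fraction g to germinate.  The base water potential
psi_b(g) is assumed normally distributed over the seed population with median
psi_b(50) and spread sigma_psib, which makes the cumulative germination
fraction at time t

    g(t) = Phi( (psi_eff - theta_HTT / ((T - Tb) t) - psi_b(50)) / sigma_psib )

where Phi is the standard normal CDF and, above the optimum temperature To,
the effective water potential is shifted by psi_eff = psi - kT * (T - To)
(fixed theta_HTT, threshold drift convention).  Probit-transforming observed
fractions linearises this relation, so parameters are estimated by repeated
probit regression: scan the accumulation constant, regress probit(g) on the
threshold coordinate, keep the value maximising R^2.

Internal units are hours and degrees Celsius (hydrotime in MPa.h, thermal
time in degC.h, hydrothermal time in MPa.degC.h); day-based inputs are
converted at the boundary (24 h/day).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from .timecourse import (
    HOURS_PER_DAY,
    FitFailureError,
    GerminationTimeCourse,
    UndefinedIndexError,
)

__all__ = [
    "ThermalParams",
    "HydroParams",
    "HTTParams",
    "FitDiagnostics",
    "tt_sub",
    "tt_supra",
    "gr_thermal",
    "hydrotime_theta",
    "gr_hydro",
    "theta_htt",
    "effective_psi",
    "predict_time_course",
    "interpolate_tg",
    "fit_thermal",
    "fit_hydrotime_probit",
    "fit_htt",
    "table1_grid",
    "table1_from_tg",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalParams:
    """Cardinal temperatures and thermal constants from GR-vs-T regression."""

    Tb: float                     # degC, base
    thetaT1: float                # degC.h, sub-optimal thermal constant
    To: float | None = None       # degC, optimum (branch intersection)
    Tc: float | None = None       # degC, ceiling (supra x-intercept)
    thetaT2: float | None = None  # degC.h, supra-optimal thermal constant


@dataclass(frozen=True)
class HydroParams:
    """Hydrotime parameters at one temperature."""

    thetaH: float       # MPa.h
    psib50: float       # MPa, median base water potential
    sigma_psib: float   # MPa

    def __post_init__(self) -> None:
        if self.thetaH <= 0 or self.sigma_psib <= 0:
            raise ValueError("thetaH and sigma_psib must be positive")


@dataclass(frozen=True)
class HTTParams:
    """Joint hydrothermal-time parameters across the full (T, psi) grid."""

    thetaHTT: float     # MPa.degC.h
    Tb: float           # degC
    psib50: float       # MPa
    sigma_psib: float   # MPa
    kT: float = 0.0     # MPa/degC, psi_b(50) drift above To
    To: float | None = None  # degC

    def __post_init__(self) -> None:
        if self.thetaHTT <= 0 or self.sigma_psib <= 0:
            raise ValueError("thetaHTT and sigma_psib must be positive")
        if self.kT < 0:
            raise ValueError("kT must be >= 0")

    @property
    def thetaH_at_To(self) -> float:
        """Hydrotime constant at the optimum, theta_HTT / (To - Tb), MPa.h."""
        if self.To is None:
            raise ValueError("To is not set")
        return self.thetaHTT / (self.To - self.Tb)


@dataclass
class FitDiagnostics:
    r_squared: float
    n_obs: int
    F_statistic: float | None = None
    standard_error: float | None = None
    p_value: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared must lie in [0, 1]")


# ---------------------------------------------------------------------------
# forward relations
# ---------------------------------------------------------------------------

def tt_sub(T: float, Tb: float, tg: float) -> float:
    """Sub-optimal thermal time (T - Tb) * tg, degC.h."""
    if T <= Tb:
        raise ValueError(f"T={T} must exceed Tb={Tb} for sub-optimal thermal time")
    if tg <= 0:
        raise ValueError("tg must be positive")
    return (T - Tb) * tg


def tt_supra(T: float, Tc: float, tg: float) -> float:
    """Supra-optimal thermal time (Tc - T) * tg, degC.h."""
    if T >= Tc:
        raise ValueError(f"T={T} must be below Tc={Tc} for supra-optimal thermal time")
    if tg <= 0:
        raise ValueError("tg must be positive")
    return (Tc - T) * tg


def gr_thermal(T: float, Tb: float, thetaT1: float) -> float:
    """Germination rate GR = (T - Tb) / thetaT1, 1/h; zero at T = Tb."""
    if thetaT1 <= 0:
        raise ValueError("thetaT1 must be positive")
    return max(0.0, T - Tb) / thetaT1


def hydrotime_theta(psi: float, psib: float, tg: float) -> float:
    """Hydrotime (psi - psib) * tg, MPa.h; requires psi above the threshold."""
    if psi <= psib:
        raise ValueError(
            f"psi={psi} must exceed psib={psib}: that seed fraction never germinates"
        )
    if tg <= 0:
        raise ValueError("tg must be positive")
    return (psi - psib) * tg


def gr_hydro(psi: float, psib: float, thetaH: float) -> float:
    """Germination rate GR = max(0, psi - psib) / thetaH, 1/h."""
    if thetaH <= 0:
        raise ValueError("thetaH must be positive")
    return max(0.0, psi - psib) / thetaH


def theta_htt(psi: float, psib: float, T: float, Tb: float, tg: float) -> float:
    """Hydrothermal time (psi - psib) * (T - Tb) * tg, MPa.degC.h."""
    if psi <= psib:
        raise ValueError("psi must exceed psib")
    if T <= Tb:
        raise ValueError("T must exceed Tb")
    if tg <= 0:
        raise ValueError("tg must be positive")
    return (psi - psib) * (T - Tb) * tg


def effective_psi(psi: float, T: float, kT: float, To: float | None) -> float:
    """Water potential corrected for supra-optimal threshold drift."""
    if To is None or kT == 0:
        return psi
    return psi - kT * max(0.0, T - To)


def predict_time_course(
    params: HTTParams, T: float, psi: float, times_h: Sequence[float]
) -> np.ndarray:
    """Cumulative germinated fraction at each time under the HTT model.

    ``g(t) = Phi((psi_eff - thetaHTT/((T - Tb) t) - psib50) / sigma_psib)``,
    non-decreasing in t with asymptote ``Phi((psi_eff - psib50)/sigma_psib)``.
    Temperatures at or below the base give an all-zero prediction.
    """
    t = np.asarray(times_h, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if T <= params.Tb:
        warnings.warn(f"T={T} <= Tb={params.Tb}: no thermal driving force", stacklevel=2)
        return np.zeros_like(t)
    psi_eff = effective_psi(psi, T, params.kT, params.To)
    psib_g = psi_eff - params.thetaHTT / ((T - params.Tb) * t)
    return norm.cdf((psib_g - params.psib50) / params.sigma_psib)


def interpolate_tg(tc: GerminationTimeCourse, g: float) -> float:
    """Time (hours) at which the cumulative fraction first reaches ``g``.

    Linear interpolation between the bracketing observations; raises
    :class:`UndefinedIndexError` when the fraction is never reached.
    """
    if not 0 < g <= 1:
        raise ValueError("g must lie in (0, 1]")
    frac = tc.fractions
    t_h = tc.times_h
    if frac[-1] < g:
        raise UndefinedIndexError(
            "fraction_not_reached", f"cumulative fraction never reaches {g}"
        )
    j = int(np.argmax(frac >= g))
    if frac[j] == g or j == 0:
        return float(t_h[j])
    i = j - 1
    return float(t_h[i] + (g - frac[i]) * (t_h[j] - t_h[i]) / (frac[j] - frac[i]))


# ---------------------------------------------------------------------------
# probit machinery
# ---------------------------------------------------------------------------

def _probit_observations(
    curves: Iterable[GerminationTimeCourse], boundary: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten curves to (T, psi, t_h, fraction) rows usable in probit space.

    boundary="exclude" drops fractions of exactly 0 or 1; boundary="adjust"
    replaces them with 0.5/(2n) and 1 - 0.5/(2n).
    """
    T, psi, t, g = [], [], [], []
    for tc in curves:
        frac = tc.fractions.copy()
        keep = np.ones(len(frac), dtype=bool)
        if boundary == "exclude":
            keep = (frac > 0) & (frac < 1)
        elif boundary == "adjust":
            eps = 0.5 / (2 * tc.n_seeds)
            frac = np.clip(frac, eps, 1 - eps)
        else:
            raise ValueError("boundary must be 'exclude' or 'adjust'")
        T.extend([tc.temperature] * int(keep.sum()))
        psi.extend([tc.water_potential] * int(keep.sum()))
        t.extend(tc.times_h[keep])
        g.extend(frac[keep])
    return (np.asarray(T), np.asarray(psi), np.asarray(t), np.asarray(g))


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, sse) by least squares — fast path for scan loops."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _ols_diagnostics(x: np.ndarray, y: np.ndarray) -> tuple[float, float, FitDiagnostics]:
    """Full OLS of y on x with the usual regression diagnostics."""
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    intercept = float(res.params[0])
    diag = FitDiagnostics(
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
        F_statistic=float(res.fvalue),
        standard_error=float(np.sqrt(res.mse_resid)),
        p_value=float(res.f_pvalue),
    )
    return slope, intercept, diag


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _gr_percentile(
    curves: Sequence[GerminationTimeCourse], g: float
) -> float:
    """Pooled germination rate (1/h) for fraction g; 0 if g is never reached.

    Replicate dishes are pooled by summing counts at matched observation
    times before interpolating.  A fraction that is never reached within the
    observation window germinates at rate zero under the threshold model.
    """
    times = curves[0].times
    counts = np.zeros(len(times))
    n = 0
    for tc in curves:
        if tc.times != times:
            raise FitFailureError("replicate dishes must share observation times")
        counts += tc.counts
        n += tc.n_seeds
    pooled = GerminationTimeCourse(
        temperature=curves[0].temperature,
        water_potential=curves[0].water_potential,
        times=times,
        cumulative_counts=np.round(counts).astype(int),
        n_seeds=n,
        replicate_id="pooled",
    )
    try:
        return 1.0 / interpolate_tg(pooled, g)
    except UndefinedIndexError:
        return 0.0


def fit_thermal(
    curves: Sequence[GerminationTimeCourse], g: float = 0.5
) -> tuple[ThermalParams, FitDiagnostics]:
    """Cardinal temperatures from GR(g)-vs-T regression at a single psi.

    Sub-optimal branch: GR rises linearly with T; its x-intercept is the
    base temperature Tb and the reciprocal slope the thermal constant
    thetaT1.  Supra-optimal branch (when >= 2 temperatures at/above the
    optimum are available): GR falls linearly; its x-intercept is the
    ceiling Tc, -1/slope the constant thetaT2, and the branch intersection
    the optimum To.
    """
    by_T: dict[float, list[GerminationTimeCourse]] = {}
    for tc in curves:
        by_T.setdefault(tc.temperature, []).append(tc)
    if len(by_T) < 2:
        raise FitFailureError("thermal fit needs >= 2 temperatures")
    temps = np.array(sorted(by_T))
    gr = np.array([_gr_percentile(by_T[T], g) for T in temps])
    i_opt = int(np.argmax(gr))
    To_obs = temps[i_opt]

    sub_T, sub_gr = temps[: i_opt + 1], gr[: i_opt + 1]
    if len(sub_T) < 2:
        raise FitFailureError("thermal fit needs >= 2 sub-optimal temperatures")
    a, b, _ = _line_fit(sub_T, sub_gr)
    if a <= 0:
        raise FitFailureError("sub-optimal GR-vs-T slope is not positive")
    Tb = -b / a
    thetaT1 = 1.0 / a
    _, _, diag_sub = _ols_diagnostics(sub_T, sub_gr)

    To = Tc = thetaT2 = None
    diag_extra = {"To_observed": float(To_obs), "r_squared_sub": diag_sub.r_squared}
    supra_T, supra_gr = temps[i_opt:], gr[i_opt:]
    if len(supra_T) >= 2:
        c, d, _ = _line_fit(supra_T, supra_gr)
        if c < 0:
            Tc = -d / c
            thetaT2 = -1.0 / c
            To = (d - b) / (a - c)
            _, _, diag_supra = _ols_diagnostics(supra_T, supra_gr)
            diag_extra["r_squared_supra"] = diag_supra.r_squared
        else:
            warnings.warn("supra-optimal branch slope not negative; Tc not estimated",
                          stacklevel=2)
    else:
        warnings.warn("single temperature at/above optimum; supra branch skipped",
                      stacklevel=2)

    params = ThermalParams(Tb=Tb, thetaT1=thetaT1, To=To, Tc=Tc, thetaT2=thetaT2)
    diag = FitDiagnostics(
        r_squared=diag_sub.r_squared,
        n_obs=len(temps),
        F_statistic=diag_sub.F_statistic,
        standard_error=diag_sub.standard_error,
        p_value=diag_sub.p_value,
        extra=diag_extra,
    )
    return params, diag


def _hydrotime_r2(thetaH: float, psi: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    x = psi - thetaH / t
    _, _, sse = _line_fit(x, y)
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else 0.0


def _theta_h_initial_guess(curves: Sequence[GerminationTimeCourse]) -> float:
    """Moment-based start: reciprocal slope of GR(50) vs psi where available."""
    pts = []
    for tc in curves:
        try:
            pts.append((tc.water_potential, 1.0 / interpolate_tg(tc, 0.5)))
        except UndefinedIndexError:
            continue
    psis = sorted({p for p, _ in pts})
    if len(psis) >= 2:
        x = np.array([p for p, _ in pts])
        yy = np.array([r for _, r in pts])
        slope, _, _ = _line_fit(x, yy)
        if slope > 0:
            return 1.0 / slope
    # fallback: typical suprathreshold potential x typical germination time
    t_med = float(np.median([np.median(tc.times_h) for tc in curves]))
    return max(t_med, 1.0)


def fit_hydrotime_probit(
    curves: Sequence[GerminationTimeCourse],
    boundary: str = "exclude",
    n_grid: int = 500,
    grid_span: tuple[float, float] = (0.1, 10.0),
) -> tuple[HydroParams, FitDiagnostics]:
    """Hydrotime parameters at one temperature by repeated probit regression.

    For each candidate thetaH on a log grid around a moment-based initial
    guess, probit(g) is regressed on x = psi - thetaH/t over all (psi, t)
    observations with 0 < g < 1; the thetaH maximising R^2 wins (ties broken
    toward the smaller value), then a bounded golden-section pass refines it.
    The probit line yields psib50 (x at probit 0) and sigma_psib (reciprocal
    slope).
    """
    temps = {tc.temperature for tc in curves}
    if len(temps) != 1:
        raise FitFailureError("hydrotime fit expects curves at a single temperature")
    if len({tc.water_potential for tc in curves}) < 3:
        raise FitFailureError("hydrotime fit needs >= 3 water potentials")
    _, psi, t, gfrac = _probit_observations(curves, boundary)
    if len(gfrac) < 2:
        raise FitFailureError("no probit-transformable data (all fractions 0 or 1)")
    y = norm.ppf(gfrac)

    theta0 = _theta_h_initial_guess(curves)
    grid = np.geomspace(grid_span[0] * theta0, grid_span[1] * theta0, n_grid)
    r2 = np.array([_hydrotime_r2(th, psi, t, y) for th in grid])
    i = int(np.argmax(r2))  # first max -> smaller thetaH on ties
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda th: -_hydrotime_r2(th, psi, t, y),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10 * theta0},
        )
        best = float(res.x) if -res.fun >= r2[i] else float(grid[i])
    else:
        best = float(grid[i])

    x = psi - best / t
    slope, intercept, _ = _line_fit(x, y)
    if slope <= 1e-12:
        raise FitFailureError(
            "probit slope not positive: no water-potential signal (sigma -> inf)"
        )
    slope, intercept, diag = _ols_diagnostics(x, y)
    params = HydroParams(thetaH=best, psib50=-intercept / slope, sigma_psib=1.0 / slope)
    diag.extra = {"temperature": float(temps.pop()), "theta_grid_step": float(
        grid[1] / grid[0])}
    return params, diag


def _htt_design(
    T: np.ndarray, psi: np.ndarray, t: np.ndarray,
    thetaHTT: float, Tb: float, kT: float, To: float,
) -> np.ndarray | None:
    if thetaHTT <= 0 or kT < 0 or Tb >= T.min():
        return None
    psi_eff = psi - kT * np.maximum(0.0, T - To)
    return psi_eff - thetaHTT / ((T - Tb) * t)


def fit_htt(
    curves: Sequence[GerminationTimeCourse],
    To: float | None = None,
    boundary: str = "exclude",
) -> tuple[HTTParams, FitDiagnostics]:
    """Joint hydrothermal-time fit across the full (T, psi) grid.

    Optimises (thetaHTT, Tb, kT) by a coarse grid scan followed by
    Nelder-Mead polish, minimising the residual sum of squares of the probit
    regression of g on psi_eff - thetaHTT/((T - Tb) t); the probit line gives
    psib50 and sigma_psib, and R^2 is reported over all retained
    observations.  The optimum To is taken as the temperature with the
    highest pooled GR(50) unless supplied; with no data above To, kT is fixed
    at 0 with a warning.
    """
    by_T: dict[float, list[GerminationTimeCourse]] = {}
    for tc in curves:
        by_T.setdefault(tc.temperature, []).append(tc)
    if len(by_T) < 2:
        raise FitFailureError("HTT fit needs >= 2 temperatures")
    if len({tc.water_potential for tc in curves}) < 3:
        raise FitFailureError("HTT fit needs >= 3 water potentials")

    if To is None:
        best_rate, To = -1.0, max(by_T)
        for T_val, group in by_T.items():
            psi_max = max(tc.water_potential for tc in group)
            sub = [tc for tc in group if tc.water_potential == psi_max]
            rate = _gr_percentile(sub, 0.5)
            if rate > best_rate:
                best_rate, To = rate, T_val
    To = float(To)

    T, psi, t, gfrac = _probit_observations(curves, boundary)
    if len(gfrac) < 3:
        raise FitFailureError("no probit-transformable data (all fractions 0 or 1)")
    y = norm.ppf(gfrac)
    sst = float(((y - y.mean()) ** 2).sum())

    fit_kT = any(T_val > To for T_val in by_T)
    if not fit_kT:
        warnings.warn("no supra-optimal temperatures: kT fixed at 0", stacklevel=2)

    def sse(thetaHTT: float, Tb: float, kT: float) -> float:
        x = _htt_design(T, psi, t, thetaHTT, Tb, kT, To)
        if x is None:
            return np.inf
        _, _, s = _line_fit(x, y)
        return s

    # coarse scan
    t_typ = float(np.median(t))
    theta_grid = np.geomspace(0.05 * t_typ, 50.0 * t_typ, 25)
    Tb_grid = np.linspace(0.0, T.min() - 2.0, 9)
    kT_grid = np.linspace(0.0, 0.3, 7) if fit_kT else np.array([0.0])
    best = (np.inf, theta_grid[0], Tb_grid[0], 0.0)
    for th in theta_grid:
        for tb in Tb_grid:
            for k in kT_grid:
                s = sse(th, tb, k)
                if s < best[0]:
                    best = (s, th, tb, k)
    _, th0, tb0, k0 = best

    # Nelder-Mead polish (log-thetaHTT for scale)
    if fit_kT:
        def obj(v):
            return sse(np.exp(v[0]), v[1], v[2])
        x0 = [np.log(th0), tb0, k0]
    else:
        def obj(v):
            return sse(np.exp(v[0]), v[1], 0.0)
        x0 = [np.log(th0), tb0]
    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 5000,
                            "maxfev": 8000})
    thetaHTT = float(np.exp(res.x[0]))
    Tb = float(res.x[1])
    kT = float(res.x[2]) if fit_kT else 0.0
    kT = max(kT, 0.0)

    if Tb >= T.min() - 1e-9:
        raise FitFailureError("base temperature hit the data boundary (Tb >= min T)")

    x = _htt_design(T, psi, t, thetaHTT, Tb, kT, To)
    slope, intercept, _ = _line_fit(x, y)
    if slope <= 1e-12:
        raise FitFailureError("probit slope not positive in HTT fit")
    slope, intercept, diag = _ols_diagnostics(x, y)
    params = HTTParams(
        thetaHTT=thetaHTT, Tb=Tb, psib50=-intercept / slope,
        sigma_psib=1.0 / slope, kT=kT, To=To,
    )
    diag.extra = {"sse": float(res.fun), "sst": sst, "kT_estimated": fit_kT}
    return params, diag


# ---------------------------------------------------------------------------
# per-treatment constant grid
# ---------------------------------------------------------------------------

_GRID_COLUMNS = [
    "temperature_C", "psi_MPa", "tg_h", "TTsub_Ch", "TTsupra_Ch",
    "thetaH_MPah", "thetaHTT_MPaCh", "GR_per_h",
]


def table1_from_tg(
    tg_by_cell: dict[tuple[float, float], float],
    Tb: float, Tc: float, psib: float,
) -> pd.DataFrame:
    """Per-treatment thermal/hydro/hydrothermal constants from known tg values.

    ``tg_by_cell`` maps (temperature degC, psi MPa) to the germination time
    tg in hours for the chosen percentile.  Cells whose driving force
    vanishes (psi <= psib, T outside (Tb, Tc)) get NaN markers.
    """
    rows = []
    for (T, psi), tg in sorted(tg_by_cell.items(), key=lambda kv: (kv[0][0], -kv[0][1])):
        row = dict.fromkeys(_GRID_COLUMNS, np.nan)
        row["temperature_C"], row["psi_MPa"] = T, psi
        if tg is not None and np.isfinite(tg) and tg > 0:
            row["tg_h"] = tg
            row["GR_per_h"] = 1.0 / tg
            if T > Tb:
                row["TTsub_Ch"] = tt_sub(T, Tb, tg)
            if T < Tc:
                row["TTsupra_Ch"] = tt_supra(T, Tc, tg)
            if psi > psib:
                row["thetaH_MPah"] = hydrotime_theta(psi, psib, tg)
                if T > Tb:
                    row["thetaHTT_MPaCh"] = theta_htt(psi, psib, T, Tb, tg)
        rows.append(row)
    return pd.DataFrame(rows, columns=_GRID_COLUMNS)


def table1_grid(
    curves: Sequence[GerminationTimeCourse],
    Tb: float, Tc: float, psib: float, g: float = 0.5,
) -> pd.DataFrame:
    """Per-treatment constants with tg(g) interpolated from pooled time courses."""
    by_cell: dict[tuple[float, float], list[GerminationTimeCourse]] = {}
    for tc in curves:
        by_cell.setdefault((tc.temperature, tc.water_potential), []).append(tc)
    tg_by_cell: dict[tuple[float, float], float] = {}
    for cell, group in by_cell.items():
        rate = _gr_percentile(group, g)
        tg_by_cell[cell] = 1.0 / rate if rate > 0 else np.nan
    return table1_from_tg(tg_by_cell, Tb, Tc, psib)
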