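"""Synthetic germination studies with hydrothermal-time population structure.

Each seed in a dish draws its own base water potential from
``Normal(psib50 + kT*max(0, T - To), sigma_psib)``; a seed whose threshold
lies below the medium's water potential germinates at

    tg = theta_HTT / ((psi - psi_b) * (T - Tb))   hours,

otherwise never (no dormancy release).  Scoring the dish at the observation
times yields exactly the kind of cumulative count table the index and
fitting code consumes, with the binomial sampling noise of a real 10-seed
dish — or, with ``noise_mode="none"``, the expected counts from the
closed-form CDF.

Defaults reproduce the reference study design: 15/20/25/30 degC x
0/-0.3/-0.6/-0.9/-1.2 MPa, 3 replicate dishes of 10 seeds, daily counts for
10 days.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import datasets
from .models import HTTParams, effective_psi, fit_hydrotime_probit, fit_htt, predict_time_course
from .timecourse import HOURS_PER_DAY, FitFailureError, GerminationTimeCourse

__all__ = ["SimulationConfig", "simulate_dish", "simulate_study", "recovery_experiment"]

_DEFAULT_TIMES_H = tuple(float(h) for h in range(24, 241, 24))


@dataclass(frozen=True)
class SimulationConfig:
    """Design and truth of a synthetic germination study."""

    true_params: HTTParams = field(default_factory=datasets.sunflower_htt_params)
    temperatures: tuple[float, ...] = datasets.SUNFLOWER_TEMPERATURES
    water_potentials: tuple[float, ...] = datasets.SUNFLOWER_WATER_POTENTIALS
    n_replicates: int = 3
    n_seeds_per_dish: int = 10
    observation_times_h: tuple[float, ...] = _DEFAULT_TIMES_H
    rng_seed: int = 0
    noise_mode: str = "binomial"  # or "none"

    def __post_init__(self) -> None:
        if self.n_seeds_per_dish < 1:
            raise ValueError("n_seeds_per_dish must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.temperatures or not self.water_potentials:
            raise ValueError("empty treatment grid")
        t = np.asarray(self.observation_times_h)
        if len(t) == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing and > 0")
        if self.noise_mode not in ("binomial", "none"):
            raise ValueError("noise_mode must be 'binomial' or 'none'")


def _dish_rng(config: SimulationConfig, T: float, psi: float, rep: int) -> np.random.Generator:
    """Deterministic per-dish substream from (seed, T, psi, replicate)."""
    key = (int(config.rng_seed), int(round(T * 100)), int(round(-psi * 1000)), int(rep))
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_dish(
    config: SimulationConfig,
    T: float,
    psi: float,
    replicate: int = 0,
    rng: np.random.Generator | None = None,
) -> GerminationTimeCourse:
    """One dish's cumulative counts at the configured observation times."""
    p = config.true_params
    times_h = np.asarray(config.observation_times_h)
    n = config.n_seeds_per_dish
    if T <= p.Tb:
        warnings.warn(f"T={T} <= Tb={p.Tb}: dish never germinates", stacklevel=2)
        counts = np.zeros(len(times_h), dtype=int)
    elif config.noise_mode == "none":
        frac = predict_time_course(p, T, psi, times_h)
        counts = np.round(frac * n).astype(int)
        counts = np.maximum.accumulate(counts)
    else:
        if rng is None:
            rng = _dish_rng(config, T, psi, replicate)
        psi_eff = effective_psi(psi, T, p.kT, p.To)
        psib = rng.normal(p.psib50, p.sigma_psib, size=n)
        germinates = psib < psi_eff
        tg = np.full(n, np.inf)
        tg[germinates] = p.thetaHTT / ((psi_eff - psib[germinates]) * (T - p.Tb))
        counts = (tg[None, :] <= times_h[:, None]).sum(axis=1)
    return GerminationTimeCourse(
        temperature=T,
        water_potential=psi,
        times=tuple(times_h / HOURS_PER_DAY),
        cumulative_counts=tuple(int(c) for c in counts),
        n_seeds=n,
        replicate_id=f"r{replicate + 1}",
    )


def simulate_study(config: SimulationConfig) -> tuple[list[GerminationTimeCourse], HTTParams]:
    """Full grid x replicates; returns the courses and the generating truth."""
    courses = []
    for T in config.temperatures:
        for psi in config.water_potentials:
            for rep in range(config.n_replicates):
                courses.append(simulate_dish(config, T, psi, rep))
    return courses, config.true_params


def recovery_experiment(
    config: SimulationConfig,
    fit: str = "htt",
    n_repeats: int = 50,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Simulate -> fit -> score, repeated; one row of estimates per repeat.

    ``fit`` selects the estimator: "htt" (joint grid fit) or "hydrotime"
    (single-temperature fit on the curves at ``fit_kwargs['temperature']``).
    Fit failures are recorded (NaN row, ``fit_failed=True``), not raised.
    The returned frame carries per-parameter relative errors and a
    ``summary()``-style aggregate is left to the caller (mean bias / RMSE
    are one groupby away).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    fit_kwargs = dict(fit_kwargs or {})
    truth = config.true_params
    rows = []
    for i in range(n_repeats):
        cfg = replace(config, rng_seed=config.rng_seed + i)
        courses, _ = simulate_study(cfg)
        row: dict[str, float | bool] = {"repeat": i, "fit_failed": False}
        try:
            if fit == "htt":
                params, diag = fit_htt(courses, **fit_kwargs)
                est = {
                    "thetaHTT": params.thetaHTT, "Tb": params.Tb,
                    "psib50": params.psib50, "sigma_psib": params.sigma_psib,
                    "kT": params.kT,
                }
                true = {
                    "thetaHTT": truth.thetaHTT, "Tb": truth.Tb,
                    "psib50": truth.psib50, "sigma_psib": truth.sigma_psib,
                    "kT": truth.kT,
                }
            elif fit == "hydrotime":
                T_fit = fit_kwargs.pop("temperature", None) or min(
                    config.temperatures, key=lambda T: abs(T - (truth.To or T)))
                sub = [tc for tc in courses if tc.temperature == T_fit]
                params, diag = fit_hydrotime_probit(sub, **fit_kwargs)
                fit_kwargs["temperature"] = T_fit
                est = {
                    "thetaH": params.thetaH, "psib50": params.psib50,
                    "sigma_psib": params.sigma_psib,
                }
                true = {
                    "thetaH": truth.thetaHTT / (T_fit - truth.Tb),
                    "psib50": truth.psib50, "sigma_psib": truth.sigma_psib,
                }
            else:
                raise ValueError(f"unknown fit {fit!r}")
        except FitFailureError:
            row["fit_failed"] = True
            rows.append(row)
            continue
        row["r_squared"] = diag.r_squared
        for name, val in est.items():
            row[name] = val
            row[f"{name}_error"] = val - true[name]
            denom = abs(true[name])
            row[f"{name}_rel_error"] = (val - true[name]) / denom if denom > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
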