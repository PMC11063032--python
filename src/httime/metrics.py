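"""Scalar germination indices computed from dish-level time courses.

All the classical seed-lot performance statistics: germination percentage,
mean germination time (MGT) and rate (MGR), germination energy (GE),
germination rate index (GRI), germination index (GI), Timson's index,
coefficient of velocity of germination (CVG), time to 50% germination (T50)
and the two seed vigor indices (length- and dry-weight-based).

Conventions
-----------
* Daily new germinations are first differences of the cumulative counts.
* Day-weighted formulas (GE, GRI, GI, Timson) use integer day indices;
  non-integer observation times are floored with a warning.
* An index that is undefined (e.g. MGT with zero germination, T50 when the
  lot never reaches 50%) raises :class:`UndefinedIndexError` from the
  low-level function and is reported as a missing value with a reason code
  by :func:`index_report` — never as a silent 0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .timecourse import (
    GerminationTimeCourse,
    SeedlingMeasures,
    UndefinedIndexError,
)

__all__ = [
    "cumulative_fraction",
    "mean_germination_time",
    "mean_germination_rate",
    "germination_energy",
    "germination_rate_index",
    "germination_index",
    "timson_index",
    "coefficient_velocity",
    "time_to_50",
    "seed_vigor_indices",
    "IndexReport",
    "index_report",
]

GI_WINDOW_DAYS = 10  # weights run 10..1 over days 1..10


def cumulative_fraction(tc: GerminationTimeCourse) -> np.ndarray:
    """Cumulative germinated fraction (count / seeds sown) at each time."""
    return tc.fractions


def mean_germination_time(tc: GerminationTimeCourse) -> float:
    """MGT = sum(f_i * x_i) / sum(f_i), days.

    ``f_i`` are the newly germinated counts per observation, ``x_i`` the
    observation times in days.
    """
    f = tc.new_counts()
    total = f.sum()
    if total <= 0:
        raise UndefinedIndexError("no_germination", "MGT undefined: no seed germinated")
    return float((f * tc.times_d).sum() / total)


def mean_germination_rate(tc: GerminationTimeCourse) -> float:
    """MGR = 1 / MGT, 1/days."""
    return 1.0 / mean_germination_time(tc)


def germination_energy(tc: GerminationTimeCourse) -> float:
    """GE = sum over days of (daily increment of cumulative germination %) / day number."""
    days, new = tc.daily_new_counts()
    if np.any(days <= 0):
        raise ValueError("germination energy needs positive day numbers")
    inc_pct = 100.0 * new / tc.n_seeds
    return float((inc_pct / days).sum())


def germination_rate_index(tc: GerminationTimeCourse, variant: str = "standard") -> float:
    """GRI from daily germination percentages G_i.

    variant="standard"
        sum(G_i / d_i): each day's increment percentage divided by its day
        number (the conventional, day-weighted form; default).
    variant="as_printed"
        sum(G_i / 2): a literal day-independent form found in some reports,
        kept for comparability.
    """
    days, new = tc.daily_new_counts()
    if np.any(days <= 0):
        raise ValueError("germination rate index needs positive day numbers")
    g_pct = 100.0 * new / tc.n_seeds
    if variant == "standard":
        return float((g_pct / days).sum())
    if variant == "as_printed":
        return float((g_pct / 2.0).sum())
    raise ValueError(f"unknown GRI variant {variant!r}; use 'standard' or 'as_printed'")


def germination_index(tc: GerminationTimeCourse) -> float:
    """GI = sum over days 1..10 of (11 - d) * n_d, with n_d newly germinated seeds.

    Day-1 germinations carry weight 10, day-10 germinations weight 1.  Seeds
    germinating after day 10 fall outside the weighting window and contribute
    0, with a warning.
    """
    days, new = tc.daily_new_counts()
    late = new[days > GI_WINDOW_DAYS].sum()
    if late > 0:
        warnings.warn(
            f"{int(late)} seed(s) germinated after day {GI_WINDOW_DAYS}; "
            "they receive weight 0 in GI",
            stacklevel=2,
        )
    in_win = (days >= 1) & (days <= GI_WINDOW_DAYS)
    return float(((GI_WINDOW_DAYS + 1 - days[in_win]) * new[in_win]).sum())


def timson_index(tc: GerminationTimeCourse, window_days: int = 10) -> float:
    """Timson's index: sum of cumulative germination % over each day of the window.

    The cumulative percentage is treated as a step function of the day index
    (carried forward between observations).
    """
    if window_days < 1:
        raise ValueError("timson window must contain at least one day")
    days, new = tc.daily_new_counts()
    cum = np.cumsum(new)
    total = 0.0
    for d in range(1, window_days + 1):
        mask = days <= d
        pct = 100.0 * cum[mask][-1] / tc.n_seeds if mask.any() else 0.0
        total += pct
    return float(total)


def coefficient_velocity(tc: GerminationTimeCourse) -> float:
    """CVG = 100 * sum(n_i) / sum(n_i * t_i) = 100 / MGT, %/day."""
    return 100.0 / mean_germination_time(tc)


def time_to_50(tc: GerminationTimeCourse) -> float:
    """Time for half of the *germinated* seeds to germinate, days.

    Defined only when the final cumulative fraction reaches at least 0.5 of
    the seeds sown.  The target count is N/2 with N the final germinated
    count (Coolbear/Farooq convention); the crossing time is linearly
    interpolated between the bracketing observations.
    """
    if tc.final_fraction < 0.5:
        raise UndefinedIndexError(
            "below_half", "T50 undefined: final germination below 50%"
        )
    target = tc.final_count / 2.0
    counts = tc.counts
    times = tc.times_d
    j = int(np.argmax(counts >= target))
    if counts[j] == target or j == 0:
        return float(times[j])
    i = j - 1
    return float(
        times[i] + (target - counts[i]) * (times[j] - times[i]) / (counts[j] - counts[i])
    )


def seed_vigor_indices(
    tc: GerminationTimeCourse, sm: SeedlingMeasures
) -> tuple[float, float]:
    """(SVI-I, SVI-II) = (seedling length x germination %, dry weight x germination %)."""
    gp = tc.germination_percent
    return sm.seedling_length * gp, sm.dry_weight * gp


@dataclass
class IndexReport:
    """All scalar indices for one dish; undefined entries are None with a reason."""

    temperature: float
    water_potential: float
    replicate_id: str
    germination_percent: float
    MGT: float | None = None
    MGR: float | None = None
    GE: float | None = None
    GRI: float | None = None
    GI: float | None = None
    timson_index: float | None = None
    CVG: float | None = None
    T50: float | None = None
    SVI_length: float | None = None
    SVI_weight: float | None = None
    undefined_reasons: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def index_report(
    tc: GerminationTimeCourse,
    sm: SeedlingMeasures | None = None,
    gri_variant: str = "standard",
    timson_window: int = 10,
) -> IndexReport:
    """Compute every index for one dish, recording undefined values with reasons."""
    rep = IndexReport(
        temperature=tc.temperature,
        water_potential=tc.water_potential,
        replicate_id=tc.replicate_id,
        germination_percent=tc.germination_percent,
        metadata={
            "gri_variant": gri_variant,
            "timson_window_days": timson_window,
            "ge_interpretation": "cumulative-% increments divided by day number",
        },
    )

    def _try(name, fn):
        try:
            setattr(rep, name, fn())
        except UndefinedIndexError as err:
            rep.undefined_reasons[name] = err.reason

    _try("MGT", lambda: mean_germination_time(tc))
    _try("MGR", lambda: mean_germination_rate(tc))
    _try("GE", lambda: germination_energy(tc))
    _try("GRI", lambda: germination_rate_index(tc, gri_variant))
    _try("GI", lambda: germination_index(tc))
    _try("timson_index", lambda: timson_index(tc, timson_window))
    _try("CVG", lambda: coefficient_velocity(tc))
    _try("T50", lambda: time_to_50(tc))
    if sm is not None:
        svi1, svi2 = seed_vigor_indices(tc, sm)
        rep.SVI_length, rep.SVI_weight = svi1, svi2
    return rep
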