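"""Dish-level germination records.

A germination trial scores each Petri dish repeatedly (here: once a day),
recording the cumulative number of seeds that have shown radicle emergence.
:class:`GerminationTimeCourse` is the canonical in-memory record of one dish
under one (temperature, water potential) treatment; every index and every
threshold-model fit in this package consumes it.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

HOURS_PER_DAY = 24.0


class UndefinedIndexError(ValueError):
    """An index is undefined for this time course (e.g. nothing germinated).

    Carries a machine-readable ``reason`` code so reports can flag the value
    as missing-with-cause rather than silently writing 0.
    """

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(message or reason)


class FitFailureError(RuntimeError):
    """A model fit could not be carried out on the supplied data."""


@dataclass(frozen=True)
class GerminationTimeCourse:
    """Cumulative germination counts of one dish over time.

    Parameters
    ----------
    temperature : float
        Incubation temperature in degrees Celsius.
    water_potential : float
        Osmotic potential of the germination medium in MPa (0 for distilled
        water, negative under PEG-imposed stress).
    times : sequence of float
        Observation times in days, strictly increasing, all > 0.
    cumulative_counts : sequence of int
        Cumulative germinated count at each observation time; non-decreasing,
        each in ``[0, n_seeds]``.
    n_seeds : int
        Seeds sown in the dish.
    replicate_id : str
        Replicate label.
    """

    temperature: float
    water_potential: float
    times: tuple[float, ...]
    cumulative_counts: tuple[int, ...]
    n_seeds: int
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(
            self, "cumulative_counts", tuple(int(c) for c in self.cumulative_counts)
        )
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.water_potential > 0:
            raise ValueError("water_potential must be <= 0 MPa (water tension)")
        if len(self.times) != len(self.cumulative_counts):
            raise ValueError("times and cumulative_counts must have equal length")
        if len(self.times) == 0:
            raise ValueError("at least one observation is required")
        t = np.asarray(self.times)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        c = np.asarray(self.cumulative_counts)
        if np.any(np.diff(c) < 0):
            raise ValueError("cumulative_counts must be non-decreasing")
        if c.min() < 0 or c.max() > self.n_seeds:
            raise ValueError("cumulative_counts must lie in [0, n_seeds]")

    # -- basic views ---------------------------------------------------
    @property
    def times_d(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def times_h(self) -> np.ndarray:
        return self.times_d * HOURS_PER_DAY

    @property
    def counts(self) -> np.ndarray:
        return np.asarray(self.cumulative_counts, dtype=float)

    @property
    def fractions(self) -> np.ndarray:
        """Cumulative germinated fraction at each observation time."""
        return self.counts / self.n_seeds

    @property
    def final_count(self) -> int:
        return self.cumulative_counts[-1]

    @property
    def final_fraction(self) -> float:
        return self.final_count / self.n_seeds

    @property
    def germination_percent(self) -> float:
        return 100.0 * self.final_fraction

    def new_counts(self) -> np.ndarray:
        """Seeds newly germinated in each observation interval (first differences)."""
        return np.diff(self.counts, prepend=0.0)

    def daily_new_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Newly germinated counts aggregated onto integer day indices.

        Index formulas that weight by "day number" assume daily scoring.
        Non-integer observation times are floored to a day index with a
        warning; observations landing on the same day are summed.
        """
        days = []
        for t in self.times:
            d = int(math.floor(t + 1e-9))
            if abs(t - round(t)) > 1e-9:
                warnings.warn(
                    f"non-integer observation time {t} d floored to day {d}",
                    stacklevel=2,
                )
            days.append(d)
        days_arr = np.asarray(days)
        new = self.new_counts()
        uniq = np.unique(days_arr)
        agg = np.array([new[days_arr == d].sum() for d in uniq])
        return uniq, agg


@dataclass(frozen=True)
class SeedlingMeasures:
    """Per-replicate seedling measurements used by the vigor indices."""

    radicle_length: float  # cm
    plumule_length: float  # cm
    dry_weight: float      # g

    def __post_init__(self) -> None:
        if min(self.radicle_length, self.plumule_length, self.dry_weight) < 0:
            raise ValueError("seedling measures must be >= 0")

    @property
    def seedling_length(self) -> float:
        return self.radicle_length + self.plumule_length
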