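"""Core data containers shared across the pipeline stages.

The containers are deliberately light: plain dataclasses wrapping numpy
arrays, with validation in ``__post_init__`` and a few convenience
constructors.  All calendar times are decimal years; all follow-up times
are years since diagnosis.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LifeTable",
    "IndividualRecord",
    "TrueTrend",
    "AgeRateTable",
    "SurvivalPoint",
    "StandardWeights",
    "NetSurvivalCurve",
    "split_group",
]


def split_group(group: str) -> tuple[str, str]:
    """Split a ``country_sex`` group label at the last underscore."""
    country, _, sex = group.rpartition("_")
    if not country:
        raise ValueError(f"group label {group!r} is not of the form country_sex")
    return country, sex


@dataclass
class LifeTable:
    """Population mortality lookup by calendar year and attained age.

    Hazards are annual mortality rates (per person-year), stored as a dense
    ``(n_years, n_ages)`` array.  The hazard is treated as piecewise
    constant on unit (year, age) cells, so a person's cumulative expected
    hazard along follow-up is piecewise linear with breakpoints whenever
    their attained age or the calendar year crosses an integer.
    """

    country: str
    sex: str
    year_start: int
    hazards: np.ndarray  # shape (n_years, n_ages), age index = integer age

    def __post_init__(self) -> None:
        self.hazards = np.asarray(self.hazards, dtype=float)
        if self.hazards.ndim != 2:
            raise ValueError("hazards must be a 2-D (year, age) array")
        if not np.all(np.isfinite(self.hazards)):
            raise ValueError("life-table hazards must be finite")
        if np.any(self.hazards < 0):
            raise ValueError("life-table hazards must be non-negative")

    @property
    def n_years(self) -> int:
        return self.hazards.shape[0]

    @property
    def n_ages(self) -> int:
        return self.hazards.shape[1]

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_start + self.n_years)

    def entries(self) -> dict[tuple[int, int], float]:
        """Mapping ``(calendar_year, age) -> hazard`` (materialized)."""
        return {
            (self.year_start + i, a): float(self.hazards[i, a])
            for i in range(self.n_years)
            for a in range(self.n_ages)
        }

    def hazard(self, year: int, age: int) -> float:
        """Annual hazard for an integer (year, age) cell; strict lookup."""
        iy = int(year) - self.year_start
        ia = int(age)
        if not (0 <= iy < self.n_years and 0 <= ia < self.n_ages):
            raise KeyError(
                f"life table {self.country}/{self.sex} has no cell for "
                f"year={year}, age={age} (years {self.year_start}-"
                f"{self.year_start + self.n_years - 1}, ages 0-{self.n_ages - 1})"
            )
        return float(self.hazards[iy, ia])

    def hazard_at(self, a0: float, y0: float, t: float, *, clip_age: bool = False) -> float:
        """Hazard experienced at follow-up time ``t`` by a person aged
        ``a0`` at decimal calendar time ``y0``."""
        age = math.floor(a0 + t)
        year = math.floor(y0 + t)
        if clip_age:
            age = min(age, self.n_ages - 1)
        return self.hazard(year, age)

    def cumhaz_breakpoints(
        self, a0: float, y0: float, t_max: float, *, clip_age: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Exact cumulative expected hazard along follow-up.

        Returns ``(times, H)`` such that the cumulative hazard
        ``H_P(t) = ∫₀ᵗ λ_P(u) du`` is given exactly by linear
        interpolation of ``H`` over ``times`` (the hazard is constant
        between breakpoints).
        """
        if t_max < 0:
            raise ValueError("t_max must be non-negative")
        cuts = {0.0, float(t_max)}
        # integer crossings of attained age and calendar year
        for x0 in (a0, y0):
            u = math.ceil(x0) - x0
            if u == 0.0:
                u = 1.0
            while u < t_max:
                cuts.add(u)
                u += 1.0
        times = np.array(sorted(cuts))
        mids = 0.5 * (times[:-1] + times[1:])
        haz = np.array([self.hazard_at(a0, y0, m, clip_age=clip_age) for m in mids])
        H = np.concatenate([[0.0], np.cumsum(haz * np.diff(times))])
        return times, H

    def cumulative_hazard(
        self, a0: float, y0: float, t, *, clip_age: bool = False
    ) -> np.ndarray | float:
        """Exact ``H_P(t)`` for scalar or array ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise ValueError("follow-up times must be non-negative")
        t_max = float(t_arr.max()) if t_arr.size else 0.0
        times, H = self.cumhaz_breakpoints(a0, y0, max(t_max, 0.0), clip_age=clip_age)
        out = np.interp(t_arr, times, H)
        return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass
class IndividualRecord:
    """One patient's diagnosis and follow-up."""

    id: str
    country: str
    sex: str
    age_at_dx: float  # years, in [0, 89]
    dx_year: float  # decimal calendar year
    follow_up: float  # years, > 0
    status: str  # "died" | "censored"

    def __post_init__(self) -> None:
        if not (0.0 <= self.age_at_dx <= 89.0):
            raise ValueError(f"age_at_dx {self.age_at_dx} outside [0, 89]")
        if self.follow_up <= 0:
            raise ValueError("follow_up must be positive")
        if self.status not in ("died", "censored"):
            raise ValueError(f"status must be 'died' or 'censored', got {self.status!r}")

    @property
    def group(self) -> str:
        return f"{self.country}_{self.sex}"


@dataclass
class TrueTrend:
    """Ground-truth net-survival curve over calendar time for one group.

    ``curve`` maps decimal calendar year to a net-survival fraction in
    (0, 1].  The ``family`` and ``parameters`` fields record how the curve
    was built so that simulation-recovery tests can inspect the truth
    (e.g. a piecewise-linear family records its changepoint year).
    """

    group: str
    horizon: str  # "1y" | "5y"
    curve: Callable[[float], float]
    family: str = "custom"
    parameters: dict = field(default_factory=dict)

    def __call__(self, year) -> np.ndarray | float:
        val = np.vectorize(self.curve, otypes=[float])(year)
        return float(val) if np.ndim(year) == 0 else val

    def validate_on(self, years: Sequence[float]) -> None:
        vals = self(np.asarray(years, dtype=float))
        if np.any(vals <= 0) or np.any(vals > 1):
            raise ValueError("TrueTrend curve values must lie in (0, 1]")

    # --- constructors for the supported families -------------------------
    @classmethod
    def constant(cls, group: str, horizon: str, level: float) -> "TrueTrend":
        return cls(group, horizon, lambda y: level, "constant", {"level": level})

    @classmethod
    def linear(
        cls, group: str, horizon: str, year0: float, value0: float, slope_per_year: float
    ) -> "TrueTrend":
        """``slope_per_year`` on the fraction scale (e.g. 0.004 = 0.4 %/yr)."""
        return cls(
            group,
            horizon,
            lambda y: value0 + slope_per_year * (y - year0),
            "linear",
            {"year0": year0, "value0": value0, "slope_per_year": slope_per_year},
        )

    @classmethod
    def logistic(
        cls, group: str, horizon: str, lower: float, upper: float,
        mid_year: float, rate: float,
    ) -> "TrueTrend":
        return cls(
            group,
            horizon,
            lambda y: lower + (upper - lower) / (1.0 + math.exp(-rate * (y - mid_year))),
            "logistic",
            {"lower": lower, "upper": upper, "mid_year": mid_year, "rate": rate},
        )

    @classmethod
    def piecewise_linear(
        cls, group: str, horizon: str, year0: float, value0: float,
        slope_before: float, slope_after: float, changepoint: float,
    ) -> "TrueTrend":
        def f(y: float) -> float:
            if y <= changepoint:
                return value0 + slope_before * (y - year0)
            at_cp = value0 + slope_before * (changepoint - year0)
            return at_cp + slope_after * (y - changepoint)

        return cls(
            group, horizon, f, "piecewise-linear",
            {
                "year0": year0, "value0": value0, "slope_before": slope_before,
                "slope_after": slope_after, "changepoint": changepoint,
            },
        )


@dataclass
class AgeRateTable:
    """Age-specific case counts and person-years for one group and year."""

    group: str
    year: int
    rows: list[tuple[tuple[float, float], int, float]]  # ((lo, hi), cases, person_years)

    def __post_init__(self) -> None:
        seen: list[tuple[float, float]] = []
        for (lo, hi), cases, py in self.rows:
            if hi <= lo:
                raise ValueError(f"age band [{lo}, {hi}) is empty")
            if cases < 0 or int(cases) != cases:
                raise ValueError("case counts must be non-negative integers")
            if py <= 0:
                raise ValueError("person_years must be positive")
            for lo2, hi2 in seen:
                if lo < hi2 and lo2 < hi:
                    raise ValueError(f"age bands overlap: [{lo},{hi}) and [{lo2},{hi2})")
            seen.append((lo, hi))

    @property
    def bands(self) -> list[tuple[float, float]]:
        return [band for band, _, _ in self.rows]


@dataclass
class SurvivalPoint:
    """One group × period × horizon relative-survival estimate (percent).

    This is the observation unit of the trend model: an estimate with its
    standard error at the middle year of a 5-year calendar period.
    """

    group: str
    site: str
    period: tuple[int, int]
    horizon: str  # "1y" | "5y"
    estimate: float  # percent
    se: float  # percent
    ci: tuple[float, float] | None = None
    design: str = "cohort"  # "cohort" | "hybrid"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo <= self.estimate <= hi):
                raise ValueError(
                    f"estimate {self.estimate} outside its CI ({lo}, {hi})"
                )

    @property
    def midyear(self) -> float:
        # 5-year label range (start, end): integer midpoint, e.g. 1971-1975 -> 1973
        return float(self.period[0] + 2)


@dataclass
class StandardWeights:
    """External age-standardization weights (fractions summing to 1)."""

    rows: list[tuple[tuple[float, float], float]]  # ((lo, hi), weight)
    label: str = "custom"

    def __post_init__(self) -> None:
        total = 0.0
        seen: list[tuple[float, float]] = []
        for (lo, hi), w in self.rows:
            if w < 0:
                raise ValueError("weights must be non-negative")
            if hi <= lo:
                raise ValueError(f"age band [{lo}, {hi}) is empty")
            for lo2, hi2 in seen:
                if lo < hi2 and lo2 < hi:
                    raise ValueError("weight bands overlap")
            seen.append((lo, hi))
            total += w
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {total!r})")

    @property
    def bands(self) -> list[tuple[float, float]]:
        return [band for band, _ in self.rows]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.rows])

    def band_of(self, age: float) -> int:
        for i, (lo, hi) in enumerate(self.bands):
            if lo <= age < hi:
                return i
        raise ValueError(f"age {age} not covered by weight bands {self.bands}")


@dataclass
class NetSurvivalCurve:
    """Net survival on a follow-up time grid, with variance and risk counts.

    Net survival may exceed 1: it is a ratio of observed to expected
    survival, not a probability.
    """

    group: str
    grid: np.ndarray  # years since diagnosis, grid[0] == 0
    estimate: np.ndarray  # net survival fraction
    variance: np.ndarray
    n_at_risk: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=float)
        if self.grid[0] != 0.0:
            raise ValueError("time grid must start at 0")
        if abs(self.estimate[0] - 1.0) > 1e-12:
            raise ValueError("net survival at t=0 must be 1")
        if np.any(self.estimate <= 0):
            raise ValueError("net survival estimates must be positive")
        if np.any(self.variance < 0):
            raise ValueError("variances must be non-negative")

    def at(self, t: float) -> tuple[float, float]:
        """(estimate, variance) at grid time ``t`` (must be on the grid)."""
        idx = np.nonzero(np.isclose(self.grid, t))[0]
        if idx.size == 0:
            raise ValueError(f"t={t} is not on the curve grid")
        i = int(idx[0])
        return float(self.estimate[i]), float(self.variance[i])
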