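"""Synthetic registry data generators.

Produces individual-level cohorts, life tables, age-specific rate tables
and period-wise survival estimates with the statistical structure the
downstream estimation and trend stages assume, so that every stage can be
exercised without external data.

Excess-hazard model: the excess (cancer-specific) hazard of a patient is
constant over follow-up and depends only on the diagnosis year, calibrated
so that ``exp(-5 * excess) `` equals the ground-truth 5-year net survival
at that year.  Total hazard = population hazard (life table, advancing
with attained age and calendar year) + excess hazard; administrative
censoring at the end of the study window.
"""
from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .datatypes import AgeRateTable, IndividualRecord, LifeTable, SurvivalPoint, TrueTrend, split_group

logger = logging.getLogger(__name__)

__all__ = [
    "default_periods",
    "make_life_table",
    "simulate_cohort",
    "simulate_survival_points",
    "make_rate_table",
]

#: default study layout: ten 5-year calendar periods 1971-2020
DEFAULT_PERIODS: list[tuple[int, int]] = [(1971 + 5 * k, 1975 + 5 * k) for k in range(10)]

#: default age bands for case ages: uniform over 5-year bands 15-89
DEFAULT_AGE_RANGE: tuple[float, float] = (15.0, 90.0)


def default_periods(n: int = 10, start: int = 1971) -> list[tuple[int, int]]:
    return [(start + 5 * k, start + 5 * k + 4) for k in range(n)]


def make_life_table(
    country: str,
    sex: str,
    years: Sequence[int] | range,
    makeham_params: tuple[float, float, float],
    *,
    annual_improvement: float = 1.0,
    n_ages: int = 100,
) -> LifeTable:
    """Deterministic Gompertz–Makeham life table.

    ``hazard(age) = a + b * exp(c * age)``, optionally scaled per calendar
    year by ``annual_improvement ** (year - first_year)``.
    """
    a, b, c = (float(v) for v in makeham_params)
    if not all(math.isfinite(v) for v in (a, b, c, annual_improvement)):
        raise ValueError("Makeham parameters and improvement factor must be finite")
    if a < 0:
        raise ValueError("Makeham parameter a must be >= 0")
    if b < 0 or c < 0:
        raise ValueError("Makeham parameters b, c must be non-negative")
    years = list(years)
    ages = np.arange(n_ages)
    base = a + b * np.exp(c * ages)
    scale = np.power(annual_improvement, np.arange(len(years)))
    hazards = scale[:, None] * base[None, :]
    return LifeTable(country=country, sex=sex, year_start=int(years[0]), hazards=hazards)


def _excess_hazard(truth: TrueTrend, dx_years: np.ndarray) -> np.ndarray:
    """Constant excess hazard per diagnosis year from 5-year net survival."""
    s5 = np.asarray(truth(dx_years), dtype=float)
    if np.any(s5 <= 0) or np.any(s5 > 1):
        raise ValueError("TrueTrend curve values must lie in (0, 1]")
    return -np.log(s5) / 5.0


def _population_death_times(
    life_table: LifeTable,
    ages: np.ndarray,
    dx_years: np.ndarray,
    t_max: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-transform sampling of death times from the life table.

    The cumulative population hazard is piecewise linear in follow-up time
    (hazard constant between integer age/year crossings); we invert it
    exactly, per subject.  Ages beyond the table's top age reuse the
    top-age hazard.  Returns ``inf`` where no population death occurs
    before ``t_max``.
    """
    n = ages.size
    horizon = float(np.max(t_max)) if n else 0.0
    m = int(math.ceil(horizon)) + 1
    # per-subject breakpoints: integer crossings of attained age and year
    frac_a = np.ceil(ages) - ages
    frac_a[frac_a == 0] = 1.0
    frac_y = np.ceil(dx_years) - dx_years
    frac_y[frac_y == 0] = 1.0
    ks = np.arange(m)
    t_max = np.asarray(t_max, dtype=float)
    cuts = np.concatenate(
        [
            np.zeros((n, 1)),
            frac_a[:, None] + ks[None, :],
            frac_y[:, None] + ks[None, :],
            t_max[:, None],
        ],
        axis=1,
    )
    # cap each subject's partition at their own administrative horizon
    np.minimum(cuts, t_max[:, None], out=cuts)
    np.clip(cuts, 0.0, None, out=cuts)
    cuts.sort(axis=1)
    mids = 0.5 * (cuts[:, :-1] + cuts[:, 1:])
    widths = np.diff(cuts, axis=1)
    age_idx = np.minimum(
        np.floor(ages[:, None] + mids).astype(int), life_table.n_ages - 1
    )
    year_idx = np.floor(dx_years[:, None] + mids).astype(int) - life_table.year_start
    # zero-width segments at the per-subject cap carry no hazard; only
    # positive-width segments must lie inside the table's calendar span
    live = widths > 0
    if np.any((year_idx < 0) & live) or np.any((year_idx >= life_table.n_years) & live):
        raise ValueError(
            "cohort follow-up extends outside the life table's calendar span"
        )
    np.clip(year_idx, 0, life_table.n_years - 1, out=year_idx)
    seg_haz = life_table.hazards[year_idx, age_idx]
    H = np.concatenate([np.zeros((n, 1)), np.cumsum(seg_haz * widths, axis=1)], axis=1)
    e = rng.exponential(size=n)
    # first breakpoint whose cumulative hazard exceeds the draw
    idx = np.sum(H < e[:, None], axis=1)  # in 1..m+1; ==ncols means beyond horizon
    t_pop = np.full(n, np.inf)
    hit = idx < H.shape[1]
    i = idx[hit] - 1
    rows = np.nonzero(hit)[0]
    lam = seg_haz[rows, i]
    with np.errstate(divide="ignore", invalid="ignore"):
        dt = (e[hit] - H[rows, i]) / lam
    t_pop[hit] = cuts[rows, i] + dt
    return t_pop


def simulate_cohort(
    truth: Mapping[str, TrueTrend] | TrueTrend,
    life_table: Mapping[str, LifeTable] | LifeTable,
    n_per_period: int,
    periods: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    *,
    study_end: float | None = None,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    ltf_rate: float = 0.0,
) -> list[IndividualRecord]:
    """Simulate individual registry records under the excess-hazard model.

    Parameters
    ----------
    truth
        5-year-net-survival ``TrueTrend`` per group (or a single trend).
    life_table
        ``LifeTable`` per group or one shared table.
    n_per_period
        Patients diagnosed per group per 5-year period.
    periods
        5-year calendar periods; default 1971-2020.
    study_end
        Administrative censoring time as a decimal year; default is the
        end of the last period (its end year + 1, i.e. 2021.0 for 2020).
    age_range
        Ages at diagnosis are uniform over this half-open range.
    ltf_rate
        Optional exponential loss-to-follow-up hazard (default off).
    """
    if n_per_period < 1:
        raise ValueError("n_per_period must be >= 1")
    if periods is None:
        periods = DEFAULT_PERIODS
    if isinstance(truth, TrueTrend):
        truth = {truth.group: truth}
    if study_end is None:
        study_end = float(max(end for _, end in periods) + 1)
    rng = np.random.default_rng(seed)
    records: list[IndividualRecord] = []
    for group in sorted(truth):
        tt = truth[group]
        lt = life_table[group] if isinstance(life_table, Mapping) else life_table
        country, sex = split_group(group)
        for start, end in periods:
            n = int(n_per_period)
            dx = rng.uniform(start, end + 1, size=n)
            ages = rng.uniform(age_range[0], age_range[1], size=n)
            np.clip(ages, 0.0, 89.0, out=ages)
            lam_e = _excess_hazard(tt, dx)
            cens = study_end - dx  # administrative censoring, years
            with np.errstate(divide="ignore"):
                t_exc = np.where(
                    lam_e > 0, rng.exponential(size=n) / np.where(lam_e > 0, lam_e, 1.0), np.inf
                )
            t_pop = _population_death_times(lt, ages, dx, cens, rng)
            t_death = np.minimum(t_exc, t_pop)
            if ltf_rate > 0:
                t_ltf = rng.exponential(1.0 / ltf_rate, size=n)
                cens = np.minimum(cens, t_ltf)
            died = t_death <= cens
            fu = np.where(died, t_death, cens)
            fu = np.maximum(fu, 1e-9)  # follow_up must be > 0
            for j in range(n):
                records.append(
                    IndividualRecord(
                        id=f"{group}-{start}-{j}",
                        country=country,
                        sex=sex,
                        age_at_dx=float(ages[j]),
                        dx_year=float(dx[j]),
                        follow_up=float(fu[j]),
                        status="died" if died[j] else "censored",
                    )
                )
    return records


def simulate_survival_points(
    truth: Mapping[str, TrueTrend] | TrueTrend,
    se_level: float | Sequence[float] = 1.0,
    periods: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
    *,
    site: str = "colon",
    horizon: str | None = None,
) -> list[SurvivalPoint]:
    """Simulate period-wise survival estimates directly (trend-stage input).

    One observation per group × period at the period's middle year:
    ``observed = 100 * truth(midyear) + Normal(0, se)``, clipped to
    [0, 100] with clipping logged.  ``se_level`` may be a scalar or a
    per-period sequence of standard errors on the percent scale.
    """
    if periods is None:
        periods = DEFAULT_PERIODS
    if isinstance(truth, TrueTrend):
        truth = {truth.group: truth}
    ses = np.asarray(
        [se_level] * len(periods) if np.ndim(se_level) == 0 else se_level, dtype=float
    )
    if ses.size != len(periods):
        raise ValueError("per-period se_level must have one entry per period")
    if np.any(ses < 0):
        raise ValueError("se_level must be non-negative")
    rng = np.random.default_rng(seed)
    points: list[SurvivalPoint] = []
    n_clipped = 0
    for group in sorted(truth):
        tt = truth[group]
        for (start, end), se in zip(periods, ses):
            midyear = start + 2
            mean = 100.0 * float(tt(midyear))
            obs = mean + rng.normal(0.0, se) if se > 0 else mean
            clipped = min(max(obs, 0.0), 100.0)
            if clipped != obs:
                n_clipped += 1
            points.append(
                SurvivalPoint(
                    group=group,
                    site=site,
                    period=(start, end),
                    horizon=horizon or tt.horizon,
                    estimate=float(clipped),
                    se=float(se),
                    ci=None,
                    design="hybrid" if end + 1 > max(e for _, e in periods) else "cohort",
                )
            )
    if n_clipped:
        logger.warning("simulate_survival_points: clipped %d observations to [0, 100]", n_clipped)
    return points


def make_rate_table(
    group: str,
    year: int,
    rate_per_100k: float | Sequence[float],
    person_years: float | Sequence[float] = 50_000.0,
    *,
    bands: Sequence[tuple[float, float]] | None = None,
    seed: int | None = None,
) -> AgeRateTable:
    """Synthetic age-specific case-count table.

    ``rate_per_100k`` is the true incidence rate per band (scalar = shared).
    With a seed, counts are Poisson draws; without, deterministic rounded
    expectations.
    """
    if bands is None:
        bands = [(5.0 * k, 5.0 * (k + 1)) for k in range(18)]  # 0-89 in 5-year bands
    nb = len(bands)
    rates = np.broadcast_to(np.asarray(rate_per_100k, dtype=float), (nb,))
    pys = np.broadcast_to(np.asarray(person_years, dtype=float), (nb,))
    if np.any(rates < 0) or np.any(pys <= 0):
        raise ValueError("rates must be >= 0 and person-years > 0")
    mu = rates / 1e5 * pys
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(mu)
    else:
        counts = np.rint(mu).astype(int)
    rows = [
        ((float(lo), float(hi)), int(c), float(py))
        for (lo, hi), c, py in zip(bands, counts, pys)
    ]
    return AgeRateTable(group=group, year=int(year), rows=rows)
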