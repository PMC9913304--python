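"""Age-standardized net (relative) survival estimation.

Implements the inverse-expected-survival-weighted net-survival estimator
(Pohar Perme): each subject's at-risk and event contributions are weighted
by ``1 / S_P(t)``, the inverse of their expected survival from population
life tables, giving

    Λ_E(t) = Σ_{t_k ≤ t} Σ_i w_i(t_k) dN_i(t_k) / Σ_j w_j(t_k) Y_j(t_k)
             - ∫_0^t [Σ_i w_i(u) Y_i(u) λ_Pi(u)] / [Σ_i w_i(u) Y_i(u)] du
    S_E(t) = exp(-Λ_E(t))

with a Poisson-type variance for the weighted event increments.

Numerical convention (shared by the brute-force test oracle): the
population-hazard integral is evaluated by the midpoint rule on a
partition that cuts at every entry/exit time, every requested grid point
and every subject-level hazard breakpoint (integer attained-age/year
crossings), refined so that no subinterval exceeds ``step`` years.
Weights ``w_i(t) = exp(H_Pi(t))`` use the exact piecewise-linear
cumulative population hazard in the small-cohort path, and a midpoint-rule
cumulative hazard in the binned large-cohort path.

Ties: deaths precede censorings at the same time, so subjects censored at
an event time are still at risk there.
"""
from __future__ import annotations

import logging
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .datatypes import (
    IndividualRecord,
    LifeTable,
    NetSurvivalCurve,
    StandardWeights,
    SurvivalPoint,
)

logger = logging.getLogger(__name__)

__all__ = [
    "se_from_ci",
    "expected_survival",
    "pohar_perme",
    "age_standardize",
    "period_window_estimate",
    "load_standard_weights",
    "default_survival_weights",
]

Z_95 = 1.959964  # two-sided 95% normal quantile

#: cohorts up to this size use the exact event-time algorithm
EXACT_N_MAX = 600


def se_from_ci(ci: tuple[float, float]) -> float:
    """Standard error from a symmetric 95% confidence interval (percent)."""
    low, high = ci
    if high < low:
        raise ValueError(f"reversed confidence bounds ({low}, {high})")
    return (high - low) / (2.0 * Z_95)


def expected_survival(record: IndividualRecord, life_table: LifeTable, t: float) -> float:
    """Expected (population) survival ``S_P(t)`` for one record.

    Attained age and calendar year advance together along follow-up; the
    hazard is integrated exactly over the piecewise-constant unit cells.
    Raises if the lookup leaves the life table's span.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    H = life_table.cumulative_hazard(record.age_at_dx, record.dx_year, float(t))
    return float(np.exp(-H))


def _as_arrays(
    records: Sequence[IndividualRecord],
    entry: Sequence[float] | None,
    exit_override: Sequence[float] | None = None,
):
    n = len(records)
    a0 = np.array([r.age_at_dx for r in records])
    y0 = np.array([r.dx_year for r in records])
    T = (
        np.asarray(exit_override, dtype=float)
        if exit_override is not None
        else np.array([r.follow_up for r in records])
    )
    died = np.array([r.status == "died" for r in records])
    e = np.zeros(n) if entry is None else np.asarray(entry, dtype=float)
    if np.any(e < 0):
        raise ValueError("entry times must be non-negative")
    return a0, y0, e, T, died


def pohar_perme(
    records: Sequence[IndividualRecord],
    life_table: LifeTable,
    grid: Sequence[float],
    *,
    entry: Sequence[float] | None = None,
    step: float = 0.05,
    method: str = "auto",
) -> NetSurvivalCurve:
    """Net-survival curve on ``grid`` (years since diagnosis, starting at 0).

    ``entry`` gives optional delayed-entry (left-truncation) times for
    period/hybrid designs.  ``method`` is ``"exact"`` (event-by-event,
    exact expected-survival weights), ``"binned"`` (fine time bins, scales
    to large cohorts) or ``"auto"``.
    """
    if len(records) == 0:
        raise ValueError("pohar_perme requires at least one record")
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("grid must start at 0")
    a0, y0, e, T, died = _as_arrays(records, entry)
    if not np.any(T > 0):
        raise ValueError("all records exit at t=0; nothing to estimate")
    if method == "auto":
        method = "exact" if len(records) <= EXACT_N_MAX else "binned"
    if method == "exact":
        lam_E, var, pop_int, t_nodes = _pp_exact(a0, y0, e, T, died, life_table, grid, step)
    elif method == "binned":
        lam_E, var, pop_int, t_nodes = _pp_binned(a0, y0, e, T, died, life_table, grid, step)
    else:
        raise ValueError(f"unknown method {method!r}")
    # accumulate to the requested grid
    Lam = np.interp(grid, t_nodes, lam_E - pop_int)
    V = np.interp(grid, t_nodes, var)
    S = np.exp(-Lam)
    n_at_risk = np.array([int(np.sum((e <= t) & (T >= t))) for t in grid])
    return NetSurvivalCurve(
        group=records[0].group if records else "",
        grid=grid,
        estimate=S,
        variance=S**2 * V,
        n_at_risk=n_at_risk,
    )


def _partition(e, T, breaks, grid, t_max, step):
    """Cut points for the population-hazard integral (see module docstring)."""
    pts = {0.0, float(t_max)}
    for arr in (e, T, grid):
        for v in np.asarray(arr, dtype=float).ravel():
            if 0.0 < v < t_max:
                pts.add(float(v))
    for v in breaks:
        if 0.0 < v < t_max:
            pts.add(float(v))
    base = np.array(sorted(pts))
    out = [np.array([0.0])]
    for u0, u1 in zip(base[:-1], base[1:]):
        k = max(1, int(np.ceil((u1 - u0) / step - 1e-12)))
        out.append(np.linspace(u0, u1, k + 1)[1:])
    return np.concatenate(out)


def _pp_exact(a0, y0, e, T, died, life_table, grid, step):
    n = a0.size
    t_max = float(grid.max())
    # exact per-subject cumulative population hazard (piecewise linear)
    bp_times, bp_H, all_breaks = [], [], set()
    for i in range(n):
        ti, Hi = life_table.cumhaz_breakpoints(a0[i], y0[i], max(T[i], 1e-12), clip_age=True)
        bp_times.append(ti)
        bp_H.append(Hi)
        all_breaks.update(ti[1:-1].tolist())
    part = _partition(e, T, all_breaks, grid, t_max, step)
    mids = 0.5 * (part[:-1] + part[1:])
    widths = np.diff(part)
    # H_i evaluated at subinterval midpoints and at event times
    deaths = np.unique(T[died & (T <= t_max)])
    H_mid = np.empty((n, mids.size))
    lam_mid = np.empty((n, mids.size))
    w_at_death = np.empty((n, deaths.size))
    for i in range(n):
        H_mid[i] = np.interp(mids, bp_times[i], bp_H[i])
        lam_mid[i] = [
            life_table.hazard_at(a0[i], y0[i], m, clip_age=True) if m <= T[i] else 0.0
            for m in mids
        ]
        if deaths.size:
            w_at_death[i] = np.exp(np.interp(deaths, bp_times[i], bp_H[i]))
    w_mid = np.exp(H_mid)
    # risk set constant on each open subinterval (partition contains e, T)
    at_risk_mid = (e[:, None] <= part[None, :-1] + 1e-12) & (T[:, None] >= part[None, 1:] - 1e-12)
    denom = np.sum(np.where(at_risk_mid, w_mid, 0.0), axis=0)
    numer = np.sum(np.where(at_risk_mid, w_mid * lam_mid, 0.0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, numer / denom, 0.0)
    pop_cum = np.concatenate([[0.0], np.cumsum(ratio * widths)])
    # event terms at exact death times
    dLam = np.zeros(deaths.size)
    dVar = np.zeros(deaths.size)
    for k, tk in enumerate(deaths):
        at_risk = (e < tk) & (T >= tk)
        den = np.sum(w_at_death[at_risk, k])
        dying = died & (T == tk)
        dLam[k] = np.sum(w_at_death[dying, k]) / den
        dVar[k] = np.sum(w_at_death[dying, k] ** 2) / den**2
    lam_E = np.concatenate([[0.0], np.cumsum(dLam)])
    var = np.concatenate([[0.0], np.cumsum(dVar)])
    # express both cumulatives on a common node axis; the event terms are
    # right-continuous step functions (jump at each death time)
    nodes = np.unique(np.concatenate([part, deaths]))
    k = np.searchsorted(deaths, nodes, side="right")
    ev_cum = lam_E[k]
    var_cum = var[k]
    pop_sorted = np.interp(nodes, part, pop_cum)
    return ev_cum, var_cum, pop_sorted, nodes


def _pp_binned(a0, y0, e, T, died, life_table, grid, step):
    n = a0.size
    t_max = float(grid.max())
    edges = np.union1d(np.asarray(grid, dtype=float), np.arange(0.0, t_max + step, step))
    edges = edges[edges <= t_max + 1e-12]
    if edges[-1] < t_max:
        edges = np.append(edges, t_max)
    mids = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    nb = mids.size
    age_idx = np.minimum(np.floor(a0[:, None] + mids[None, :]).astype(int), life_table.n_ages - 1)
    year_idx = np.floor(y0[:, None] + mids[None, :]).astype(int) - life_table.year_start
    at_risk = (e[:, None] < mids[None, :]) & (T[:, None] >= mids[None, :])
    bad = at_risk & ((year_idx < 0) | (year_idx >= life_table.n_years))
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"life table {life_table.country}/{life_table.sex} has no cell for "
            f"year={int(np.floor(y0[i] + mids[j]))}, age={int(age_idx[i, j])}"
        )
    np.clip(year_idx, 0, life_table.n_years - 1, out=year_idx)
    lam = life_table.hazards[year_idx, age_idx]
    # midpoint-rule cumulative hazard: H at bin k's midpoint
    H_edge = np.cumsum(lam * widths[None, :], axis=1)
    H_mid = H_edge - 0.5 * lam * widths[None, :]
    w = np.exp(H_mid)
    denom = np.sum(np.where(at_risk, w, 0.0), axis=0)
    numer = np.sum(np.where(at_risk, w * lam, 0.0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, numer / denom, 0.0)
    pop_cum = np.concatenate([[0.0], np.cumsum(ratio * widths)])
    # deaths aggregated per bin, weights taken at the bin midpoint
    ev = np.zeros(nb)
    va = np.zeros(nb)
    is_death = died & (T <= t_max) & (T > 0)
    if np.any(is_death):
        bins = np.clip(np.searchsorted(edges, T[is_death], side="right") - 1, 0, nb - 1)
        rows = np.nonzero(is_death)[0]
        wd = w[rows, bins]
        good = denom[bins] > 0
        np.add.at(ev, bins[good], wd[good] / denom[bins[good]])
        np.add.at(va, bins[good], wd[good] ** 2 / denom[bins[good]] ** 2)
    lam_E = np.concatenate([[0.0], np.cumsum(ev)])
    var = np.concatenate([[0.0], np.cumsum(va)])
    return lam_E, var, pop_cum, edges


def age_standardize(
    curves: Mapping[tuple[float, float], NetSurvivalCurve],
    weights: StandardWeights,
) -> NetSurvivalCurve:
    """Externally weighted average of per-age-band net-survival curves.

    Weight bands without a matching curve (empty bands in small cohorts)
    are dropped and the remaining weights renormalized, with a warning.
    Variance combines as ``Σ w² var``.
    """
    present = [(band, w) for band, w in weights.rows if band in curves]
    if not present:
        raise ValueError("no weight band has a matching curve")
    dropped = [band for band, _ in weights.rows if band not in curves]
    if dropped:
        logger.warning("age_standardize: dropping empty bands %s and renormalizing", dropped)
    wsum = sum(w for _, w in present)
    grid = None
    est = var = nrisk = None
    for band, w in present:
        c = curves[band]
        if grid is None:
            grid = c.grid
            est = np.zeros_like(grid)
            var = np.zeros_like(grid)
            nrisk = np.zeros_like(grid)
        elif not np.array_equal(c.grid, grid):
            raise ValueError("band curves must share a common time grid")
        wn = w / wsum
        est = est + wn * c.estimate
        var = var + wn**2 * c.variance
        nrisk = nrisk + c.n_at_risk
    return NetSurvivalCurve(
        group=next(iter(curves.values())).group,
        grid=grid,
        estimate=est,
        variance=var,
        n_at_risk=nrisk,
    )


def _ci_from_curve(S: float, var: float) -> tuple[float, float]:
    """95% CI on the log-cumulative-excess-hazard scale when defined.

    Net survival above 1 has a negative cumulative excess hazard, where
    the log transform is undefined; fall back to a plain Wald interval.
    """
    se = float(np.sqrt(var))
    if se == 0.0:
        return (S, S)
    Lam = -np.log(S) if S > 0 else np.inf
    if 0 < S < 1 and Lam > 1e-12:
        se_loglam = se / (S * Lam)
        lo = float(np.exp(-Lam * np.exp(Z_95 * se_loglam)))
        hi = float(np.exp(-Lam * np.exp(-Z_95 * se_loglam)))
        return (lo, hi)
    return (S - Z_95 * se, S + Z_95 * se)


def period_window_estimate(
    records: Sequence[IndividualRecord],
    life_table: LifeTable,
    window: tuple[int, int],
    design: str = "cohort",
    *,
    weights: StandardWeights | None = None,
    site: str = "colon",
    study_end: float | None = None,
    horizon_max: float = 5.0,
    step: float = 0.05,
    method: str = "auto",
) -> tuple[SurvivalPoint, SurvivalPoint]:
    """Age-standardized 1- and 5-year net survival for one calendar window.

    Cohort design: patients diagnosed inside the window, full follow-up.
    Hybrid design: window diagnoses contribute as in the cohort design;
    when some window diagnosis years lack complete potential 5-year
    follow-up by ``study_end``, diagnoses from the ``horizon_max`` years
    before the window are added with delayed entry at the window start,
    so their in-window person-time informs the later follow-up years that
    the recent cohorts cannot reach.  When every window diagnosis year has
    complete potential follow-up, the hybrid design reduces exactly to the
    cohort design.
    """
    if design not in ("cohort", "hybrid"):
        raise ValueError(f"design must be 'cohort' or 'hybrid', got {design!r}")
    if weights is None:
        weights = default_survival_weights()
    start, end = window
    if study_end is None:
        study_end = float(end + 1)
    in_window = [r for r in records if start <= r.dx_year < end + 1]
    sel = list(in_window)
    entries = [0.0] * len(in_window)
    if design == "hybrid":
        # any window diagnosis year without complete potential follow-up?
        incomplete = any(r.dx_year + horizon_max > study_end for r in in_window)
        if incomplete:
            for r in records:
                if start - horizon_max <= r.dx_year < start:
                    e = start - r.dx_year
                    if r.follow_up > e:  # alive at the window start
                        sel.append(r)
                        entries.append(e)
    if not sel:
        raise ValueError(f"no eligible records for window {start}-{end} ({design} design)")
    grid = np.arange(0.0, horizon_max + 0.5, 1.0)
    # split into the external-weight age bands and standardize
    curves: dict[tuple[float, float], NetSurvivalCurve] = {}
    for band in weights.bands:
        lo, hi = band
        idx = [i for i, r in enumerate(sel) if lo <= r.age_at_dx < hi]
        if not idx:
            continue
        curves[band] = pohar_perme(
            [sel[i] for i in idx],
            life_table,
            grid,
            entry=[entries[i] for i in idx],
            step=step,
            method=method,
        )
    std = age_standardize(curves, weights)
    points = []
    for t, hz in ((1.0, "1y"), (horizon_max, "5y")):
        S, var = std.at(t)
        lo, hi = _ci_from_curve(S, var)
        points.append(
            SurvivalPoint(
                group=sel[0].group,
                site=site,
                period=(int(start), int(end)),
                horizon=hz,
                estimate=100.0 * S,
                se=100.0 * float(np.sqrt(var)),
                ci=(100.0 * min(lo, S), 100.0 * max(hi, S)),
                design=design,
            )
        )
    return points[0], points[1]


def load_standard_weights(path) -> StandardWeights:
    """Read an age-standardization weight table from CSV.

    Columns: ``age_lo, age_hi, weight``; weights are normalized to sum
    to 1.
    """
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"age_lo", "age_hi", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    w = df["weight"].to_numpy(dtype=float)
    w = w / w.sum()
    rows = [
        ((float(lo), float(hi)), float(wi))
        for lo, hi, wi in zip(df["age_lo"], df["age_hi"], w)
    ]
    return StandardWeights(rows=rows, label=str(getattr(path, "stem", path)))


def default_survival_weights() -> StandardWeights:
    """Bundled 5-band external survival-standardization weights.

    A replaceable data asset (``data/survival_weights.csv``); override
    with :func:`load_standard_weights` for a different standard.
    """
    ref = resources.files("survtrend.data").joinpath("survival_weights.csv")
    with resources.as_file(ref) as p:
        sw = load_standard_weights(p)
    sw.label = "external-5band"
    return sw
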