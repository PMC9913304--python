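"""Headline quantities derived from posterior survival curves.

All derivative-based rules operate on the posterior distribution of the
derivative: derivatives are computed per posterior draw via the analytic
basis derivatives (never by differentiating the posterior mean) and then
summarized pointwise.

Rules (95% credible level throughout):

* plausible-trend interval — a maximal sign-constant run of grid points
  where the first-derivative CI excludes zero, spanning >= 5 calendar
  years (run length = last grid year - first grid year, boundary points
  counting);
* breaking point — within a >= 3-year run where the second-derivative CI
  excludes zero, the grid year maximizing |posterior median second
  derivative|; direction "upward" for positive median curvature.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trend import PosteriorCurveSet

logger = logging.getLogger(__name__)

__all__ = [
    "Breakpoint",
    "TrendFeatures",
    "conditional_ratio",
    "annual_change",
    "plausible_intervals",
    "detect_breakpoints",
    "extract_features",
]

MIN_TREND_YEARS = 5.0
MIN_BREAK_YEARS = 3.0


@dataclass
class Breakpoint:
    year: float
    direction: str  # "upward" | "downward"
    interval: tuple[float, float]


@dataclass
class TrendFeatures:
    metric: str
    group: str
    plausible_intervals: list[tuple[float, float]]
    breakpoints: list[Breakpoint]
    annual_change: pd.DataFrame  # columns: year, median, lo, hi
    provenance: dict = field(default_factory=dict)


def conditional_ratio(
    five_year: PosteriorCurveSet, one_year: PosteriorCurveSet
) -> PosteriorCurveSet:
    """Posterior 5/1-year conditional survival: per-draw ratio of paired
    5-year and 1-year draws, ``100 * S5 / S1`` (percent).

    Draws are paired by index across the two independently fitted models.
    Draws whose 1-year curve is <= 0 anywhere on the grid cannot form a
    ratio; they are dropped (from both sets) with a logged count.
    Derivative draws follow by the quotient rule, so downstream trend
    rules see analytic derivatives of the ratio itself.
    """
    if five_year.grid.shape != one_year.grid.shape or not np.allclose(
        five_year.grid, one_year.grid
    ):
        raise ValueError("five-year and one-year grids do not match")
    if five_year.groups != one_year.groups:
        raise ValueError("five-year and one-year group sets do not match")
    if five_year.n_draws != one_year.n_draws:
        raise ValueError("draw counts differ; draws must be paired by index")
    draws: dict[str, np.ndarray] = {}
    d1: dict[str, np.ndarray] = {}
    d2: dict[str, np.ndarray] = {}
    n_excluded = 0
    for g in five_year.groups:
        S5, S1 = five_year.draws[g], one_year.draws[g]
        D5a, D1a = five_year.deriv1[g], one_year.deriv1[g]
        D5b, D1b = five_year.deriv2[g], one_year.deriv2[g]
        ok = np.all(S1 > 0, axis=1)
        n_excluded += int(np.sum(~ok))
        S5, S1 = S5[ok], S1[ok]
        D5a, D1a, D5b, D1b = D5a[ok], D1a[ok], D5b[ok], D1b[ok]
        if S5.shape[0] == 0:
            raise ValueError(f"group {g}: all draws excluded (non-positive 1-year curves)")
        R = 100.0 * S5 / S1
        dR = 100.0 * (D5a / S1 - S5 * D1a / S1**2)
        d2R = 100.0 * (
            D5b / S1
            - 2.0 * D5a * D1a / S1**2
            - S5 * D1b / S1**2
            + 2.0 * S5 * D1a**2 / S1**3
        )
        draws[g], d1[g], d2[g] = R, dR, d2R
    if n_excluded:
        logger.warning("conditional_ratio: excluded %d draws with non-positive 1-year curves", n_excluded)
    return PosteriorCurveSet(
        metric="5/1y",
        grid=five_year.grid.copy(),
        draws=draws,
        deriv1=d1,
        deriv2=d2,
        provenance={
            "five_year": five_year.provenance,
            "one_year": one_year.provenance,
            "pairing": "by draw index (induces independence between models)",
            "excluded_draws": n_excluded,
        },
        diagnostics={
            "rhat_max": max(
                five_year.diagnostics.get("rhat_max", 1.0),
                one_year.diagnostics.get("rhat_max", 1.0),
            ),
            "ess_min": min(
                five_year.diagnostics.get("ess_min", np.inf),
                one_year.diagnostics.get("ess_min", np.inf),
            ),
            "converged": five_year.diagnostics.get("converged", True)
            and one_year.diagnostics.get("converged", True),
        },
    )


def _summaries(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    med = np.median(mat, axis=0)
    lo = np.percentile(mat, 2.5, axis=0)
    hi = np.percentile(mat, 97.5, axis=0)
    return med, lo, hi


def annual_change(curves: PosteriorCurveSet) -> dict[str, pd.DataFrame]:
    """Pointwise posterior summary (median, 95% CI) of the first
    derivative, percent units per calendar year."""
    if np.any(np.diff(curves.grid) > 1.0 + 1e-12):
        raise ValueError("grid spacing exceeds 1 year; derivative rules need a finer grid")
    out: dict[str, pd.DataFrame] = {}
    for g in curves.groups:
        med, lo, hi = _summaries(curves.deriv1[g])
        out[g] = pd.DataFrame({"year": curves.grid, "median": med, "lo": lo, "hi": hi})
    return out


def _sign_runs(lo: np.ndarray, hi: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal (start_idx, end_idx, sign) runs where the CI excludes 0,
    split at sign changes."""
    sign = np.where(lo > 0, 1, np.where(hi < 0, -1, 0))
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = sign.size
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i]:
            j += 1
        runs.append((i, j, int(sign[i])))
        i = j + 1
    return runs


def plausible_intervals(curves: PosteriorCurveSet) -> dict[str, list[tuple[float, float]]]:
    """Calendar spans where the trend is credibly changing.

    Maximal sign-constant runs where the 95% CI of the first derivative
    excludes zero, kept iff they span at least 5 years.
    """
    if np.any(np.diff(curves.grid) > 0.25 + 1e-12):
        raise ValueError("plausible-interval rule requires grid spacing <= 0.25 year")
    out: dict[str, list[tuple[float, float]]] = {}
    for g in curves.groups:
        _, lo, hi = _summaries(curves.deriv1[g])
        spans = []
        for i, j, _sign in _sign_runs(lo, hi):
            if curves.grid[j] - curves.grid[i] >= MIN_TREND_YEARS:
                spans.append((float(curves.grid[i]), float(curves.grid[j])))
        out[g] = spans
    return out


def detect_breakpoints(curves: PosteriorCurveSet) -> dict[str, list[Breakpoint]]:
    """Times when the annual change itself credibly changes.

    Within each >= 3-year sign-constant run where the 95% CI of the second
    derivative excludes zero, report the grid year with maximal
    |posterior median second derivative|.
    """
    out: dict[str, list[Breakpoint]] = {}
    for g in curves.groups:
        med, lo, hi = _summaries(curves.deriv2[g])
        bps = []
        for i, j, sign in _sign_runs(lo, hi):
            if curves.grid[j] - curves.grid[i] < MIN_BREAK_YEARS:
                continue
            k = i + int(np.argmax(np.abs(med[i : j + 1])))
            bps.append(
                Breakpoint(
                    year=float(curves.grid[k]),
                    direction="upward" if sign > 0 else "downward",
                    interval=(float(curves.grid[i]), float(curves.grid[j])),
                )
            )
        out[g] = sorted(bps, key=lambda b: b.year)
    return out


def extract_features(curves: PosteriorCurveSet) -> list[TrendFeatures]:
    """Bundle all derived quantities per group."""
    ac = annual_change(curves)
    pi = plausible_intervals(curves)
    bp = detect_breakpoints(curves)
    return [
        TrendFeatures(
            metric=curves.metric,
            group=g,
            plausible_intervals=pi[g],
            breakpoints=bp[g],
            annual_change=ac[g],
            provenance=dict(curves.provenance),
        )
        for g in curves.groups
    ]
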