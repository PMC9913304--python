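"""Age-standardized rates, cumulative risks and display smoothing."""
from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
from scipy.interpolate import BSpline

from .datatypes import AgeRateTable, StandardWeights

__all__ = [
    "asr",
    "cumulative_risk",
    "smooth_series",
    "world_standard_weights",
    "crude_rate",
]


def world_standard_weights() -> StandardWeights:
    """Bundled world-standard-population weights (replaceable data asset)."""
    from .netsurv import load_standard_weights

    ref = resources.files("survtrend.data").joinpath("world_standard.csv")
    with resources.as_file(ref) as p:
        sw = load_standard_weights(p)
    sw.label = "world-standard"
    return sw


def crude_rate(table: AgeRateTable) -> float:
    """All-ages rate per 100,000 person-years."""
    cases = sum(c for _, c, _ in table.rows)
    py = sum(p for _, _, p in table.rows)
    return 1e5 * cases / py


def asr(table: AgeRateTable, weights: StandardWeights) -> float:
    """Age-standardized rate per 100,000 person-years.

    ``Σ_a w_a * (cases_a / person_years_a) * 100,000`` with the weights
    renormalized over the bands actually present in the table.  Every
    table band must have a matching weight band.
    """
    wmap = {band: w for band, w in weights.rows}
    total_w = 0.0
    acc = 0.0
    for band, cases, py in table.rows:
        if band not in wmap:
            raise ValueError(f"no standard weight for age band {band}")
        if py <= 0:
            if cases > 0:
                raise ValueError(f"band {band} has cases but zero person-years")
            continue
        total_w += wmap[band]
        acc += wmap[band] * (cases / py)
    if total_w == 0:
        raise ValueError("no weighted bands contribute to the ASR")
    return 1e5 * acc / total_w


def cumulative_risk(table: AgeRateTable, upper_age: float = 75.0) -> float:
    """Cumulative risk (percent) of the event before ``upper_age``.

    ``100 * (1 - exp(-Σ_a width_a * rate_a))`` over the bands fully below
    ``upper_age``; the bands must tile [0, upper_age) without gaps.
    """
    rows = sorted(
        (r for r in table.rows if r[0][1] <= upper_age), key=lambda r: r[0][0]
    )
    expected_lo = 0.0
    missing = []
    for (lo, hi), _, _ in rows:
        if lo > expected_lo + 1e-9:
            missing.append((expected_lo, lo))
        expected_lo = max(expected_lo, hi)
    if expected_lo < upper_age - 1e-9:
        missing.append((expected_lo, upper_age))
    if missing:
        raise ValueError(f"age bands missing below {upper_age}: {missing}")
    total = sum((hi - lo) * cases / py for (lo, hi), cases, py in rows)
    return 100.0 * (1.0 - np.exp(-total))


def _spar_to_lambda(B: np.ndarray, Omega: np.ndarray, spar: float) -> float:
    # smoothing-parameter convention of classical smoothing-spline software:
    # lambda = ratio * 256**(3*spar - 1), ratio balancing the fit and
    # penalty matrices' traces.  Visualization-only mapping; no numeric
    # equivalence to any particular smoother is promised.
    r = np.trace(B.T @ B) / max(np.trace(Omega), 1e-300)
    return float(r * 256.0 ** (3.0 * spar - 1.0))


def smooth_series(
    years,
    values,
    spar: float = 0.4,
    knots: int = 15,
    n_out: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic penalized-spline smoother for plotting rate series.

    Returns ``(grid, smoothed)`` on a fine grid over the data range.  With
    fewer than 4 distinct years the input is returned unchanged with a
    warning.  Visualization only; never feeds inference.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(x).size < 4:
        warnings.warn("smooth_series: fewer than 4 distinct years; returning input unchanged")
        return x.copy(), y.copy()
    order = np.argsort(x)
    x, y = x[order], y[order]
    ux = np.unique(x)
    k = int(min(knots, ux.size))
    interior = np.quantile(ux, np.linspace(0, 1, k)[1:-1])
    t = np.concatenate([[ux[0]] * 4, np.unique(interior), [ux[-1]] * 4])
    nb = len(t) - 4
    eye = np.eye(nb)
    spl = BSpline(t, eye, 3)
    B = spl(x)
    # penalty: Gram matrix of second derivatives (piecewise linear, so
    # 2-point Gauss-Legendre per knot interval is exact)
    d2 = spl.derivative(2)
    Omega = np.zeros((nb, nb))
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for a, b in zip(t[3:-4], t[4:-3]):
        if b <= a:
            continue
        h = 0.5 * (b - a)
        for gx in gl_x:
            pt = 0.5 * (a + b) + h * gx
            v = d2(pt)
            Omega += h * np.outer(v, v)
    lam = _spar_to_lambda(B, Omega, spar)
    A = B.T @ B + lam * Omega + 1e-10 * np.eye(nb)
    coef = np.linalg.solve(A, B.T @ y)
    grid = np.linspace(ux[0], ux[-1], n_out)
    fitted = BSpline(t, coef, 3)(grid)
    return grid, fitted
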