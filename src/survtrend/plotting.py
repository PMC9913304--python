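"""Figure panels: survival curves with plausible-trend segments drawn
solid, vertical breakpoint lines and an annual-change strip below."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .features import detect_breakpoints, plausible_intervals
from .trend import PosteriorCurveSet

__all__ = ["metric_panel", "site_sex_figure"]

_COLORS = plt.rcParams["axes.prop_cycle"].by_key()["color"]


def _solid_dashed(ax, x, y, spans, color, lw=1.8):
    """Draw y(x) dashed, overdrawing solid inside the plausible spans."""
    ax.plot(x, y, ls="--", lw=lw * 0.7, color=color, alpha=0.8)
    for s, e in spans:
        m = (x >= s) & (x <= e)
        ax.plot(x[m], y[m], ls="-", lw=lw, color=color)


def metric_panel(
    axes: tuple,
    curves: PosteriorCurveSet,
    groups: list[str],
    points=None,
) -> None:
    """One metric column: survival curve on top, annual change below."""
    ax_top, ax_bot = axes
    spans_all = plausible_intervals(curves)
    bps_all = detect_breakpoints(curves)
    for gi, g in enumerate(groups):
        color = _COLORS[gi % len(_COLORS)]
        med = np.median(curves.draws[g], axis=0)
        lo, hi = curves.quantile_band(g)
        ax_top.fill_between(curves.grid, lo, hi, color=color, alpha=0.15, lw=0)
        _solid_dashed(ax_top, curves.grid, med, spans_all[g], color)
        for bp in bps_all[g]:
            ax_top.axvline(bp.year, color=color, lw=0.8, alpha=0.6)
        d_med = np.median(curves.deriv1[g], axis=0)
        d_lo = np.percentile(curves.deriv1[g], 2.5, axis=0)
        d_hi = np.percentile(curves.deriv1[g], 97.5, axis=0)
        ax_bot.fill_between(curves.grid, d_lo, d_hi, color=color, alpha=0.15, lw=0)
        _solid_dashed(ax_bot, curves.grid, d_med, spans_all[g], color, lw=1.2)
        if points:
            sub = [p for p in points if p.group == g]
            if sub:
                ax_top.errorbar(
                    [p.midyear for p in sub],
                    [p.estimate for p in sub],
                    yerr=[1.96 * p.se for p in sub],
                    fmt="o", ms=3, color=color, alpha=0.6, lw=0.8,
                )
    ax_bot.axhline(0.0, color="k", lw=0.6)
    ax_top.set_ylabel("survival (%)")
    ax_bot.set_ylabel("annual change\n(%/year)")
    ax_bot.set_xlabel("calendar year")
    ax_top.set_title(curves.metric)


def site_sex_figure(curvesets: dict, sex: str, points, site: str):
    """Per-site, per-sex figure: one column per metric, countries as
    color-coded lines."""
    metrics = [m for m in ("1y", "5/1y", "5y") if m in curvesets]
    fig, axes = plt.subplots(
        2, len(metrics), figsize=(4.2 * len(metrics), 5.5),
        sharex=True, height_ratios=[2.5, 1], squeeze=False,
    )
    for k, m in enumerate(metrics):
        curves = curvesets[m]
        groups = [g for g in curves.groups if g.endswith(f"_{sex}")]
        pts = [
            p for p in points
            if p.site == site and p.horizon == m and p.group.endswith(f"_{sex}")
        ]
        metric_panel((axes[0][k], axes[1][k]), curves, groups, pts)
    fig.suptitle(f"{site} — {sex}")
    fig.tight_layout()
    return fig
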