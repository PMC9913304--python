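"""End-to-end pipeline: simulate -> estimate -> trend -> features -> report.

Each stage reads and writes plain files in the run's output directory, so
the CLI subcommands compose: running the stages one by one is identical
to running the whole pipeline.  Every artifact embeds the run config hash
and seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as sio
from .datatypes import SurvivalPoint, TrueTrend
from .features import extract_features
from .netsurv import period_window_estimate
from .synthetic import (
    default_periods,
    make_life_table,
    make_rate_table,
    simulate_cohort,
    simulate_survival_points,
)
from .trend import TrendModelSpec, fit_trend
from .features import conditional_ratio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "default_demo_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "estimate", "trend", "features", "report")


@dataclass
class RunConfig:
    """Serializable run configuration; ``hash`` keys every artifact."""

    data: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    @property
    def hash(self) -> str:
        # purely locational fields are excluded: the same analysis run
        # into a different directory is the same run
        data = {k: v for k, v in self.data.items() if k != "outdir"}
        canon = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @property
    def seed(self) -> int:
        return int(self.data.get("seed", 0))

    def get(self, *keys, default=None):
        node = self.data
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node


def default_demo_config(seed: int = 1, outdir: str = "out") -> RunConfig:
    """Small self-contained demo: 2 countries x 2 sexes, 3 sites."""
    sites = {
        "colon": {
            "1y": {"family": "logistic", "lower": 0.55, "upper": 0.90, "mid_year": 1995, "rate": 0.08},
            "5y": {"family": "logistic", "lower": 0.30, "upper": 0.70, "mid_year": 1998, "rate": 0.08},
        },
        "rectum": {
            "1y": {"family": "linear", "year0": 1971, "value0": 0.60, "slope_per_year": 0.005},
            "5y": {"family": "piecewise-linear", "year0": 1971, "value0": 0.30,
                   "slope_before": 0.002, "slope_after": 0.008, "changepoint": 1995},
        },
        "small_intestine": {
            "1y": {"family": "constant", "level": 0.70},
            "5y": {"family": "linear", "year0": 1971, "value0": 0.35, "slope_per_year": 0.004},
        },
    }
    return RunConfig(
        {
            "seed": seed,
            "outdir": outdir,
            "countries": ["norland", "sudland"],
            "sexes": ["male", "female"],
            "periods": {"n": 10, "start": 1971},
            "sites": sites,
            "group_offsets": {"norland_male": 0.0, "norland_female": 0.02,
                              "sudland_male": -0.03, "sudland_female": -0.01},
            "simulate": {"mode": "points", "se_level": 1.0, "n_per_period": 1500},
            "life_table": {"a": 0.0004, "b": 2.0e-5, "c": 0.095, "improvement": 0.995},
            "model": {"method": "exact", "draws": 1500},
        }
    )


def _truth_from_config(group: str, horizon: str, params: dict, offset: float) -> TrueTrend:
    fam = params["family"]
    p = {k: v for k, v in params.items() if k != "family"}
    if fam == "constant":
        base = TrueTrend.constant(group, horizon, **p)
    elif fam == "linear":
        base = TrueTrend.linear(group, horizon, **p)
    elif fam == "logistic":
        base = TrueTrend.logistic(group, horizon, **p)
    elif fam == "piecewise-linear":
        base = TrueTrend.piecewise_linear(group, horizon, **p)
    else:
        raise ValueError(f"unknown truth family {fam!r}")
    if offset == 0.0:
        return base
    inner = base.curve
    return TrueTrend(
        group, horizon, lambda y: min(max(inner(y) + offset, 1e-6), 1.0),
        base.family, {**base.parameters, "offset": offset},
    )


def _groups(config: RunConfig) -> list[str]:
    return sorted(
        f"{c}_{s}" for c in config.get("countries") for s in config.get("sexes")
    )


def _periods(config: RunConfig) -> list[tuple[int, int]]:
    return default_periods(
        int(config.get("periods", "n", default=10)),
        int(config.get("periods", "start", default=1971)),
    )


def _model_spec(config: RunConfig, seed_offset: int) -> TrendModelSpec:
    overrides = config.get("model", default={}) or {}
    spec = TrendModelSpec(seed=config.seed + seed_offset)
    for k, v in overrides.items():
        if not hasattr(spec, k):
            raise ValueError(f"unknown model option {k!r}")
        setattr(spec, k, v)
    spec.seed = config.seed + seed_offset
    return spec


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.hash, "seed": config.seed}


# -- stages ----------------------------------------------------------------
def stage_simulate(config: RunConfig, outdir: Path) -> None:
    periods = _periods(config)
    groups = _groups(config)
    offsets = config.get("group_offsets", default={}) or {}
    mode = config.get("simulate", "mode", default="points")
    all_points: list[SurvivalPoint] = []
    lt = make_life_table(
        "pooled",
        "all",
        range(periods[0][0] - 1, periods[-1][1] + 3),
        (
            config.get("life_table", "a", default=4e-4),
            config.get("life_table", "b", default=2e-5),
            config.get("life_table", "c", default=0.095),
        ),
        annual_improvement=config.get("life_table", "improvement", default=1.0),
    )
    sio.write_life_table(lt, outdir / "life_table.csv")
    for si, (site, horizons) in enumerate(sorted(config.get("sites").items())):
        if mode == "points":
            for hi, (horizon, params) in enumerate(sorted(horizons.items())):
                truths = {
                    g: _truth_from_config(g, horizon, params, float(offsets.get(g, 0.0)))
                    for g in groups
                }
                all_points.extend(
                    simulate_survival_points(
                        truths,
                        se_level=config.get("simulate", "se_level", default=1.0),
                        periods=periods,
                        seed=config.seed + 101 * si + 11 * hi,
                        site=site,
                        horizon=horizon,
                    )
                )
        elif mode == "records":
            truths5 = {
                g: _truth_from_config(g, "5y", horizons["5y"], float(offsets.get(g, 0.0)))
                for g in groups
            }
            records = simulate_cohort(
                truths5,
                lt,
                int(config.get("simulate", "n_per_period", default=1500)),
                periods,
                seed=config.seed + 101 * si,
            )
            sio.write_records(records, outdir / f"records_{site}.csv")
        else:
            raise ValueError(f"unknown simulate mode {mode!r}")
    if mode == "points":
        sio.write_survival_points(all_points, outdir / "survival_points.csv")
    # small demo rate tables for the descriptive stage
    tables = [
        make_rate_table(g, y, rate_per_100k=30.0 + 0.3 * (y - periods[0][0]), seed=config.seed + y)
        for g in groups
        for y in range(periods[0][0], periods[-1][1] + 1, 5)
    ]
    sio.write_rate_tables(tables, outdir / "rate_tables.csv")


def stage_estimate(config: RunConfig, outdir: Path) -> None:
    periods = _periods(config)
    lts = sio.read_life_table(outdir / "life_table.csv")
    lt = lts[0]
    study_end = float(periods[-1][1] + 1)
    all_points: list[SurvivalPoint] = []
    for site in sorted(config.get("sites")):
        rec_path = outdir / f"records_{site}.csv"
        if not rec_path.exists():
            continue
        records = sio.read_records(rec_path)
        by_group: dict[str, list] = {}
        for r in records:
            by_group.setdefault(r.group, []).append(r)
        for g in sorted(by_group):
            for start, end in periods:
                design = "hybrid" if end + 1 >= study_end else "cohort"
                p1, p5 = period_window_estimate(
                    by_group[g], lt, (start, end), design,
                    site=site, study_end=study_end, method="binned", step=0.02,
                )
                all_points.extend([p1, p5])
    if not all_points:
        raise ValueError("estimate stage found no record files to process")
    sio.write_survival_points(all_points, outdir / "survival_points.csv")


def stage_trend(config: RunConfig, outdir: Path) -> None:
    points = sio.read_nordcan_export(outdir / "survival_points.csv")
    if not points:
        raise ValueError("trend stage: no survival points found")
    sites = sorted({p.site for p in points})
    for si, site in enumerate(sites):
        fits = {}
        for hi, horizon in enumerate(("1y", "5y")):
            sub = [p for p in points if p.site == site and p.horizon == horizon]
            if not sub:
                continue
            spec = _model_spec(config, 1000 * si + 100 * hi)
            fits[horizon] = fit_trend(sub, spec, metric=horizon)
            sio.save_curveset(fits[horizon], outdir / f"curves_{site}_{horizon.replace('/', '')}.npz")
        if "1y" in fits and "5y" in fits:
            ratio = conditional_ratio(fits["5y"], fits["1y"])
            sio.save_curveset(ratio, outdir / f"curves_{site}_5over1.npz")


def stage_features(config: RunConfig, outdir: Path) -> None:
    found = False
    for path in sorted(outdir.glob("curves_*.npz")):
        curves = sio.load_curveset(path)
        feats = extract_features(curves)
        for f in feats:
            f.provenance.update(_stamp(config))
        stem = path.stem.replace("curves_", "")
        sio.write_features(feats, outdir / f"features_{stem}.json", extra=_stamp(config))
        sio.write_derivative_summaries(feats, outdir / f"annual_change_{stem}.csv")
        found = True
    if not found:
        raise ValueError("features stage: no fitted curve sets found")


def stage_report(config: RunConfig, outdir: Path) -> None:
    from .plotting import site_sex_figure

    points = sio.read_nordcan_export(outdir / "survival_points.csv")
    sites = sorted({p.site for p in points})
    sexes = config.get("sexes") or sorted({p.group.rpartition("_")[2] for p in points})
    n_panels = 0
    for site in sites:
        curve_paths = {
            "1y": outdir / f"curves_{site}_1y.npz",
            "5/1y": outdir / f"curves_{site}_5over1.npz",
            "5y": outdir / f"curves_{site}_5y.npz",
        }
        curvesets = {
            m: sio.load_curveset(p) for m, p in curve_paths.items() if p.exists()
        }
        if not curvesets:
            raise ValueError(f"report stage: no curves for site {site}")
        for sex in sexes:
            fig = site_sex_figure(curvesets, sex, points, site)
            fig.savefig(outdir / f"panel_{site}_{sex}.png", dpi=120)
            fig.savefig(outdir / f"panel_{site}_{sex}.svg")
            import matplotlib.pyplot as plt

            plt.close(fig)
            n_panels += 1
    logger.info("report stage wrote %d panels", n_panels)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "estimate": stage_estimate,
    "trend": stage_trend,
    "features": stage_features,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> Path:
    """Run the requested stages (default: all applicable) in order.

    The estimate stage is skipped automatically in points mode, where the
    simulate stage already emits the trend-stage input.  Any stage failure
    aborts with an error naming the stage.
    """
    outdir = Path(config.get("outdir", default="out"))
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    (outdir / "run.json").write_text(json.dumps(_stamp(config), sort_keys=True))
    if stages is None:
        stages = list(STAGES)
        if config.get("simulate", "mode", default="points") == "points":
            stages.remove("estimate")
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
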