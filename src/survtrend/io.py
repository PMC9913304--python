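"""Readers and writers for the interchange formats.

All formats are plain UTF-8 CSV/JSON with headers.  Documented dialects:

* survival points (registry-export style): columns ``country, sex, site,
  period, horizon, estimate, ci_low, ci_high`` with ``period`` written as
  ``"start-end"`` (e.g. ``1971-1975``); optional ``design`` column.
* life table: ``country, sex, year, age, hazard`` (one row per cell).
* individual records: ``id, country, sex, age_dx, dx_date (ISO 8601),
  futime_years, status`` with status in ``{dead, censored}``.
* age-rate table: ``group, year, age_lo, age_hi, cases, person_years``.
"""
from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import AgeRateTable, IndividualRecord, LifeTable, SurvivalPoint
from .features import Breakpoint, TrendFeatures
from .netsurv import Z_95, se_from_ci
from .trend import PosteriorCurveSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_nordcan_export",
    "read_nordcan_export_detailed",
    "write_survival_points",
    "read_life_table",
    "write_life_table",
    "read_records",
    "write_records",
    "read_rate_tables",
    "write_rate_tables",
    "features_to_json",
    "write_features",
    "write_derivative_summaries",
    "save_curveset",
    "load_curveset",
]

_EXPORT_COLUMNS = ["country", "sex", "site", "period", "horizon", "estimate", "ci_low", "ci_high"]


def _parse_period(text: str) -> tuple[int, int]:
    start, _, end = str(text).partition("-")
    return int(start), int(end)


def read_nordcan_export_detailed(
    path, column_map: dict[str, str] | None = None
) -> tuple[list[SurvivalPoint], list[tuple[int, str]]]:
    """Read a registry-export CSV of period survival estimates.

    ``column_map`` maps nonstandard column names in the file to the
    canonical dialect (e.g. ``{"land": "country"}``).  Returns
    ``(points, rejects)`` where rejects are ``(line_number, reason)``
    pairs; rows in = points out + rejects.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _EXPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival-point file missing columns: {missing}")
    points: list[SurvivalPoint] = []
    rejects: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        lineno = int(i) + 2  # header is line 1
        try:
            ci = (float(row["ci_low"]), float(row["ci_high"]))
            se = se_from_ci(ci)
            points.append(
                SurvivalPoint(
                    group=f"{row['country']}_{row['sex']}",
                    site=str(row["site"]),
                    period=_parse_period(row["period"]),
                    horizon=str(row["horizon"]),
                    estimate=float(row["estimate"]),
                    se=se,
                    ci=ci,
                    design=str(row.get("design", "cohort")),
                )
            )
        except (ValueError, KeyError) as exc:
            rejects.append((lineno, str(exc)))
    for lineno, reason in rejects:
        logger.warning("rejected row at line %d: %s", lineno, reason)
    return points, rejects


def read_nordcan_export(path, column_map: dict[str, str] | None = None) -> list[SurvivalPoint]:
    points, _ = read_nordcan_export_detailed(path, column_map)
    return points


def write_survival_points(points: Sequence[SurvivalPoint], path) -> None:
    rows = []
    for p in points:
        country, _, sex = p.group.rpartition("_")
        ci = p.ci if p.ci is not None else (p.estimate - Z_95 * p.se, p.estimate + Z_95 * p.se)
        rows.append(
            {
                "country": country,
                "sex": sex,
                "site": p.site,
                "period": f"{p.period[0]}-{p.period[1]}",
                "horizon": p.horizon,
                "estimate": repr(p.estimate),
                "ci_low": repr(float(ci[0])),
                "ci_high": repr(float(ci[1])),
                "design": p.design,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# -- life tables -----------------------------------------------------------
def write_life_table(lt: LifeTable, path) -> None:
    years = np.repeat(np.array(list(lt.years)), lt.n_ages)
    ages = np.tile(np.arange(lt.n_ages), lt.n_years)
    pd.DataFrame(
        {
            "country": lt.country,
            "sex": lt.sex,
            "year": years,
            "age": ages,
            "hazard": lt.hazards.ravel(),
        }
    ).to_csv(path, index=False)


def read_life_table(path) -> list[LifeTable]:
    """Read one or more life tables (grouped by country and sex)."""
    df = pd.read_csv(path)
    missing = {"country", "sex", "year", "age", "hazard"} - set(df.columns)
    if missing:
        raise ValueError(f"life-table file missing columns: {sorted(missing)}")
    tables = []
    for (country, sex), sub in df.groupby(["country", "sex"], sort=True):
        y0, y1 = int(sub["year"].min()), int(sub["year"].max())
        n_ages = int(sub["age"].max()) + 1
        hz = np.zeros((y1 - y0 + 1, n_ages))
        hz[sub["year"].to_numpy() - y0, sub["age"].to_numpy()] = sub["hazard"].to_numpy()
        tables.append(LifeTable(country=str(country), sex=str(sex), year_start=y0, hazards=hz))
    return tables


# -- individual records ----------------------------------------------------
def _decimal_year_to_date(y: float) -> str:
    year = int(np.floor(y))
    days = 366 if _dt.date(year, 12, 31).timetuple().tm_yday == 366 else 365
    doy = min(int((y - year) * days), days - 1)
    return (_dt.date(year, 1, 1) + _dt.timedelta(days=doy)).isoformat()


def _date_to_decimal_year(text: str) -> float:
    d = _dt.date.fromisoformat(str(text))
    days = 366 if _dt.date(d.year, 12, 31).timetuple().tm_yday == 366 else 365
    return d.year + (d.timetuple().tm_yday - 1) / days


def write_records(records: Sequence[IndividualRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "country": [r.country for r in records],
            "sex": [r.sex for r in records],
            "age_dx": [repr(r.age_at_dx) for r in records],
            "dx_date": [_decimal_year_to_date(r.dx_year) for r in records],
            "futime_years": [repr(r.follow_up) for r in records],
            "status": ["dead" if r.status == "died" else "censored" for r in records],
        }
    ).to_csv(path, index=False)


def read_records(path) -> list[IndividualRecord]:
    df = pd.read_csv(path)
    missing = {"id", "country", "sex", "age_dx", "dx_date", "futime_years", "status"} - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            IndividualRecord(
                id=str(row["id"]),
                country=str(row["country"]),
                sex=str(row["sex"]),
                age_at_dx=float(row["age_dx"]),
                dx_year=_date_to_decimal_year(row["dx_date"]),
                follow_up=float(row["futime_years"]),
                status="died" if str(row["status"]) == "dead" else "censored",
            )
        )
    return out


# -- rate tables -----------------------------------------------------------
def write_rate_tables(tables: Sequence[AgeRateTable], path) -> None:
    rows = []
    for t in tables:
        for (lo, hi), cases, py in t.rows:
            rows.append(
                {
                    "group": t.group,
                    "year": t.year,
                    "age_lo": lo,
                    "age_hi": hi,
                    "cases": cases,
                    "person_years": py,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rate_tables(path) -> list[AgeRateTable]:
    df = pd.read_csv(path)
    missing = {"group", "year", "age_lo", "age_hi", "cases", "person_years"} - set(df.columns)
    if missing:
        raise ValueError(f"rate-table file missing columns: {sorted(missing)}")
    tables = []
    for (group, year), sub in df.groupby(["group", "year"], sort=True):
        rows = [
            ((float(r["age_lo"]), float(r["age_hi"])), int(r["cases"]), float(r["person_years"]))
            for _, r in sub.iterrows()
        ]
        tables.append(AgeRateTable(group=str(group), year=int(year), rows=rows))
    return tables


# -- features --------------------------------------------------------------
def features_to_json(features: Sequence[TrendFeatures], extra: dict | None = None) -> str:
    payload = {
        "features": [
            {
                "metric": f.metric,
                "group": f.group,
                "plausible_intervals": [[s, e] for s, e in f.plausible_intervals],
                "breakpoints": [
                    {
                        "year": b.year,
                        "direction": b.direction,
                        "interval": [b.interval[0], b.interval[1]],
                    }
                    for b in f.breakpoints
                ],
                "provenance": f.provenance,
            }
            for f in features
        ],
    }
    if extra:
        payload.update(extra)
    return json.dumps(payload, sort_keys=True, indent=1)


def write_features(features: Sequence[TrendFeatures], path, extra: dict | None = None) -> None:
    Path(path).write_text(features_to_json(features, extra))


def read_features(path) -> list[TrendFeatures]:
    payload = json.loads(Path(path).read_text())
    out = []
    for f in payload["features"]:
        out.append(
            TrendFeatures(
                metric=f["metric"],
                group=f["group"],
                plausible_intervals=[tuple(x) for x in f["plausible_intervals"]],
                breakpoints=[
                    Breakpoint(b["year"], b["direction"], tuple(b["interval"]))
                    for b in f["breakpoints"]
                ],
                annual_change=pd.DataFrame(),
                provenance=f.get("provenance", {}),
            )
        )
    return out


def write_derivative_summaries(features: Sequence[TrendFeatures], path) -> None:
    """Tidy CSV of grid-wise annual-change summaries."""
    frames = []
    for f in features:
        df = f.annual_change.copy()
        df.insert(0, "group", f.group)
        df.insert(0, "metric", f.metric)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# -- posterior curve sets (runtime artifact, binary npz) -------------------
def save_curveset(curves: PosteriorCurveSet, path) -> None:
    arrays = {"grid": curves.grid}
    for g in curves.groups:
        arrays[f"draws::{g}"] = curves.draws[g]
        arrays[f"deriv1::{g}"] = curves.deriv1[g]
        arrays[f"deriv2::{g}"] = curves.deriv2[g]
    meta = json.dumps(
        {
            "metric": curves.metric,
            "provenance": curves.provenance,
            "diagnostics": curves.diagnostics,
        },
        sort_keys=True,
    )
    np.savez_compressed(path, __meta__=np.array(meta), **arrays)


def load_curveset(path) -> PosteriorCurveSet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        grid = z["grid"]
        draws, d1, d2 = {}, {}, {}
        for key in z.files:
            if key.startswith("draws::"):
                draws[key[7:]] = z[key]
            elif key.startswith("deriv1::"):
                d1[key[8:]] = z[key]
            elif key.startswith("deriv2::"):
                d2[key[8:]] = z[key]
    return PosteriorCurveSet(
        metric=meta["metric"],
        grid=grid,
        draws=draws,
        deriv1=d1,
        deriv2=d2,
        provenance=meta["provenance"],
        diagnostics=meta["diagnostics"],
    )
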