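"""Winter severity from daily weather records.

Implements the accumulated winter season severity index (AWSSI): a winter
season is delimited by temperature/snow/calendar trigger rules, and every
day inside the season earns points from banded scoring tables for its
maximum and minimum temperature, its snowfall and its standing snow depth.
The accumulated point total up to a survey date is the winter severity
``w``; the day count from the season onset to the survey date is the
winter duration ``d``.

Daily records are held in a pandas DataFrame with columns ``date`` (one
row per calendar day, contiguous), ``tmax``, ``tmin``, ``tavg`` (degrees
Celsius), ``prcp`` (mm liquid equivalent), ``snwd`` (cm standing snow) and
optionally ``snowfall`` (cm).  Missing observations are NaN.  Imputation
helpers add boolean ``<field>_imputed`` companion columns.

A winter season spans 1 July of its first calendar year through 30 June of
the second, so December-starting winters are assigned unambiguously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import GapError, RangeError, ValidationError

TEMPERATURE_FIELDS = ("tmax", "tmin", "tavg")

#: AWSSI trigger thresholds (fixed by the index definition, not scoring config)
WINTER_START_TMAX_C = 0.0
WINTER_START_SNOW_DEPTH_CM = 0.25
WINTER_END_TMAX_C = 0.0
WINTER_END_SNOWFALL_CM = 0.25
WINTER_END_SNOW_DEPTH_CM = 2.5


# ---------------------------------------------------------------------------
# scoring configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreTables:
    """Banded AWSSI point tables plus the snowfall-estimation rules.

    Temperature bands are ``(upper_bound_c, points)`` pairs: a value earns
    the points of the smallest bound it is less than or equal to.  Snow
    bands are ``(lower_bound_cm, points)`` pairs: a value earns the points
    of the largest bound it is greater than or equal to.
    """

    tmax_points: tuple[tuple[float, int], ...]
    tmin_points: tuple[tuple[float, int], ...]
    snowfall_points: tuple[tuple[float, int], ...]
    snow_depth_points: tuple[tuple[float, int], ...]
    warm_day_mean_celsius: float = 0.0
    snow_to_liquid_ratio: float = 10.0
    melt_cm_per_degree_day: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "ScoreTables":
        """Load tables from a YAML file; the packaged default when omitted."""
        if path is None:
            text = (
                resources.files("batdyn").joinpath("awssi_tables.yaml").read_text()
            )
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        rules = raw.get("snow_rules", {})
        return cls(
            tmax_points=tuple((float(a), int(b)) for a, b in raw["tmax_points"]),
            tmin_points=tuple((float(a), int(b)) for a, b in raw["tmin_points"]),
            snowfall_points=tuple(
                (float(a), int(b)) for a, b in raw["snowfall_points"]
            ),
            snow_depth_points=tuple(
                (float(a), int(b)) for a, b in raw["snow_depth_points"]
            ),
            warm_day_mean_celsius=float(rules.get("warm_day_mean_celsius", 0.0)),
            snow_to_liquid_ratio=float(rules.get("snow_to_liquid_ratio", 10.0)),
            melt_cm_per_degree_day=float(rules.get("melt_cm_per_degree_day", 2.0)),
        )


def _score_temperature(value: float, bands: tuple[tuple[float, int], ...]) -> int:
    if not np.isfinite(value):
        raise ValidationError("temperature must be imputed before scoring")
    points = 0
    for bound, pts in bands:
        if value <= bound:
            points = max(points, pts)
    return points


def _score_snow(value: float, bands: tuple[tuple[float, int], ...]) -> int:
    if not np.isfinite(value) or value < 0:
        return 0
    points = 0
    for bound, pts in bands:
        if value >= bound:
            points = max(points, pts)
    return points


# ---------------------------------------------------------------------------
# record validation / imputation
# ---------------------------------------------------------------------------

def _check_contiguous(dates: pd.Series) -> None:
    d = pd.to_datetime(dates)
    if len(d) < 2:
        return
    steps = d.diff().dropna()
    bad = steps[steps != pd.Timedelta(days=1)]
    if len(bad):
        i = bad.index[0]
        raise GapError(
            f"daily series is not contiguous: gap between "
            f"{d.loc[i - 1].date()} and {d.loc[i].date()}"
        )


def _harmonic_design(dates: pd.Series) -> np.ndarray:
    doy = pd.to_datetime(dates).dt.dayofyear.to_numpy(float)
    ang = 2.0 * np.pi * doy / 365.25
    return np.column_stack(
        [np.ones_like(ang), np.sin(ang), np.cos(ang), np.sin(2 * ang), np.cos(2 * ang)]
    )


def impute_temperatures(
    records: pd.DataFrame, donor_count: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Fill missing daily temperatures by predictive mean matching.

    Each temperature field is regressed on day-of-year harmonics plus the
    other two (provisionally completed) temperature fields; a missing value
    is replaced by the *observed* value of a donor day drawn uniformly from
    the ``donor_count`` days whose regression predictions are nearest the
    missing day's prediction.  Deterministic for a fixed ``seed``.

    The post-imputation ordering ``tmin <= tavg <= tmax`` is enforced: a
    draw that breaks it is replaced by the nearest donor that satisfies it,
    falling back to clipping into the admissible interval.
    """
    df = records.reset_index(drop=True).copy()
    _check_contiguous(df["date"])
    if len(df) < 365:
        raise ValidationError("need at least one full year of daily records")
    for f in TEMPERATURE_FIELDS:
        if df[f].isna().all():
            raise ValidationError(f"temperature column {f!r} is entirely missing")
        if df[f].isna().mean() >= 0.5:
            raise ValidationError(f"more than half of {f!r} is missing")

    rng = np.random.default_rng(seed)
    harm = _harmonic_design(df["date"])

    # provisional completion from harmonics alone, so cross-field predictors
    # are available on every row in the second pass
    provisional = {}
    for f in TEMPERATURE_FIELDS:
        obs = df[f].notna().to_numpy()
        y = df[f].to_numpy(float)
        beta, *_ = np.linalg.lstsq(harm[obs], y[obs], rcond=None)
        filled = y.copy()
        filled[~obs] = harm[~obs] @ beta
        provisional[f] = filled

    for f in TEMPERATURE_FIELDS:
        flag_col = f"{f}_imputed"
        if flag_col not in df.columns:
            df[flag_col] = False
        obs = df[f].notna().to_numpy()
        if obs.all():
            continue
        others = [g for g in TEMPERATURE_FIELDS if g != f]
        design = np.column_stack([harm] + [provisional[g] for g in others])
        y = df[f].to_numpy(float)
        beta, *_ = np.linalg.lstsq(design[obs], y[obs], rcond=None)
        pred = design @ beta
        donor_pred = pred[obs]
        donor_val = y[obs]
        values = y.copy()
        for i in np.flatnonzero(~obs):
            order = np.argsort(np.abs(donor_pred - pred[i]), kind="stable")
            pool = order[: max(1, donor_count)]
            pick = rng.integers(len(pool))
            values[i] = donor_val[pool[pick]]
            # ordering repair against the row's currently known fields
            lo, hi = _ordering_bounds(f, df.loc[i], values[i])
            if not (lo <= values[i] <= hi):
                ok = [j for j in pool if lo <= donor_val[j] <= hi]
                values[i] = donor_val[ok[0]] if ok else float(np.clip(values[i], lo, hi))
        df.loc[~obs, f] = values[~obs]
        df.loc[~obs, flag_col] = True

    # final ordering repair on rows where an imputed tavg strayed
    bad = (df["tavg"] < df["tmin"]) | (df["tavg"] > df["tmax"])
    if bad.any():
        df.loc[bad, "tavg"] = df.loc[bad, ["tmin", "tmax"]].mean(axis=1)
        df.loc[bad, "tavg_imputed"] = True
    return df


def _ordering_bounds(field_name: str, row: pd.Series, value: float) -> tuple[float, float]:
    tmax = row["tmax"] if pd.notna(row.get("tmax")) else np.inf
    tmin = row["tmin"] if pd.notna(row.get("tmin")) else -np.inf
    tavg = row["tavg"] if pd.notna(row.get("tavg")) else np.nan
    if field_name == "tmax":
        lo = tavg if np.isfinite(tavg) else tmin
        return (lo if np.isfinite(lo) else -np.inf, np.inf)
    if field_name == "tmin":
        hi = tavg if np.isfinite(tavg) else tmax
        return (-np.inf, hi if np.isfinite(hi) else np.inf)
    return (tmin, tmax)


def fill_precipitation(records: pd.DataFrame) -> pd.DataFrame:
    """Set missing liquid precipitation to zero (conservative fill)."""
    df = records.copy()
    missing = df["prcp"].isna()
    df["prcp_imputed"] = missing.to_numpy()
    df.loc[missing, "prcp"] = 0.0
    if (df["prcp"] < 0).any():
        raise ValidationError("negative precipitation")
    return df


def estimate_snowfall(
    tmax: float, tmin: float, prcp: float, tables: ScoreTables | None = None
) -> float:
    """Estimate daily snowfall (cm) from temperature extremes and liquid precip.

    Zero on warm days (mean temperature above the configured threshold);
    otherwise the liquid amount converted with the snow-to-liquid ratio.
    """
    if tables is None:
        tables = ScoreTables.from_yaml()
    if prcp < 0:
        raise ValidationError("negative precipitation")
    if prcp == 0:
        return 0.0
    if (tmax + tmin) / 2.0 > tables.warm_day_mean_celsius:
        return 0.0
    return prcp * tables.snow_to_liquid_ratio / 10.0  # mm liquid -> cm snow


def add_snow_estimates(
    records: pd.DataFrame, tables: ScoreTables | None = None
) -> pd.DataFrame:
    """Add a ``snowfall`` column and carry-forward-fill missing snow depth.

    Snowfall on each day is the observed value when a ``snowfall`` column is
    present and observed, otherwise estimated from temperature and
    precipitation.  Missing snow depth is filled by the accumulation/melt
    rule ``depth(t) = max(0, depth(t-1) + snowfall(t) - melt(t))`` with a
    degree-day melt proportional to positive mean temperature.
    """
    if tables is None:
        tables = ScoreTables.from_yaml()
    df = records.copy()
    tmax = df["tmax"].to_numpy(float)
    tmin = df["tmin"].to_numpy(float)
    prcp = df["prcp"].to_numpy(float)
    est = np.where(
        (prcp > 0) & ((tmax + tmin) / 2.0 <= tables.warm_day_mean_celsius),
        prcp * tables.snow_to_liquid_ratio / 10.0,
        0.0,
    )
    if "snowfall" in df.columns:
        snowfall = df["snowfall"].to_numpy(float)
        snowfall = np.where(np.isfinite(snowfall), snowfall, est)
    else:
        snowfall = est
    df["snowfall"] = snowfall

    depth = df["snwd"].to_numpy(float).copy()
    mean_t = (tmax + tmin) / 2.0
    melt = tables.melt_cm_per_degree_day * np.clip(mean_t, 0.0, None)
    prev = 0.0
    filled = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        if np.isfinite(depth[i]):
            prev = depth[i]
        else:
            prev = max(0.0, prev + snowfall[i] - melt[i])
            depth[i] = prev
            filled[i] = True
    df["snwd"] = depth
    df["snwd_imputed"] = filled
    return df


# ---------------------------------------------------------------------------
# winter seasons
# ---------------------------------------------------------------------------

@dataclass
class WinterSeason:
    """One scored winter with its daily AWSSI point series.

    ``daily`` has columns date, temp_points, snow_points, points and
    cumulative_awssi, one row per day from start_date to end_date.
    """

    label: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    daily: pd.DataFrame = field(repr=False)

    @property
    def total(self) -> float:
        return float(self.daily["cumulative_awssi"].iloc[-1])


@dataclass(frozen=True)
class SeverityAtDate:
    """Severity ``w`` (AWSSI points) and duration ``d`` (days) at a query date."""

    w: float
    d: int


def _season_window(records: pd.DataFrame, season_label: str | int) -> pd.DataFrame:
    first_year = int(str(season_label).split("-")[0])
    lo = pd.Timestamp(first_year, 7, 1)
    hi = pd.Timestamp(first_year + 1, 6, 30)
    dates = pd.to_datetime(records["date"])
    window = records.loc[(dates >= lo) & (dates <= hi)].copy()
    window["date"] = pd.to_datetime(window["date"])
    if window.empty or window["date"].min() > lo or window["date"].max() < hi:
        raise RangeError(
            f"records must cover {lo.date()}..{hi.date()} for season {season_label}"
        )
    return window.sort_values("date").reset_index(drop=True)


def find_winter_start(records: pd.DataFrame, season_label: str | int) -> pd.Timestamp:
    """Earliest day with tmax <= 0 C, snow depth >= 0.25 cm, or 1 December."""
    win = _season_window(records, season_label)
    first_year = int(str(season_label).split("-")[0])
    dec1 = pd.Timestamp(first_year, 12, 1)
    trigger = (win["tmax"] <= WINTER_START_TMAX_C) | (
        win["snwd"] >= WINTER_START_SNOW_DEPTH_CM
    )
    hits = win.loc[trigger.fillna(False), "date"]
    start = hits.min() if len(hits) else dec1
    return min(start, dec1)


def find_winter_end(records: pd.DataFrame, season_label: str | int) -> pd.Timestamp:
    """Latest day with tmax <= 0 C, snowfall >= 0.25 cm, depth >= 2.5 cm, or 1 March."""
    win = _season_window(records, season_label)
    if "snowfall" not in win.columns:
        win = add_snow_estimates(win)
    first_year = int(str(season_label).split("-")[0])
    mar1 = pd.Timestamp(first_year + 1, 3, 1)
    trigger = (
        (win["tmax"] <= WINTER_END_TMAX_C)
        | (win["snowfall"] >= WINTER_END_SNOWFALL_CM)
        | (win["snwd"] >= WINTER_END_SNOW_DEPTH_CM)
    )
    hits = win.loc[trigger.fillna(False), "date"]
    end = hits.max() if len(hits) else mar1
    return max(end, mar1)


def accumulate_awssi(
    records: pd.DataFrame,
    start_date,
    end_date,
    tables: ScoreTables | None = None,
    label: str | None = None,
) -> WinterSeason:
    """Score every day in [start_date, end_date] and accumulate AWSSI points."""
    if tables is None:
        tables = ScoreTables.from_yaml()
    start_date = pd.Timestamp(start_date)
    end_date = pd.Timestamp(end_date)
    if start_date > end_date:
        raise ValidationError("start_date must be <= end_date")
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    win = df.loc[(df["date"] >= start_date) & (df["date"] <= end_date)]
    win = win.sort_values("date").reset_index(drop=True)
    if len(win) != (end_date - start_date).days + 1:
        raise RangeError("records do not cover the requested season range")
    if win[["tmax", "tmin"]].isna().any().any():
        raise ValidationError(
            "missing tmax/tmin inside the season; run impute_temperatures first"
        )
    if "snowfall" not in win.columns or win["snowfall"].isna().any() or win[
        "snwd"
    ].isna().any():
        win = add_snow_estimates(win, tables)

    temp_pts = np.array(
        [
            _score_temperature(r.tmax, tables.tmax_points)
            + _score_temperature(r.tmin, tables.tmin_points)
            for r in win.itertuples()
        ],
        dtype=float,
    )
    snow_pts = np.array(
        [
            _score_snow(r.snowfall, tables.snowfall_points)
            + _score_snow(r.snwd, tables.snow_depth_points)
            for r in win.itertuples()
        ],
        dtype=float,
    )
    daily = pd.DataFrame(
        {
            "date": win["date"],
            "temp_points": temp_pts,
            "snow_points": snow_pts,
            "points": temp_pts + snow_pts,
        }
    )
    daily["cumulative_awssi"] = daily["points"].cumsum()
    if label is None:
        label = f"{start_date.year}-{start_date.year + 1}"
    return WinterSeason(label=label, start_date=start_date, end_date=end_date, daily=daily)


def score_season(
    records: pd.DataFrame, season_label: str | int, tables: ScoreTables | None = None
) -> WinterSeason:
    """Find the season bounds and accumulate AWSSI in one call."""
    win = add_snow_estimates(_season_window(records, season_label), tables)
    start = find_winter_start(win, season_label)
    end = find_winter_end(win, season_label)
    season = accumulate_awssi(win, start, end, tables, label=str(season_label))
    return season


def severity_at(season: WinterSeason, query_date) -> SeverityAtDate:
    """Severity and duration accumulated from the season onset to a date."""
    q = pd.Timestamp(query_date)
    if q < season.start_date:
        warnings.warn(
            f"query date {q.date()} precedes winter onset {season.start_date.date()}",
            stacklevel=2,
        )
        return SeverityAtDate(w=0.0, d=0)
    if q > season.end_date:
        w = season.total
    else:
        w = float(
            season.daily.loc[season.daily["date"] <= q, "cumulative_awssi"].iloc[-1]
        )
    return SeverityAtDate(w=w, d=int((q - season.start_date).days))
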