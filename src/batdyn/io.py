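"""Readers, writers and the end-to-end pipeline.

CSV dialects are pinned: comma-separated, UTF-8, ISO-8601 dates.  Column
names follow the survey-table convention of long-term hibernaculum
monitoring datasets (species abbreviations like ``Mmyo``/``Rhip``,
``awssi.winter`` for severity at the survey date, ``sampling.winter`` for
winter duration), with a synonym map accepting cleaner names.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, growth, weather
from .errors import ValidationError

log = logging.getLogger("batdyn")

WEATHER_COLUMNS = {"DATE": "date", "TMAX": "tmax", "TMIN": "tmin",
                   "TAVG": "tavg", "PRCP": "prcp", "SNWD": "snwd",
                   "SNOW": "snowfall"}

SURVEY_SYNONYMS = {
    "year": "Year", "date": "Date",
    "awssi.winter": "awssi.winter", "awssi_winter": "awssi.winter", "w": "awssi.winter",
    "sampling.winter": "sampling.winter", "sampling_winter": "sampling.winter",
    "d": "sampling.winter",
}

SECTION_SYNONYMS = {
    "hall": "Hall", "entrance hall": "Hall", "halstatt hall": "Hall",
    "predsin": "Hall", "předsíň": "Hall",
    "german gallery": "German Gallery",
    "giant pots": "Giant Pots", "obri hrnce": "Giant Pots", "obří hrnce": "Giant Pots",
    "bruna cave": "Bruna Cave", "brunna cave": "Bruna Cave",
    "main corridor": "Main Corridor", "hlavni chodba": "Main Corridor",
    "hlavní chodba": "Main Corridor",
}


def read_weather_csv(path: str | Path) -> pd.DataFrame:
    """Read a GHCN-Daily-style metric CSV (DATE, TMAX, TMIN, TAVG, PRCP, SNWD)."""
    raw = pd.read_csv(path)
    cols = {c: WEATHER_COLUMNS.get(c.upper(), c.lower()) for c in raw.columns}
    df = raw.rename(columns=cols)
    required = {"date", "tmax", "tmin", "tavg", "prcp", "snwd"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"weather file lacks columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    for c in ("tmax", "tmin", "tavg", "prcp", "snwd", "snowfall"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df.sort_values("date").reset_index(drop=True)


def write_weather_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={v: k for k, v in WEATHER_COLUMNS.items()})
    out = out[[c for c in out.columns if not c.endswith("_imputed")]]
    out.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_surveys(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read the annual survey table; one observation frame per species.

    Blank count cells mark years without a survey of that species and are
    dropped from the species' series (absent from the likelihood sums).
    Returns a mapping species-code -> DataFrame(t, n, w, d) plus the
    survey dates under the key ``_dates``.
    """
    raw = pd.read_csv(path)
    ren = {c: SURVEY_SYNONYMS.get(c.strip().lower(), c.strip()) for c in raw.columns}
    df = raw.rename(columns=ren)
    for col in ("Year", "awssi.winter", "sampling.winter"):
        if col not in df.columns:
            raise ValidationError(f"survey file lacks column {col!r}")
    if df["Year"].duplicated().any():
        dup = sorted(df.loc[df["Year"].duplicated(), "Year"].unique())
        raise ValidationError(f"duplicate survey year(s) {dup}")
    meta = {"Year", "Date", "awssi.winter", "sampling.winter"}
    out: dict[str, pd.DataFrame] = {}
    for sp in [c for c in df.columns if c not in meta]:
        counts = pd.to_numeric(df[sp], errors="coerce")
        keep = counts.notna()
        if (counts[keep] < 0).any():
            raise ValidationError(f"negative count for species {sp!r}")
        out[sp] = pd.DataFrame(
            {
                "t": df.loc[keep, "Year"].astype(int).to_numpy(),
                "n": counts[keep].astype(int).to_numpy(),
                "w": pd.to_numeric(df.loc[keep, "awssi.winter"]).to_numpy(float),
                "d": pd.to_numeric(df.loc[keep, "sampling.winter"]).to_numpy(float),
            }
        ).reset_index(drop=True)
    if "Date" in df.columns:
        out["_dates"] = df[["Year", "Date"]].copy()
    return out


def write_surveys_csv(surveys: pd.DataFrame, path: str | Path,
                      species: str = "Mmyo") -> None:
    """Write a one-species observation frame in the survey-table dialect."""
    out = pd.DataFrame(
        {
            "Year": surveys["t"].astype(int),
            species: surveys["n"].astype(int),
            "awssi.winter": surveys["w"],
            "sampling.winter": surveys["d"],
        }
    )
    out.to_csv(path, index=False)


def read_clusters(path: str | Path) -> pd.DataFrame:
    """Read per-cluster records (year, section, size), normalising section names."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("year", "section", "size"):
        if col not in df.columns:
            raise ValidationError(f"cluster file lacks column {col!r}")
    df["section"] = [
        SECTION_SYNONYMS.get(str(s).strip().lower(), str(s).strip())
        for s in df["section"]
    ]
    unknown = set(df["section"]) - set(clustering.SECTION_THERMAL)
    if unknown:
        raise ValidationError(f"unknown cave section(s): {sorted(unknown)}")
    df["year"] = df["year"].astype(int)
    df["size"] = df["size"].astype(int)
    if (df["size"] < 1).any():
        raise ValidationError("cluster size must be >= 1")
    return df


def write_clusters_csv(clusters: pd.DataFrame, path: str | Path) -> None:
    clusters[["year", "section", "size"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    surveys_path: str
    clusters_path: str | None = None
    weather_path: str | None = None
    species: str = "Mmyo"
    clustering_species: str | None = None  # defaults to `species`
    score_tables_path: str | None = None
    seed: int = 0
    profile_params: tuple[str, ...] = ("a", "b", "a_w", "b_w")
    profile_grid: int = 201
    log10_abundance_in_lrt: bool = False
    out_dir: str = "batdyn_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, pd.DataFrame):
        return _jsonable(x.to_dict(orient="list"))
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def growth_report(fit: growth.GrowthFit, ls: growth.LSGrowthFit) -> dict:
    return {
        "ls": {
            "a": ls.params.a, "b": ls.params.b, "g": ls.g,
            "g_ci95": list(ls.g_ci95),
        },
        "ml": {
            "a": fit.params.a, "b": fit.params.b,
            "a_w": fit.sev_model.a_w, "b_w": fit.sev_model.b_w,
            "a_d": fit.dur_model.a_d, "b_d": fit.dur_model.b_d,
            "lnl_max": fit.lnl_max, "g": fit.g,
            "g_ci95": list(fit.g_ci95) if fit.g_ci95 else None,
            "ci95": {k: list(v) for k, v in fit.ci95.items()},
            "profiles": {k: v.to_dict(orient="list") for k, v in fit.profiles.items()},
        },
    }


def run_growth(obs: pd.DataFrame, profile_params=("a", "b", "a_w", "b_w"),
               n_grid: int = 201, c: int = 1977) -> tuple[growth.GrowthFit, growth.LSGrowthFit]:
    ls = growth.fit_growth_ls(obs, c=c)
    dur = growth.fix_duration_model(obs, ls.params)
    fit = growth.fit_growth_ml(obs, dur_model=dur, c=c)
    for name in profile_params:
        growth.profile_ci(obs, fit, name, n_grid=n_grid)
    return fit, ls


def run_clustering(clusters: pd.DataFrame, surveys: pd.DataFrame,
                   log10_abundance: bool = False) -> dict:
    sev_by_year = {
        int(r.t): weather.SeverityAtDate(w=float(r.w), d=int(r.d))
        for r in surveys.itertuples()
    }
    summaries = clustering.summarize_all_years(clusters, sev_by_year)
    summaries = summaries[summaries["year"].isin(sev_by_year)]
    table = clustering.model_selection_table(summaries)
    sol = clustering.solitary_intercept_test(summaries)
    abundance = {int(r.t): float(r.n) for r in surveys.itertuples()}
    spatial = clustering.spatial_lrt(clusters, abundance, log10_abundance=log10_abundance)
    giant = clustering.giant_pots_lrt(clusters, abundance, log10_abundance=log10_abundance)
    return {
        "summaries": summaries,
        "model_selection": [
            {
                "response": r.response,
                "retained_terms": list(r.retained_terms),
                "aic_null": r.aic_null, "aic_final": r.aic_final,
                "delta_aic": r.delta_aic,
                "f_stat": r.f_stat, "df": list(r.df) if r.df else None,
                "p_value": r.p_value,
            }
            for r in table
        ],
        "solitary": {
            "mean": sol.mean, "t": sol.t, "df": sol.df, "p_value": sol.p_value,
        },
        "spatial_lrt": {"statistic": spatial.statistic, "df": spatial.df,
                        "p_value": spatial.p_value},
        "giant_pots_lrt": {"statistic": giant.statistic, "df": giant.df,
                           "p_value": giant.p_value},
        "max_cluster_size": int(clusters["size"].max()),
    }


def run_pipeline(config: AnalysisConfig) -> dict:
    """Severity -> growth (LS + ML + profiles) -> clustering, with reports.

    Writes ``report.json`` (machine-readable; every number of the run) and
    ``summary.txt`` (human-readable restatement of the same numbers) into
    the output directory and returns the report dict.  A stage failure
    aborts the run and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: _jsonable(v) for k, v in vars(config).items()},
                    "seed": config.seed}
    written: list[Path] = []
    try:
        if config.weather_path:
            log.info("stage severity: scoring winters from %s", config.weather_path)
            wdf = read_weather_csv(config.weather_path)
            wdf = weather.fill_precipitation(wdf)
            wdf = weather.impute_temperatures(wdf, seed=config.seed)
            tables = weather.ScoreTables.from_yaml(config.score_tables_path)
            seasons = {}
            years = sorted(set(pd.to_datetime(wdf["date"]).dt.year))
            for y in years[:-1]:
                try:
                    seasons[f"{y}-{y+1}"] = weather.score_season(wdf, y, tables)
                except Exception:
                    continue
            report["awssi"] = {
                lab: {"start": str(s.start_date.date()), "end": str(s.end_date.date()),
                      "total": s.total}
                for lab, s in seasons.items()
            }

        log.info("stage growth: species %s from %s", config.species, config.surveys_path)
        all_surveys = read_surveys(config.surveys_path)
        if config.species not in all_surveys:
            raise ValidationError(
                f"species {config.species!r} not in survey table; available: "
                f"{sorted(k for k in all_surveys if not k.startswith('_'))}"
            )
        obs = all_surveys[config.species]
        fit, ls = run_growth(obs, config.profile_params, config.profile_grid)
        report["growth"] = growth_report(fit, ls)

        if config.clusters_path:
            sp = config.clustering_species or config.species
            log.info("stage clustering: species %s from %s", sp, config.clusters_path)
            clusters = read_clusters(config.clusters_path)
            cl = run_clustering(clusters, all_surveys[sp],
                                config.log10_abundance_in_lrt)
            cl["summaries"] = cl["summaries"].to_dict(orient="list")
            report["clustering"] = cl

        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
        written.append(report_path)
        summary_path = out_dir / "summary.txt"
        summary_path.write_text(render_summary(report))
        written.append(summary_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return report


def render_summary(report: dict) -> str:
    """Human-readable restatement of the numbers in the machine report."""
    lines = []
    g = report.get("growth")
    if g:
        lines.append("Exponential growth")
        lines.append(
            f"  least squares: g = {g['ls']['g']:.2f} %/yr, "
            f"95% CI [{g['ls']['g_ci95'][0]:.2f}, {g['ls']['g_ci95'][1]:.2f}]"
        )
        ml = g["ml"]
        ci = ml.get("g_ci95")
        ci_txt = f", 95% profile CI [{ci[0]:.2f}, {ci[1]:.2f}]" if ci else ""
        lines.append(f"  maximum likelihood: g = {ml['g']:.2f} %/yr{ci_txt}")
        lines.append(
            f"  parameters: a = {ml['a']:.3f}, b = {ml['b']:.5f}, "
            f"a_w = {ml['a_w']:.3f}, b_w = {ml['b_w']:.4f} "
            f"(lnL = {ml['lnl_max']:.3f})"
        )
    c = report.get("clustering")
    if c:
        lines.append("Clustering behaviour")
        sol = c["solitary"]
        lines.append(
            f"  solitary fraction: mean = {sol['mean']:.4f}, "
            f"t = {sol['t']:.2f} (df {sol['df']})"
        )
        for row in c["model_selection"]:
            terms = " + ".join(["1"] + row["retained_terms"])
            fpart = (
                f", F({row['df'][0]},{row['df'][1]}) = {row['f_stat']:.2f}"
                if row["f_stat"] is not None else ""
            )
            lines.append(
                f"  {row['response']}: final model {terms}, "
                f"dAIC = {row['delta_aic']:.2f}{fpart}"
            )
        sp = c["spatial_lrt"]
        gp = c["giant_pots_lrt"]
        lines.append(
            f"  spatial LRT: -2dlnL = {sp['statistic']:.1f} (df {sp['df']}); "
            f"Giant Pots LRT: -2dlnL = {gp['statistic']:.1f} (df {gp['df']})"
        )
        lines.append(f"  maximum cluster size: {c['max_cluster_size']}")
    return "\n".join(lines) + "\n"
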