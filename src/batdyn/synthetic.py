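"""Synthetic weather, census and cluster data with the assumed structure.

The generators produce desk-scale stand-ins for the three inputs of the
analysis — daily weather records, annual census counts and per-cluster
records — with the statistical structure the models assume, so every
stage of the pipeline can be exercised and parameter-recovery experiments
run without any external data.

Defaults emulate a 42-year Central European hibernaculum study: a
temperate seasonal climate with occasional winter snow and a few percent
of missing observations; counts growing exponentially at ~10% per year
from a few animals, with residual magnitude linked linearly to winter
severity (mean) and winter duration (scale); a stable ~14% solitary
fraction; and cluster sizes growing with log10 abundance, the largest
clusters preferentially in the Giant Pots section.

All randomness flows through one ``numpy`` Generator seeded from the
scenario seed, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import weather as wx
from .clustering import SECTION_THERMAL
from .errors import ValidationError
from .growth import GrowthParams, predict_abundance

SECTIONS = tuple(SECTION_THERMAL)
_WARM = tuple(s for s, c in SECTION_THERMAL.items() if c == "warm")
_COLD = tuple(s for s, c in SECTION_THERMAL.items() if c == "cold")


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth for one synthetic study.

    Growth truth (a, b, c) and the residual links (a_w, b_w) / (a_d, b_d)
    mirror the parameters of the likelihood model; the clustering truths
    mirror the patterns the clustering analyses look for.
    """

    seed: int = 0
    year_start: int = 1977
    year_end: int = 2018

    # exponential growth truth: ~10%/yr from 8 animals in the anchor year
    a: float = 8.0
    b: float = 1.10
    c: int = 1977

    # residual links: mean |residual| rises with severity w (AWSSI points),
    # residual scale rises with duration d (days)
    a_w: float = 10.0
    b_w: float = 0.02
    a_d: float = 2.0
    b_d: float = 0.05

    # clustering truth
    solitary_fraction: float = 0.136
    cluster_mean_intercept: float = -5.6   # mean size = intercept + slope*log10 n
    cluster_mean_slope: float = 4.8
    cluster_dispersion: float = 5.0        # NB size parameter for cluster sizes
    warm_logit_intercept: float = -6.0     # P(warm) = logistic(a + b*log10 n)
    warm_logit_slope: float = 2.0
    giant_pots_affinity: float = 0.7       # chance the largest cold clusters sit in Giant Pots

    # weather truth (degrees Celsius, mm, cm)
    temp_mean: float = 9.0
    temp_amplitude: float = 10.5
    temp_noise_sd: float = 3.0
    temp_noise_rho: float = 0.7
    diurnal_half_range: float = 4.0
    wet_day_prob: float = 0.35
    wet_day_mean_mm: float = 3.0
    missing_rate: float = 0.05

    # survey timing: day-of-February used as the annual census date
    survey_month: int = 2
    survey_day: int = 20

    def __post_init__(self):
        if not 0.0 <= self.solitary_fraction <= 1.0:
            raise ValidationError("solitary_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")

    @property
    def growth_params(self) -> GrowthParams:
        return GrowthParams(a=self.a, b=self.b, c=self.c)

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def gen_weather(config: ScenarioConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily weather spanning 1 July before the first survey year to 30 June
    after the last: sinusoidal annual temperature cycle with AR(1) noise,
    occasional precipitation falling as snow on cold days with carry-forward
    snow depth, and missing values at the configured rate.

    Every winter is guaranteed at least one freezing day in January, so the
    seasonal severity index is never degenerate.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dates = pd.date_range(
        start=pd.Timestamp(config.year_start - 1, 7, 1),
        end=pd.Timestamp(config.year_end, 6, 30),
        freq="D",
    )
    m = len(dates)
    doy = dates.dayofyear.to_numpy(float)
    # warmest around mid-July (doy ~196), coldest mid-January
    seasonal = config.temp_mean + config.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - 196.0) / 365.25
    )
    noise = np.empty(m)
    eps = rng.normal(0.0, config.temp_noise_sd, size=m)
    rho = config.temp_noise_rho
    noise[0] = eps[0]
    for i in range(1, m):
        noise[i] = rho * noise[i - 1] + np.sqrt(max(1.0 - rho**2, 0.0)) * eps[i]
    tavg = seasonal + noise
    half = config.diurnal_half_range
    tmax = tavg + half * (0.8 + 0.4 * rng.random(m))
    tmin = tavg - half * (0.8 + 0.4 * rng.random(m))

    # force one freezing mid-winter day per season so a real trigger exists
    years = dates.year.to_numpy()
    for first_year in range(config.year_start - 1, config.year_end):
        jan = (years == first_year + 1) & (dates.month == 1)
        if jan.any() and tmax[jan].min() > 0:
            j = np.flatnonzero(jan)[np.argmin(tmax[jan])]
            shift = tmax[j] + 1.0
            tmax[j] -= shift
            tavg[j] -= shift
            tmin[j] -= shift

    prcp = np.where(
        rng.random(m) < config.wet_day_prob,
        rng.exponential(config.wet_day_mean_mm, size=m),
        0.0,
    )
    df = pd.DataFrame(
        {"date": dates, "tmax": tmax, "tmin": tmin, "tavg": tavg, "prcp": prcp}
    )
    # standing snow from the same accumulation/melt rule the scorer uses
    df["snwd"] = np.nan
    tables = wx.ScoreTables.from_yaml()
    df = wx.add_snow_estimates(df, tables)
    df = df.drop(columns=["snwd_imputed"])

    if config.missing_rate > 0:
        for col in ("tmax", "tmin", "tavg", "prcp", "snwd"):
            mask = rng.random(m) < config.missing_rate
            df.loc[mask, col] = np.nan
        df = df.drop(columns=["snowfall"])  # downstream re-estimates it
    return df


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

def survey_dates(config: ScenarioConfig) -> dict[int, pd.Timestamp]:
    """The fixed late-February census date for every survey year."""
    return {
        t: pd.Timestamp(t, config.survey_month, config.survey_day)
        for t in range(config.year_start, config.year_end + 1)
    }


def gen_surveys(
    config: ScenarioConfig,
    severities: dict[int, wx.SeverityAtDate],
    rng: np.random.Generator | None = None,
    zero_noise: bool = False,
) -> pd.DataFrame:
    """Annual counts from the growth curve with severity-linked residuals.

    A Poisson deviate around n_hat = a*b**(t-c) supplies the residual sign;
    its magnitude is replaced by a draw from N(a_w + b_w*w, (a_d + b_d*d)^2)
    clipped at zero, so the expected absolute residual follows the severity
    line and its spread the duration line.  With all four residual-link
    truths zero the counts are left pure Poisson; ``zero_noise=True``
    returns deterministically rounded expectations.  Clipping the normal
    draw at zero (the model's |residual| law has no exact generative
    counterpart) slightly shrinks the realised mean when the severity line
    is small relative to the duration scale.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    missing = [t for t in range(config.year_start, config.year_end + 1) if t not in severities]
    if missing:
        raise ValidationError(f"severities missing for years {missing}")
    rows = []
    pure_poisson = (config.a_w, config.b_w, config.a_d, config.b_d) == (0, 0, 0, 0)
    for t in range(config.year_start, config.year_end + 1):
        sev = severities[t]
        mu = predict_abundance(config.growth_params, t)
        if zero_noise:
            n = int(round(mu))
        elif pure_poisson:
            n = int(rng.poisson(mu))
        else:
            p = rng.poisson(mu)
            sign = np.sign(p - mu) or 1.0
            mean_r = max(config.a_w + config.b_w * sev.w, 0.0)
            scale_r = max(config.a_d + config.b_d * sev.d, 1e-6)
            r = max(rng.normal(mean_r, scale_r), 0.0)
            n = max(int(round(mu + sign * r)), 0)
        rows.append({"t": t, "n": n, "w": float(sev.w), "d": int(sev.d)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def _partition_sizes(
    total: int, mean_size: float, dispersion: float, rng: np.random.Generator
) -> list[int]:
    """Cluster sizes >= 2 summing exactly to ``total`` (total >= 2)."""
    mean_size = max(mean_size, 2.0)
    sizes: list[int] = []
    remaining = total
    excess_mean = max(mean_size - 2.0, 1e-9)
    # negative binomial on the excess over the minimum size of 2
    p = dispersion / (dispersion + excess_mean)
    while remaining >= 2:
        s = 2 + int(rng.negative_binomial(dispersion, p))
        if s >= remaining - 1:  # avoid leaving a remainder of 1
            s = remaining
        sizes.append(s)
        remaining -= s
    if remaining == 1:
        sizes[-1] += 1
    return sizes


def gen_clusters(
    config: ScenarioConfig,
    surveys: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cluster records whose sizes sum exactly to each year's count.

    A ``solitary_fraction`` share of each year's bats become size-1 records;
    the rest are partitioned into clusters of at least two with mean size
    following the configured line in log10 abundance (zero-truncated
    negative-binomial excess).  Sections are drawn with warm-section
    probability increasing with abundance through the logistic link; among
    the cold sections the largest clusters preferentially occupy the Giant
    Pots with probability ``giant_pots_affinity``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    rows = []
    for rec in surveys.itertuples():
        n_total = int(rec.n)
        if n_total == 0:
            continue
        n_sol = int(round(config.solitary_fraction * n_total))
        if n_total - n_sol == 1:
            n_sol += 1  # a lone leftover bat cannot form a cluster
            if n_sol > n_total:
                warnings.warn(f"year {rec.t}: count too small to cluster", stacklevel=2)
                n_sol = n_total
        log10n = np.log10(max(n_total, 1))
        mean_size = config.cluster_mean_intercept + config.cluster_mean_slope * log10n
        sizes = [1] * n_sol
        if n_total - n_sol >= 2:
            sizes += _partition_sizes(
                n_total - n_sol, mean_size, config.cluster_dispersion, rng
            )

        p_warm = 1.0 / (1.0 + np.exp(-(config.warm_logit_intercept
                                       + config.warm_logit_slope * log10n)))
        order = np.argsort(sizes)[::-1]  # largest first for the affinity rule
        for k in order:
            size = sizes[k]
            if rng.random() < p_warm:
                section = _WARM[int(rng.random() < 0.2)]  # Main Corridor favoured
            elif size >= 2 and rng.random() < config.giant_pots_affinity * min(
                1.0, size / max(mean_size, 2.0)
            ):
                section = "Giant Pots"
            else:
                section = _COLD[rng.integers(len(_COLD))]
            rows.append({"year": int(rec.t), "section": section, "size": int(size)})
    return pd.DataFrame(rows, columns=["year", "section", "size"])


# ---------------------------------------------------------------------------
# one-call scenario
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: ScenarioConfig
    weather: pd.DataFrame = field(repr=False)
    severities: dict[int, wx.SeverityAtDate] = field(repr=False)
    surveys: pd.DataFrame = field(repr=False)
    clusters: pd.DataFrame = field(repr=False)


def generate_study(config: ScenarioConfig, score_tables=None) -> SyntheticStudy:
    """Generate weather, score its winters, then draw surveys and clusters.

    Weather is generated first; the severity/duration pair at each year's
    survey date is computed with the severity engine (after imputing the
    injected missing values) and fed to the survey generator, so the
    synthetic counts respond to the same ``w`` and ``d`` the analysis
    later recomputes.
    """
    weather_df = gen_weather(config)
    filled = wx.fill_precipitation(weather_df)
    filled = wx.impute_temperatures(filled, seed=config.seed + 3)
    severities = {}
    for t, date in survey_dates(config).items():
        season = wx.score_season(filled, t - 1, tables=score_tables)
        severities[t] = wx.severity_at(season, date)
    surveys = gen_surveys(config, severities)
    clusters = gen_clusters(config, surveys)
    return SyntheticStudy(
        config=config, weather=weather_df, severities=severities,
        surveys=surveys, clusters=clusters,
    )
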