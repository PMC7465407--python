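"""Clustering behaviour of hibernating bats: summaries, model selection, LRTs.

Cluster records are rows (year, section, size) where size is the number of
touching individuals; size 1 is a solitary bat.  The cave sections fall in
two thermal classes: the Hall, the German Gallery and the Giant Pots are
thermally unstable ("cold"), the Bruna Cave and the Main Corridor are
thermally stable ("warm").

Annual summaries (proportion of bats in warm sections, proportion roosting
solitarily, number of clusters, mean and SD of cluster size) are modelled
by multiple linear regression on log10 abundance, winter severity ``w``
and winter duration ``d`` with all pairwise interactions; terms are pruned
by backward selection on AIC.  Section-specific cluster-size/abundance
relationships are compared with nested likelihood-ratio tests where each
least-squares line contributes its Gaussian log-likelihood at the MLE
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

#: canonical cave sections and their thermal class
SECTION_THERMAL: dict[str, str] = {
    "Hall": "cold",
    "German Gallery": "cold",
    "Giant Pots": "cold",
    "Bruna Cave": "warm",
    "Main Corridor": "warm",
}

WARM_SECTIONS = frozenset(k for k, v in SECTION_THERMAL.items() if v == "warm")

#: candidate regression terms (1 denotes the always-present intercept)
EQ2_TERMS = ("log10n", "w", "d", "log10n:w", "log10n:d", "w:d")

_MAIN_OF = {
    "log10n:w": ("log10n", "w"),
    "log10n:d": ("log10n", "d"),
    "w:d": ("w", "d"),
}


# ---------------------------------------------------------------------------
# annual summaries
# ---------------------------------------------------------------------------

def summarize_year(
    clusters: pd.DataFrame,
    severity=None,
    count_solitary_as_cluster: bool = False,
) -> dict:
    """Summarise one year of cluster records.

    ``prop_warm`` and ``prop_solitary`` are weighted by individuals.  By
    default a "cluster" requires at least two touching bats, so solitary
    records are excluded from ``n_clusters``/``mean_size``/``sd_size``
    (``count_solitary_as_cluster=True`` switches to counting them as
    clusters of one).  ``severity`` may carry ``w``/``d`` attributes to be
    copied into the summary.
    """
    if clusters.empty:
        raise ValidationError("no cluster records for this year")
    unknown = set(clusters["section"]) - set(SECTION_THERMAL)
    if unknown:
        raise ValidationError(f"unknown cave section(s): {sorted(unknown)}")
    sizes = clusters["size"].to_numpy(float)
    if (sizes < 1).any():
        raise ValidationError("cluster size must be >= 1")

    n_total = float(sizes.sum())
    warm = clusters["section"].isin(WARM_SECTIONS).to_numpy()
    solitary = sizes == 1
    grouped = sizes if count_solitary_as_cluster else sizes[~solitary]
    out = {
        "year": int(clusters["year"].iloc[0]),
        "n_total": n_total,
        "prop_warm": float(sizes[warm].sum() / n_total),
        "prop_solitary": float(sizes[solitary].sum() / n_total),
        "n_clusters": int(len(grouped)),
        "mean_size": float(grouped.mean()) if len(grouped) else float("nan"),
        "sd_size": float(grouped.std(ddof=1)) if len(grouped) > 1 else float("nan"),
    }
    if severity is not None:
        out["w"] = float(severity.w)
        out["d"] = float(severity.d)
    return out


def summarize_all_years(
    clusters: pd.DataFrame,
    severities: dict[int, object] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Annual clustering summaries for every year present in the records."""
    rows = []
    for year, grp in clusters.groupby("year", sort=True):
        sev = severities.get(int(year)) if severities else None
        rows.append(summarize_year(grp, severity=sev, **kwargs))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# backward AIC model selection
# ---------------------------------------------------------------------------

@dataclass
class ModelSelectionResult:
    response: str
    retained_terms: tuple[str, ...]
    aic_null: float     # AIC of the full starting model
    aic_final: float
    delta_aic: float
    f_stat: float | None
    df: tuple[int, int] | None
    p_value: float | None
    coefficients: dict[str, float]


def _design(summaries: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    base = {
        "log10n": np.log10(summaries["n_total"].to_numpy(float)),
        "w": summaries["w"].to_numpy(float),
        "d": summaries["d"].to_numpy(float),
    }
    X = [np.ones(len(summaries))]
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X.append(base[a] * base[b])
        else:
            X.append(base[term])
    return np.column_stack(X)


def _fit_ols(y: np.ndarray, X: np.ndarray):
    res = sm.OLS(y, X).fit()
    # AIC with k = regression coefficients + 1 for the error variance,
    # Gaussian lnL at the MLE variance (matches R's AIC for lm objects)
    aic = -2.0 * res.llf + 2.0 * (X.shape[1] + 1)
    return res, float(aic)


def _response_vector(summaries: pd.DataFrame, response: str) -> tuple[np.ndarray, np.ndarray]:
    """Response values plus a keep-mask dropping years where it is undefined.

    A year can lack a response (no clusters at all, or a single cluster has
    no size SD); such years are excluded from that response's regression,
    and the reported residual df shrinks accordingly.
    """
    if response == "log10_n_clusters":
        n = summaries["n_clusters"].to_numpy(float)
        keep = n > 0
        y = np.where(keep, np.log10(np.where(keep, n, 1.0)), np.nan)
    else:
        y = summaries[response].to_numpy(float)
        keep = np.isfinite(y)
    if not keep.all():
        dropped = summaries.loc[~keep, "year"].tolist()
        warnings.warn(
            f"response {response!r} undefined in year(s) {dropped}; dropped",
            stacklevel=3,
        )
    return y[keep], keep


def _droppable(terms: tuple[str, ...]) -> list[str]:
    kept_inter = [t for t in terms if ":" in t]
    out = []
    for t in terms:
        if ":" in t:
            out.append(t)
        elif not any(t in _MAIN_OF[i] for i in kept_inter):
            out.append(t)
    return out


def backward_aic(summaries: pd.DataFrame, response: str) -> ModelSelectionResult:
    """Backward AIC elimination over the clustering term set.

    Starts from the full model (intercept + log10 abundance + severity +
    duration + pairwise interactions) fit by ordinary least squares and
    repeatedly removes the term whose removal lowers AIC most, never
    removing a main effect while one of its interactions is retained,
    until no removal improves AIC.  Ties drop the higher-order term first,
    then lexicographically.  The reported F statistic compares the final
    model against the intercept-only model.
    """
    y, keep = _response_vector(summaries, response)
    summaries = summaries.loc[keep].reset_index(drop=True)
    if len(summaries) < 10:
        raise ValidationError("need at least 10 annual summaries with this response")
    terms = tuple(EQ2_TERMS)
    res, aic_full = _fit_ols(y, _design(summaries, terms))
    aic_cur = aic_full
    while terms:
        candidates = []
        for t in _droppable(terms):
            trial = tuple(x for x in terms if x != t)
            _, aic_t = _fit_ols(y, _design(summaries, trial))
            candidates.append((aic_t, 0 if ":" in t else 1, t))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        if candidates and candidates[0][0] < aic_cur:
            aic_cur = candidates[0][0]
            terms = tuple(x for x in terms if x != candidates[0][2])
        else:
            break

    X = _design(summaries, terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(f"collinear design for terms {terms}", stacklevel=2)
    res, aic_final = _fit_ols(y, X)
    names = ("intercept",) + terms
    coefs = dict(zip(names, map(float, res.params)))
    if terms:
        f_stat = float(res.fvalue)
        df = (int(res.df_model), int(res.df_resid))
        p_value = float(res.f_pvalue)
    else:
        f_stat = df = p_value = None
    return ModelSelectionResult(
        response=response,
        retained_terms=terms,
        aic_null=aic_full,
        aic_final=aic_final,
        delta_aic=aic_full - aic_final,
        f_stat=f_stat,
        df=df,
        p_value=p_value,
        coefficients=coefs,
    )


#: the five clustering responses reported for the model-selection table
TABLE_RESPONSES = (
    "prop_warm",
    "prop_solitary",
    "log10_n_clusters",
    "mean_size",
    "sd_size",
)


def model_selection_table(summaries: pd.DataFrame) -> list[ModelSelectionResult]:
    """Backward AIC selection for every clustering response."""
    return [backward_aic(summaries, resp) for resp in TABLE_RESPONSES]


# ---------------------------------------------------------------------------
# solitary-fraction intercept test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolitaryTest:
    mean: float
    t: float
    df: int
    p_value: float
    degenerate: bool


def solitary_intercept_test(summaries: pd.DataFrame) -> SolitaryTest:
    """One-sample t test of the annual solitary proportions against zero.

    Equivalent to the intercept of an intercept-only least-squares model:
    t = mean / (sd / sqrt(m)) on m - 1 degrees of freedom.
    """
    p = summaries["prop_solitary"].to_numpy(float)
    m = len(p)
    if m < 3:
        raise ValidationError("need at least 3 years")
    mean = float(p.mean())
    sd = float(p.std(ddof=1))
    if sd == 0:
        return SolitaryTest(mean=mean, t=float("nan"), df=m - 1, p_value=float("nan"),
                            degenerate=True)
    t = mean / (sd / np.sqrt(m))
    return SolitaryTest(
        mean=mean, t=float(t), df=m - 1,
        p_value=float(2 * stats.t.sf(abs(t), m - 1)), degenerate=False,
    )


# ---------------------------------------------------------------------------
# nested likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRTResult:
    """Nested likelihood-ratio comparison of least-squares line models.

    ``df`` counts the mean-parameter difference (two per extra line), the
    convention long-term monitoring reports print.  Because every
    least-squares log-likelihood is evaluated at its own MLE variance, the
    alternative model in fact also frees one variance per group;
    ``df_full`` counts those too and is the reference that calibrates the
    test under the null, so ``p_value`` is computed from it, after an
    exact-mean Bartlett correction for finite per-group sample sizes.
    """

    statistic: float
    df: int
    df_full: int
    p_value: float
    groups: tuple[str, ...]


def _bartlett_factor(group_sizes: list[int], p: int = 2) -> float:
    """Exact-mean Bartlett correction for the line-comparison LR statistic.

    The statistic is T = m ln(RSS_0/m) - sum_g m_g ln(RSS_g/m_g).  Under the
    null each RSS is marginally sigma^2 * chi2 with m - p degrees of
    freedom, and E[ln chi2_nu] = ln 2 + psi(nu/2), so E[T] follows in
    closed form.  Dividing T by E[T]/df restores the nominal chi-square
    calibration at small per-group sample sizes.
    """
    from scipy.special import digamma

    m = int(sum(group_sizes))

    def mean_mlog(mm: int) -> float:
        nu = max(mm - p, 1)
        return mm * (np.log(2.0) + digamma(nu / 2.0) - np.log(mm))

    expected = mean_mlog(m) - sum(mean_mlog(mg) for mg in group_sizes)
    df = 3 * (len(group_sizes) - 1)
    if df <= 0 or expected <= 0:
        return 1.0
    return expected / df


def _line_lnl(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian log-likelihood of a least-squares line at the MLE variance."""
    m = len(y)
    if m == 0:
        return 0.0
    if m >= 2 and np.ptp(x) > 0:
        X = np.column_stack([np.ones(m), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    else:
        resid = y - y.mean()
    s2 = max(float(resid @ resid) / m, 1e-12)
    return -0.5 * m * (np.log(2.0 * np.pi * s2) + 1.0)


def _lrt_inputs(
    clusters: pd.DataFrame,
    abundance_by_year,
    log10_abundance: bool,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    abun = dict(abundance_by_year)
    missing = sorted(set(clusters["year"]) - set(abun))
    if missing:
        raise ValidationError(f"no abundance value for year(s) {missing}")
    x = clusters["year"].map(abun).to_numpy(float)
    if log10_abundance:
        x = np.log10(x)
    y = clusters["size"].to_numpy(float)
    return x, y, clusters["section"]


def _fold_small_sections(sections: pd.Series, min_clusters: int) -> pd.Series:
    counts = sections.value_counts()
    small = set(counts[counts < min_clusters].index)
    if small:
        warnings.warn(
            f"section(s) with fewer than {min_clusters} clusters folded into a "
            f"pooled remainder: {sorted(small)}",
            stacklevel=3,
        )
        sections = sections.where(~sections.isin(small), "pooled remainder")
    return sections


def spatial_lrt(
    clusters: pd.DataFrame,
    abundance_by_year,
    log10_abundance: bool = False,
    min_clusters: int = 3,
) -> LRTResult:
    """LRT for section-specific cluster-size vs abundance lines.

    Null: one pooled least-squares line of cluster size on annual
    abundance.  Alternative: an independent line per cave section (each
    contributing two mean parameters; variances are profiled out, giving
    df = 2*(number of sections) - 2).  Sections with fewer than
    ``min_clusters`` records are folded into a pooled remainder.
    """
    x, y, sections = _lrt_inputs(clusters, abundance_by_year, log10_abundance)
    sections = _fold_small_sections(sections, min_clusters)
    groups = tuple(sorted(sections.unique()))
    lnl_null = _line_lnl(x, y)
    lnl_alt = sum(
        _line_lnl(x[(sections == g).to_numpy()], y[(sections == g).to_numpy()])
        for g in groups
    )
    stat = max(0.0, -2.0 * (lnl_null - lnl_alt))
    df = 2 * (len(groups) - 1)
    df_full = 3 * (len(groups) - 1)
    if df_full > 0:
        sizes = [int((sections == g).sum()) for g in groups]
        p = float(stats.chi2.sf(stat / _bartlett_factor(sizes), df_full))
    else:
        p = 1.0
    return LRTResult(statistic=float(stat), df=df, df_full=df_full, p_value=p,
                     groups=groups)


def giant_pots_lrt(
    clusters: pd.DataFrame,
    abundance_by_year,
    focal_section: str = "Giant Pots",
    log10_abundance: bool = False,
    min_clusters: int = 3,
) -> LRTResult:
    """LRT for a distinct cluster-size/abundance line in one focal section.

    Alternative: one line for the focal section plus one pooled line for
    all other sections; null: a single pooled line.  df = 2.
    """
    x, y, sections = _lrt_inputs(clusters, abundance_by_year, log10_abundance)
    focal = (sections == focal_section).to_numpy()
    if focal.sum() < min_clusters:
        raise ValidationError(
            f"{focal_section!r} has fewer than {min_clusters} cluster records"
        )
    lnl_null = _line_lnl(x, y)
    lnl_alt = _line_lnl(x[focal], y[focal]) + _line_lnl(x[~focal], y[~focal])
    stat = max(0.0, -2.0 * (lnl_null - lnl_alt))
    factor = _bartlett_factor([int(focal.sum()), int((~focal).sum())])
    return LRTResult(
        statistic=float(stat), df=2, df_full=3,
        p_value=float(stats.chi2.sf(stat / factor, 3)),
        groups=(focal_section, "other"),
    )
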