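"""Exponential population growth corrected for winter severity and duration.

The census model is exponential growth

    n_hat(t) = a * b**(t - c),        g = (b - 1) * 100   [% per year]

with ``c`` an anchor year (1977 by default) so ``a`` is the expected count
in the anchor year.  Observed annual counts ``n_t`` enter a composite
log-likelihood

    lnL(n | t, w, d) = lnL(n | t) + lnL(r | t, w, d)

whose first term is the Poisson log-probability of the counts given
``n_hat`` and whose second term scores the absolute residuals
``r_t = |n_t - n_hat_t|`` under a normal density with mean given by a
linear winter-severity model ``r_hat_w = a_w + b_w * w_t`` and standard
deviation given by a linear winter-duration model
``r_hat_d = a_d + b_d * d_t``.  The duration line is fixed in advance from
the residuals of a plain least-squares growth fit; ``(a, b, a_w, b_w)``
are then co-estimated by maximising the composite likelihood.  Confidence
intervals come from likelihood profiles with the chi-square(1) 95% cutoff.

Observations are held in a DataFrame with columns ``t`` (calendar year),
``n`` (count), ``w`` (AWSSI at the survey date) and ``d`` (winter duration
in days at the survey date).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import FitError, ValidationError

CHI2_1_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207...
SCALE_FLOOR = 1e-6

OBS_COLUMNS = ("t", "n", "w", "d")


def _as_obs(obs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValidationError(f"observation table lacks columns {missing}")
    if (obs["n"] < 0).any():
        raise ValidationError("counts must be non-negative")
    if not np.allclose(obs["n"], np.round(obs["n"])):
        raise ValidationError("counts must be integers")
    return obs


@dataclass(frozen=True)
class GrowthParams:
    """Exponential growth curve n_hat = a * b**(t - c)."""

    a: float
    b: float
    c: int = 1977

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("growth parameters a, b must be positive")


@dataclass(frozen=True)
class SeverityResidualModel:
    """Expected absolute residual as a line in winter severity: a_w + b_w * w."""

    a_w: float
    b_w: float

    def predict(self, w):
        return self.a_w + self.b_w * np.asarray(w, float)


@dataclass(frozen=True)
class DurationResidualModel:
    """Residual scale as a line in winter duration: a_d + b_d * d (floored)."""

    a_d: float
    b_d: float

    def predict(self, d):
        return np.maximum(self.a_d + self.b_d * np.asarray(d, float), SCALE_FLOOR)


def predict_abundance(params: GrowthParams, t) -> np.ndarray | float:
    """Expected count a * b**(t - c) for one year or an array of years."""
    t = np.asarray(t, float)
    out = params.a * params.b ** (t - params.c)
    return float(out) if out.ndim == 0 else out


def growth_rate(params: GrowthParams) -> float:
    """Annual growth rate in percent, g = (b - 1) * 100."""
    return (params.b - 1.0) * 100.0


# ---------------------------------------------------------------------------
# likelihood components
# ---------------------------------------------------------------------------

def lnL_counts(obs: pd.DataFrame, params: GrowthParams) -> float:
    """Poisson log-likelihood of the observed counts under the growth curve.

    sum_t [ n_t * ln n_hat_t - n_hat_t - ln(n_t!) ], with the factorial via
    log-gamma.
    """
    obs = _as_obs(obs)
    n = obs["n"].to_numpy(float)
    mu = predict_abundance(params, obs["t"].to_numpy(float))
    return float(np.sum(n * np.log(mu) - mu - special.gammaln(n + 1.0)))


def lnL_residuals(
    obs: pd.DataFrame,
    params: GrowthParams,
    sev_model: SeverityResidualModel,
    dur_model: DurationResidualModel,
    strict_typo: bool = False,
) -> float:
    """Normal log-likelihood of absolute growth-curve residuals.

    Residuals r_t = |n_t - n_hat_t| are scored under N(mean = a_w + b_w*w_t,
    sd = a_d + b_d*d_t), the scale floored at a small positive constant.
    ``strict_typo=True`` reproduces, for forensic comparison only, the
    printed normalisation 1/sqrt(2*r_hat_w*sd^2) in place of the standard
    normal constant.
    """
    obs = _as_obs(obs)
    n = obs["n"].to_numpy(float)
    r = np.abs(n - predict_abundance(params, obs["t"].to_numpy(float)))
    mean = sev_model.predict(obs["w"].to_numpy(float))
    sd = dur_model.predict(obs["d"].to_numpy(float))
    z2 = (r - mean) ** 2 / (2.0 * sd**2)
    if strict_typo:
        norm_arg = 2.0 * mean * sd**2
        if np.any(norm_arg <= 0):
            return -np.inf
        return float(np.sum(-0.5 * np.log(norm_arg) - z2))
    return float(np.sum(-0.5 * np.log(2.0 * np.pi * sd**2) - z2))


def total_lnL(
    obs: pd.DataFrame,
    params: GrowthParams,
    sev_model: SeverityResidualModel,
    dur_model: DurationResidualModel,
) -> float:
    """Composite log-likelihood: Poisson count term + residual term."""
    return lnL_counts(obs, params) + lnL_residuals(obs, params, sev_model, dur_model)


# ---------------------------------------------------------------------------
# least-squares fit and the fixed duration line
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LSGrowthFit:
    params: GrowthParams
    g: float
    g_ci95: tuple[float, float]
    se_b: float
    cov: np.ndarray = field(repr=False)


def fit_growth_ls(obs: pd.DataFrame, c: int = 1977, log_scale: bool = False) -> LSGrowthFit:
    """Nonlinear least squares of n on a*b**(t-c).

    The 95% CI for g uses the delta method on the asymptotic covariance of
    b (g is linear in b, so the interval is b +/- 1.96*SE scaled by 100).
    ``log_scale=True`` instead fits the log-linear regression
    ln n = ln a + (t-c) ln b by ordinary least squares (zero counts excluded).
    """
    obs = _as_obs(obs)
    if len(obs) < 3:
        raise ValidationError("need at least 3 observations")
    t = obs["t"].to_numpy(float)
    n = obs["n"].to_numpy(float)

    if log_scale:
        keep = n > 0
        X = np.column_stack([np.ones(keep.sum()), t[keep] - c])
        y = np.log(n[keep])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (keep.sum() - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        a_hat, b_hat = float(np.exp(beta[0])), float(np.exp(beta[1]))
        se_b = float(b_hat * np.sqrt(cov[1, 1]))  # delta method through exp
    else:
        # log-linear start keeps curve_fit away from the flat region
        pos = n > 0
        slope0, inter0 = np.polyfit(t[pos] - c, np.log(n[pos]), 1)
        p0 = (max(np.exp(inter0), 1e-3), np.exp(slope0))
        try:
            popt, pcov = optimize.curve_fit(
                lambda tt, a, b: a * b ** (tt - c), t, n, p0=p0, maxfev=20000
            )
        except RuntimeError as e:  # pragma: no cover - pathological inputs
            raise FitError(f"least-squares growth fit did not converge: {e}") from e
        a_hat, b_hat = float(popt[0]), float(popt[1])
        cov = pcov
        se_b = float(np.sqrt(pcov[1, 1]))
        if not np.isfinite(se_b):
            raise FitError("singular covariance in least-squares growth fit")

    params = GrowthParams(a=a_hat, b=b_hat, c=c)
    g = growth_rate(params)
    half = 1.959963984540054 * 100.0 * se_b
    return LSGrowthFit(
        params=params, g=g, g_ci95=(g - half, g + half), se_b=se_b,
        cov=np.asarray(cov),
    )


def fix_duration_model(obs: pd.DataFrame, ls_params: GrowthParams) -> DurationResidualModel:
    """OLS of absolute least-squares residuals on winter duration.

    The resulting (a_d, b_d) line is held fixed during the maximum
    likelihood search to reduce its dimensionality.
    """
    obs = _as_obs(obs)
    d = obs["d"].to_numpy(float)
    if np.ptp(d) == 0:
        raise ValidationError("winter duration is constant; duration line is rank-deficient")
    r = np.abs(obs["n"].to_numpy(float) - predict_abundance(ls_params, obs["t"].to_numpy(float)))
    b_d, a_d = np.polyfit(d, r, 1)
    return DurationResidualModel(a_d=float(a_d), b_d=float(b_d))


def fit_severity_line(obs: pd.DataFrame, params: GrowthParams) -> SeverityResidualModel:
    """OLS of absolute residuals on winter severity (used as an ML start)."""
    obs = _as_obs(obs)
    w = obs["w"].to_numpy(float)
    r = np.abs(obs["n"].to_numpy(float) - predict_abundance(params, obs["t"].to_numpy(float)))
    if np.ptp(w) == 0:
        return SeverityResidualModel(a_w=float(r.mean()), b_w=0.0)
    b_w, a_w = np.polyfit(w, r, 1)
    return SeverityResidualModel(a_w=float(a_w), b_w=float(b_w))


# ---------------------------------------------------------------------------
# maximum likelihood fit
# ---------------------------------------------------------------------------

PARAM_NAMES = ("a", "b", "a_w", "b_w")


@dataclass
class GrowthFit:
    """Maximum-likelihood growth fit with profiles and intervals."""

    params: GrowthParams
    sev_model: SeverityResidualModel
    dur_model: DurationResidualModel
    lnl_max: float
    g: float
    se: dict[str, float] = field(default_factory=dict)
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    g_ci95: tuple[float, float] | None = None

    def theta(self) -> np.ndarray:
        return np.array(
            [self.params.a, self.params.b, self.sev_model.a_w, self.sev_model.b_w]
        )


def _make_lnl(obs: pd.DataFrame, dur_model: DurationResidualModel, c: int):
    """Fast closure over validated arrays for optimiser-internal evaluation.

    Equivalent to :func:`total_lnL` (asserted in the test suite) but skips
    per-call validation and object construction.
    """
    obs = _as_obs(obs)
    n = obs["n"].to_numpy(float)
    tc = obs["t"].to_numpy(float) - c
    w = obs["w"].to_numpy(float)
    sd = dur_model.predict(obs["d"].to_numpy(float))
    lgam = special.gammaln(n + 1.0)
    log_norm = -0.5 * np.log(2.0 * np.pi * sd**2)

    def lnl(theta: np.ndarray) -> float:
        a, b, a_w, b_w = theta
        if a <= 0 or b <= 0:
            return -np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            mu = a * b ** tc
            pois = np.sum(n * np.log(mu) - mu - lgam)
            r = np.abs(n - mu)
            resid = np.sum(log_norm - (r - (a_w + b_w * w)) ** 2 / (2.0 * sd**2))
            val = pois + resid
        return float(val) if np.isfinite(val) else -np.inf

    return lnl


def _lnl_theta(theta: np.ndarray, obs: pd.DataFrame, dur_model: DurationResidualModel,
               c: int) -> float:
    return _make_lnl(obs, dur_model, c)(np.asarray(theta, float))


def _minimize(fun, x0):
    return optimize.minimize(
        fun, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 20000, "maxfev": 20000},
    )


def fit_growth_ml(
    obs: pd.DataFrame,
    dur_model: DurationResidualModel | None = None,
    start: np.ndarray | None = None,
    c: int = 1977,
) -> GrowthFit:
    """Maximise the composite likelihood over (a, b, a_w, b_w).

    Derivative-free Nelder-Mead from a deterministic grid of eight starts
    spanning a in [n_first/2, 2*n_first] and b in [1.0, 1.3]; the
    severity line is started at its OLS estimate against least-squares
    residuals.  When ``dur_model`` is omitted it is fixed from the
    least-squares fit first.
    """
    obs = _as_obs(obs).sort_values("t").reset_index(drop=True)
    ls = fit_growth_ls(obs, c=c)
    if dur_model is None:
        dur_model = fix_duration_model(obs, ls.params)
    sev0 = fit_severity_line(obs, ls.params)

    n_first = max(float(obs["n"].iloc[0]), 1.0)
    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(np.asarray(start, float))
    starts.append(np.array([ls.params.a, ls.params.b, sev0.a_w, sev0.b_w]))
    for a0 in (0.5 * n_first, 2.0 * n_first):
        for b0 in (1.0, 1.1, 1.2, 1.3):
            starts.append(np.array([a0, b0, sev0.a_w, sev0.b_w]))

    fun = _make_lnl(obs, dur_model, c)
    neg = lambda th: -fun(th)
    best = None
    for x0 in starts:
        res = _minimize(neg, x0)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("maximum likelihood growth fit did not converge")

    a, b, a_w, b_w = best.x
    fit = GrowthFit(
        params=GrowthParams(a=float(a), b=float(b), c=c),
        sev_model=SeverityResidualModel(a_w=float(a_w), b_w=float(b_w)),
        dur_model=dur_model,
        lnl_max=float(-best.fun),
        g=float((b - 1.0) * 100.0),
    )
    fit.se = _asymptotic_se(fit, obs)
    return fit


def _asymptotic_se(fit: GrowthFit, obs: pd.DataFrame) -> dict[str, float]:
    """SEs from a finite-difference Hessian of the composite lnL at the MLE."""
    theta = fit.theta()
    f = _make_lnl(obs, fit.dur_model, fit.params.c)
    k = len(theta)
    h = np.maximum(np.abs(theta), 1.0) * 1e-4
    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    se = {}
    try:
        cov = np.linalg.inv(-H)
        diag = np.diag(cov)
        for name, v in zip(PARAM_NAMES, diag):
            se[name] = float(np.sqrt(v)) if v > 0 else float("nan")
    except np.linalg.LinAlgError:
        se = {name: float("nan") for name in PARAM_NAMES}
    return se


# ---------------------------------------------------------------------------
# profile likelihood intervals
# ---------------------------------------------------------------------------

def profile_interval(
    lnl_fun,
    theta_hat: np.ndarray,
    index: int,
    lnl_max: float | None = None,
    se: float | None = None,
    n_grid: int = 201,
    span_se: float = 5.0,
    max_widen: int = 4,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Profile one coordinate of an arbitrary log-likelihood.

    For every grid value of coordinate ``index`` the remaining coordinates
    are re-maximised (Nelder-Mead warm-started from the running optimum);
    the 95% interval is where the profile stays within chi2(1)/2 = 1.9207
    of the maximum, endpoints interpolated linearly between grid points.
    The grid spans ``span_se`` estimated standard errors each side and is
    widened automatically when the profile has not dropped below the
    cutoff at a boundary.

    Returns ``((lo, hi), profile)`` with the profile as a DataFrame of
    grid values and profile log-likelihoods.  Open endpoints (still above
    the cutoff after widening) are reported as -inf/inf with a warning.
    """
    theta_hat = np.asarray(theta_hat, float)
    if lnl_max is None:
        lnl_max = lnl_fun(theta_hat)
    if se is None or not np.isfinite(se) or se <= 0:
        se = max(abs(theta_hat[index]) * 0.1, 1e-3)
    cutoff = lnl_max - CHI2_1_95_HALF
    free = [i for i in range(len(theta_hat)) if i != index]

    def profile_at(value: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        if not free:
            th = theta_hat.copy(); th[index] = value
            return lnl_fun(th), th
        def neg(sub):
            th = theta_hat.copy()
            th[index] = value
            th[free] = sub
            v = lnl_fun(th)
            return -v if np.isfinite(v) else 1e300
        res = _minimize(neg, warm[free])
        th = theta_hat.copy(); th[index] = value; th[free] = res.x
        return -res.fun, th

    span = span_se * se
    for _ in range(max_widen + 1):
        grid = np.linspace(theta_hat[index] - span, theta_hat[index] + span, n_grid)
        # walk outwards from the MLE on each side, warm-starting
        order = np.argsort(np.abs(grid - theta_hat[index]), kind="stable")
        prof = np.full(n_grid, np.nan)
        warm_lo = warm_hi = theta_hat
        for gi in order:
            warm = warm_lo if grid[gi] <= theta_hat[index] else warm_hi
            val, th = profile_at(grid[gi], warm)
            prof[gi] = val
            if grid[gi] <= theta_hat[index]:
                warm_lo = th
            else:
                warm_hi = th
        if prof[0] < cutoff and prof[-1] < cutoff:
            break
        span *= 2.0
    profile = pd.DataFrame({"value": grid, "lnl": prof})

    def crossing(side: int) -> float:
        idx = np.arange(n_grid) if side > 0 else np.arange(n_grid)[::-1]
        prev = None
        for gi in idx:
            if grid[gi] * side < theta_hat[index] * side:
                continue
            if prof[gi] < cutoff and prev is not None:
                x0, y0 = grid[prev], prof[prev]
                x1, y1 = grid[gi], prof[gi]
                if y1 == y0:
                    return x1
                return float(x0 + (cutoff - y0) * (x1 - x0) / (y1 - y0))
            prev = gi
        warnings.warn("profile CI endpoint outside grid; interval is open", stacklevel=3)
        return float("inf") if side > 0 else float("-inf")

    return (crossing(-1), crossing(+1)), profile


def profile_ci(
    obs: pd.DataFrame,
    fit: GrowthFit,
    param_name: str,
    n_grid: int = 201,
    span_se: float = 5.0,
) -> tuple[float, float]:
    """95% profile-likelihood interval for one growth-model parameter.

    The interval and the profile curve are stored on ``fit`` (``ci95`` and
    ``profiles``); for ``b`` the growth-rate interval ``g_ci95`` is filled
    in as well.
    """
    obs = _as_obs(obs)
    index = PARAM_NAMES.index(param_name)
    fun = _make_lnl(obs, fit.dur_model, fit.params.c)
    se = fit.se.get(param_name)
    (lo, hi), profile = profile_interval(
        fun, fit.theta(), index, lnl_max=fit.lnl_max, se=se,
        n_grid=n_grid, span_se=span_se,
    )
    fit.ci95[param_name] = (lo, hi)
    fit.profiles[param_name] = profile
    if param_name == "b":
        fit.g_ci95 = ((lo - 1.0) * 100.0, (hi - 1.0) * 100.0)
    return lo, hi
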