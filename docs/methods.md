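# Methods

This note documents the models implemented in `batdyn`, the assumptions
behind them, the numerical and design choices that were genuinely open,
and the limitations a user should know before trusting output on real
data. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Winter severity (AWSSI)

Winter boundaries follow the accumulated winter season severity index
rules: the season starts on the earliest day with daily maximum
temperature ≤ 0 °C or snow depth ≥ 0.25 cm, and no later than
1 December; it ends on the latest day with maximum temperature ≤ 0 °C,
snowfall ≥ 0.25 cm or snow depth ≥ 2.5 cm, and no earlier than 1 March.
A season is assigned to the 1 July – 30 June window around it, which
makes December-starting winters unambiguous. Between the boundaries each
day earns points from banded scoring tables — separately for the daily
maximum and minimum temperature and for snowfall and standing snow
depth — and the running point total is the index. The severity at a
survey date `w` is the total accumulated through that date (inclusive);
the duration `d` is the whole-day count from the season onset to the
survey date, so a survey on the onset day has d = 0.

**Point tables.** The daily point tables are shipped as
`src/batdyn/awssi_tables.yaml` and can be replaced via
`ScoreTables.from_yaml(path)` (or `--score-tables` on the command line).
The default is a metric adaptation of the conventional Fahrenheit/inch
bands (≈ 2.8 °C temperature steps below freezing, snowfall and depth
bands converted at 2.54 cm/in). Season totals are sensitive to edge-band
choices, which is exactly why the tables are configuration rather than
code: two users can agree on the engine while disagreeing on the scoring.

**Missing data.** Missing temperatures are imputed by predictive mean
matching: each field is regressed on day-of-year harmonics (annual and
semi-annual sine/cosine) plus the other two temperature fields
(provisionally completed from harmonics alone), and each missing value is
replaced by the observed value of a donor day drawn uniformly from the
five days (configurable) with the nearest regression predictions. The
draw is deterministic given a seed. The ordering tmin ≤ tavg ≤ tmax is
enforced after imputation: a violating draw is replaced by the nearest
admissible donor, falling back to the midpoint of the admissible
interval. Missing precipitation is set to zero (conservative: it can
only under-score a winter). Missing snow depth is filled by a
carry-forward water balance, depth(t) = max(0, depth(t−1) + snowfall(t)
− melt(t)), with melt proportional to positive mean temperature
(default 2 cm per positive degree-day). Snowfall, where not observed, is
estimated as precipitation × the 10:1 snow-to-liquid ratio on days whose
mean temperature is ≤ 0 °C, zero otherwise; both the threshold and the
ratio sit in the score-table configuration.

## Exponential growth with severity-linked residuals

Counts are modelled as n̂(t) = a·b^(t−c) with anchor year c (default
1977), so `a` is the expected count in the anchor year, `b` the annual
multiplier and g = (b − 1)·100 the percentage growth rate. The composite
log-likelihood is the sum of

- a Poisson term, Σ_t [n_t ln n̂_t − n̂_t − ln n_t!], computed with
  log-gamma; and
- a normal term on the absolute residuals r_t = |n_t − n̂_t|, with mean
  r̂_w = a_w + b_w·w_t (the winter-severity line, co-estimated) and
  standard deviation r̂_d = a_d + b_d·d_t (the winter-duration line).

The duration line is fixed before the likelihood search by ordinary least
squares of the absolute residuals of a plain nonlinear least-squares
growth fit on d — this halves the dimensionality of the search, at the
price of conditioning on the least-squares fit. Residuals inside the
search are recomputed from the current candidate (a, b), not frozen.

Numerical choices:

- The residual scale r̂_d is floored at 1e−6 so the density stays proper
  when the fitted duration line crosses zero inside the observed range.
- The normal term uses the standard normalisation 1/√(2π·r̂_d²). A
  `strict_typo` flag reproduces, for forensic comparison only, the
  variant normalisation 1/√(2·r̂_w·r̂_d²) that sometimes appears in
  print; it is not a proper density and is never used in fitting.
- Scoring |residuals| with an ordinary (not folded) normal density is
  statistically unconventional but implemented as such deliberately; see
  the calibration limitation below.
- Maximisation is Nelder–Mead (xatol = fatol = 1e−8) from nine
  deterministic starts: the least-squares solution plus a grid of
  a ∈ {n₁/2, 2n₁} × b ∈ {1.0, 1.1, 1.2, 1.3}, with the severity line
  started at its OLS estimate. The best converged start wins, so the fit
  is reproducible without randomness.
- The least-squares comparison fit is raw-scale nonlinear least squares
  (counts on curve), matching the exponential model as written; a
  log-scale OLS variant is available (`log_scale=True`) because the two
  can disagree noticeably on fast-growing series. Its 95% CI for g uses
  the delta method on the asymptotic covariance of b (g is linear in b).

**Profile likelihood intervals.** For a focal parameter the remaining
parameters are re-maximised on a grid (default 201 points spanning ±5
estimated standard errors, widened automatically while the profile has
not crossed the cutoff at a boundary), and the 95% interval is the region
where the profile stays within χ²₁(0.95)/2 = 1.9207 of the maximum,
endpoints interpolated linearly between grid points. The machinery is
generic (`profile_interval` accepts any log-likelihood callable) and is
validated in the suite against the closed-form interval of an exact
Gaussian likelihood. Standard errors used to scale the grid come from a
finite-difference Hessian at the optimum. Recovery and coverage
experiments use a coarser 21-point grid over ±4 SE to keep 200-replicate
runs fast; the interpolation error this introduces is small relative to
the effects being measured.

**Calibration limitation (important).** The composite likelihood scores
every observation twice: once as a Poisson count and once through the
normal density of its absolute residual. The two terms are not a joint
probability model — no generative law has both margins — so the curvature
of the composite log-likelihood overstates the information in the data
and the profile intervals are systematically too short under any
generator we can write down. `scripts/acceptance.py` quantifies this:
the recovery experiment's median growth-rate estimate is nearly unbiased,
while nominal-95% profile intervals for b cover the truth well below 95%
under the default generator. The same machinery applied to the Poisson
term alone is calibrated (checked in the suite), which localises the
shortfall in the model structure, not the optimiser or profiler. Users
should treat the ML point estimate as the headline result and regard its
profile CI as an optimistic lower bound on uncertainty; the least-squares
CI is the more honest interval for the uncorrected trend.

## Clustering behaviour

A cluster record is (year, cave section, size), size 1 being a solitary
bat. Sections carry a fixed thermal classification: the Hall, German
Gallery and Giant Pots are thermally unstable ("cold"), the Bruna Cave
and Main Corridor thermally stable ("warm"). Annual summaries weight the
warm and solitary proportions by individuals. "Clusters" require at
least two touching bats by default, so solitary records are excluded from
the cluster count, mean and SD (but counted in totals and the solitary
proportion); a `count_solitary_as_cluster` switch flips this convention,
which visibly changes the model-selection responses. Years in which a
response is undefined (no clusters, or a single cluster with no size SD)
are dropped from that response's regression with a warning, and the
reported degrees of freedom shrink accordingly — the code never assumes a
fixed number of usable years.

**Model selection.** Each clustering response is regressed by OLS on
log₁₀ n, w, d and their three pairwise interactions. Backward
elimination removes, at each step, the term whose removal lowers AIC
most, never removing a main effect while one of its interactions remains
(marginality); ties drop the higher-order term first, then
lexicographically, so the search is deterministic. AIC is computed as
2k − 2lnL with the Gaussian log-likelihood at the MLE variance and k
counting the regression coefficients plus one for the variance — the
convention of R's `AIC()` for linear models, which yields the familiar
negative AICs for proportion responses. The reported F statistic
compares the final model to the intercept-only model. Proportions are
analysed untransformed; only the number of clusters is log₁₀-transformed,
as its response name says. Under pure noise this procedure retains some
term in most replicates — AIC keeps any given noise term with probability
near P(χ²₁ > 2) ≈ 0.16 — so an intercept-only outcome is the single most
common, but not the dominant, result; the suite asserts exactly that.

**Solitary fraction.** The overall solitary fraction is tested with the
intercept-only least-squares model of the annual proportions, equivalent
to a one-sample t statistic mean/(sd/√m) on m − 1 df; constant
proportions are flagged degenerate rather than reported as t = ∞.

**Spatial likelihood-ratio tests.** Cluster size is regressed on annual
abundance (raw scale by default, log₁₀ by option). The null model is one
pooled least-squares line; the alternative fits an independent line per
cave section (or: one line for the Giant Pots and one for everything
else). Each least-squares fit contributes its Gaussian log-likelihood at
the MLE variance RSS/m, and the statistic is −2(lnL_null − Σ lnL_groups).
Sections with fewer than three records are folded into a pooled remainder
with a warning. Two degree-of-freedom counts are reported: `df`
(two mean parameters per extra line — the convention such statistics are
usually printed with, 8 for five sections and 2 for the focal-section
test) and `df_full` (adding one variance per extra group, 3·(G−1)),
which is the reference that actually calibrates the statistic, because
evaluating each group's likelihood at its own MLE variance frees those
variances too. P-values use `df_full` after an exact-mean Bartlett
correction: under the null each RSS is marginally σ²·χ² with known
degrees of freedom, so E[T] has a closed form through the digamma
function, and T is scaled by df_full/E[T] before the χ² tail is taken.
The acceptance script verifies that both tests then reject a true null at
close to the nominal 5%.

## Synthetic data generator

The generator produces a complete desk-scale study: daily weather,
annual survey counts and per-cluster records, all driven by one seeded
`numpy` Generator per stage (byte-identical outputs for a fixed seed).

What it emulates, and the defaults: a 42-year study (1977–2018) in a
temperate Central European climate (annual mean 9 °C, seasonal amplitude
10.5 °C, AR(1) day-to-day noise, occasional precipitation falling as snow
on cold days, 5% missing observations); exponential growth at 10 %/yr
from 8 animals (a = 8, b = 1.10), censused each 20 February; residual
magnitude rising with winter severity (a_w = 10, b_w = 0.02 per AWSSI
point) and residual spread rising with winter duration (a_d = 2,
b_d = 0.05 per day) — magnitudes chosen so that typical residuals are
tens of animals against counts growing from 8 to ~400, matching the
visual scatter of long-term hibernaculum series; a stable solitary
fraction of 0.136; cluster mean size rising with log₁₀ abundance from
about 4 to about 10 over the observed range; warm-section use rising
with abundance through a logistic link; and a preference of the largest
cold-section clusters for the Giant Pots. Cluster sizes are drawn as
2 + a negative-binomial excess and adjusted so they sum exactly to the
year's census count — conservation is exact by construction.

What it does not emulate: real station weather statistics (no fronts,
no elevation effects, no multi-station structure), true bat demography
(no births/deaths/immigration, no density dependence), disease dynamics,
or observation error in the counts themselves. Passing tests on this
generator therefore show that the estimators recover the structure they
assume; they cannot show that real censuses satisfy those assumptions.

One structural caveat is inherited from the model: the composite
likelihood's residual law has no coherent generative counterpart, so the
generator injects residual magnitude by replacing the Poisson deviation
of each year with a zero-clipped normal draw of the modelled mean and
scale, keeping the Poisson sign. The clipping slightly shrinks the
realised mean when the severity line is small relative to the duration
scale, and the injected counts are overdispersed relative to the Poisson
term — which is precisely the regime in which the composite likelihood's
intervals undercover (see above).

## Experiment sizes

The recovery experiment uses 200 replicated 42-year series and profiles
only b (21-point grid); the LRT null calibration uses 500 simulations of
300 records across 35 years; the model-selection null behaviour is
checked on 100 replicates. These sizes put Monte-Carlo error comfortably
below the effects being asserted while keeping a full run of the suite
and the acceptance script in the low minutes on a single core.

## Known limitations

- Profile CIs from the composite likelihood are anti-conservative
  (documented and measured above); the point estimates are fine.
- The AWSSI point tables are a metric adaptation; absolute season totals
  are configuration-dependent, and only within-configuration comparisons
  are meaningful.
- Whether the survey day itself is counted inside d (inclusive here) and
  whether LRT abundance is raw or log₁₀ (raw by default) are conventions,
  both exposed as options because printed statistics shift with them.
- The imputation model assumes a smooth seasonal cycle plus same-day
  cross-field information; it will underperform on series with abrupt
  inhomogeneities (station moves, instrument changes), which the package
  deliberately does not attempt to detect.
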