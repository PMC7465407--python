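# batdyn

Winter-severity-corrected population growth and clustering analysis for
long-term censuses of hibernating bats.

Annual winter counts of bats in underground hibernacula are one of the few
practical windows on bat population trends, but each count is a snapshot
taken on one day of one winter: how far into winter the survey falls and
how harsh that winter has been both move the number of animals actually
present and visible. `batdyn` is a toolkit for analysing such series. It
is written for ecologists and biostatisticians working with multi-decade
hibernaculum monitoring data (one census per winter, plus per-cluster
roost records) and for anyone who wants to stress-test this class of
model on synthetic data.

The package provides four analysis layers behind one `batdyn` command:

1. **Winter severity** (`batdyn.weather`) — delimits each winter season
   and accumulates the Accumulated Winter Season Severity Index (AWSSI)
   from daily weather records (GHCN-Daily-style CSV), including
   predictive-mean-matching imputation of missing temperatures,
   conservative zero-fill of missing precipitation, snowfall estimation
   from temperature and precipitation, and accumulation/melt filling of
   missing snow depth. The daily point tables are shipped as an editable
   YAML configuration.
2. **Growth likelihood** (`batdyn.growth`) — fits exponential population
   growth n̂ = a·bᵗ⁻ᶜ to annual counts n_t by maximising the composite
   log-likelihood

   ln L(n | t, w, d) = ln L(n | t) + ln L(r | t, w, d),

   the sum of a Poisson term for the counts and a normal term for the
   absolute residuals r_t = |n_t − n̂_t|, whose mean follows a line in
   winter severity w (parameters a_w, b_w, co-estimated) and whose scale
   follows a line in winter duration d (parameters a_d, b_d, fixed in
   advance from least-squares residuals). The annual growth rate is
   g = (b − 1)·100 %. Confidence intervals come from likelihood profiles
   with the χ²₁ 95% cutoff; a plain nonlinear least-squares fit is
   provided for comparison.
3. **Clustering behaviour** (`batdyn.clustering`) — annual summaries of
   roosting behaviour (proportion of bats in warm cave sections,
   proportion solitary, number of clusters, mean and SD of cluster size),
   backward-AIC selection over linear models in log₁₀ abundance, w, d and
   their pairwise interactions, a one-sample test of the solitary
   fraction, and nested likelihood-ratio tests for section-specific
   cluster-size/abundance relationships.
4. **Synthetic data** (`batdyn.synthetic`) — seeded generators for daily
   weather, survey series and cluster records with the statistical
   structure the models assume, so the whole pipeline runs with no
   external data and supports parameter-recovery experiments.

## Worked example

Generate a synthetic 42-year study and analyse it end to end:

```sh
batdyn simulate --seed 4 --out sim
batdyn growth --surveys sim/surveys.csv --species Mmyo --profile b --out fit
batdyn clusters --clusters sim/clusters.csv --surveys sim/surveys.csv \
    --species Mmyo --out clus
batdyn awssi --weather sim/weather.csv --season 1990 --query-date 1991-02-20
```

which prints

```
ML: g = 10.04 %/yr, profile CI [9.73, 10.35]
LS: g = 10.12 %/yr, CI [9.41, 10.82]
solitary fraction 0.136 (t = 90.11)
spatial LRT -2dlnL = 174.9 (df 8); Giant Pots LRT -2dlnL = 88.3 (df 2)
season	start	end	w	d
1990	1990-12-01	1991-04-08	291	81
```

Reading the output: the scenario's true growth rate is 10 %/yr, and both
the severity-corrected maximum-likelihood estimate (`g = 10.04`) and the
uncorrected least-squares estimate recover it; the generator's true
solitary fraction is 0.136 and the clustering pipeline estimates exactly
that; the two likelihood-ratio statistics are large because the generator
deliberately places the biggest clusters in the Giant Pots section; and
the 1990/91 winter began on 1 December, had accumulated 291 AWSSI points
by the 20 February survey date (`w`), 81 days into the winter (`d`).

A YAML scenario file can override any generator truth
(`batdyn simulate --scenario my_scenario.yaml --out dir`), and
`batdyn all --config analysis.yaml` runs severity → growth → clustering
on real input files in one step, writing `report.json` and `summary.txt`.

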