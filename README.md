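# ofhl — the odd Fréchet half-logistic distribution

A statistics package for lifetime and epidemic-rate data built around the
odd Fréchet half-logistic (OFHL) distribution: the half-logistic CDF
`M(x; θ) = (1 − e^{−θx})/(1 + e^{−θx})` pushed through the odd Fréchet
transform `F = exp{−[(1 − M)/M]^α}`. Writing the baseline odds ratio as
`g(x) = 2e^{−θx}/(1 − e^{−θx})`, the model is

```
F(x; α, θ) = exp{−g(x)^α},            x > 0,  α, θ > 0
f(x; α, θ) = αθ g(x)^α / (1 − e^{−θx}) · exp{−g(x)^α}
Q(u)       = (1/θ) · log[1 + 2/(−log u)^{1/α}]
```

Its hazard can be decreasing, increasing, bathtub-shaped or upside-down
bathtub-shaped depending on `(α, θ)`, which is what makes the family useful
when a Weibull- or gamma-style monotone hazard does not fit.

The package provides, for practitioners and for anyone studying estimation
methods on this family:

* **Distribution theory** (`ofhl.distribution`) — log-space stable
  pdf/cdf/sf/hazard, closed-form quantiles and inverse-transform sampling,
  raw/incomplete/conditional moments (double-series with honest
  non-convergence detection plus a quadrature fallback), MGF, mean residual
  life, mean waiting time, extreme order statistics.
* **Six classical estimators** (`ofhl.estimation`) — maximum likelihood,
  Anderson–Darling, Cramér–von Mises, maximum product of spacings, ordinary
  and weighted least squares, all through one deterministic multi-start
  optimizer contract.
* **Goodness of fit** (`ofhl.gof`) — AIC/SIC/CAIC/HQIC, A*, W*,
  Kolmogorov–Smirnov statistic and p-value, the half-logistic baseline fit
  for model comparison, and the TTT (total time on test) diagnostic.
* **Monte-Carlo estimator comparison** (`ofhl.simulation`) — seeded,
  byte-reproducible bias/MSE/MRE tables with the tie-averaged rank
  aggregation used to order the six methods.
* **Data** (`ofhl.datasets`) — two published datasets: 108 daily COVID-19
  mortality rates for Mexico (Mar 4 – Jul 20, 2020) and 45 chemotherapy
  survival times in years, plus one-column text/CSV readers.
* A CLI (`ofhl fit|gof|simulate|ttt|fixtures`).

## Worked example

```python
import ofhl

covid = ofhl.load_fixture("covid_mexico")        # 108 mortality rates
res = ofhl.fit(covid, "mle")
print(res.estimates)
print(round(res.neg_log_likelihood, 3))
rep = ofhl.gof_report(covid, res.estimates)
print(round(rep.aic, 4), round(rep.sic, 4), round(rep.ks, 4), round(rep.ks_pvalue, 4))

hl = ofhl.fit_hl_mle(covid)                      # one-parameter baseline
print(round(ofhl.gof_report(covid, hl.estimates, model="hl").aic, 4))
```

prints

```
Params(alpha=1.008379867621132, theta=0.2807437564627561)
266.453
536.9064 542.2706 0.0696 0.6716
573.5781
```

The MLE `α̂ ≈ 1.008` says the COVID data are close to the plain odd
Fréchet transform of the half-logistic (`α = 1`); the OFHL AIC of 536.9
versus 573.6 for the half-logistic baseline is a decisive improvement, and
the KS p-value of 0.67 shows no evidence against the fitted model. The
same package reproduces the published estimates of all six methods on both
shipped datasets to four decimal places (see `tests/test_acceptance.py`).

A small simulation, from the command line:

```sh
ofhl simulate --seed 7 --scale 100 --out sim.csv --summary-out ranks.csv
```

runs the three-parameter-set study at 10 replications per cell and writes
tidy per-cell AVE/Bias/MSE/MRE with ranks.

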