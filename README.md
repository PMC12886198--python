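# cpcox — change-point Cox model for current status data

Current status data arise when each subject is examined once, at time
`U`, and only the indicator `delta = 1{T <= U}` of whether the event has
already happened is recorded — the failure time `T` itself is never
observed.  `cpcox` fits a partially linear Cox model with a **change
point** in a covariate `E` to such data:

```
Lambda(t | x, z, e) = Lambda0(t) * exp{ beta'x + g(z)
                                        + (gamma'x + h(z)) * 1{e > zeta} }
```

Treatment effects `beta` jump by `gamma` once `E` crosses the unknown
threshold `zeta`; the covariates `Z` act through nonparametric functions
`g` and `h`, modelled either by a small two-headed ReLU network (the
"deep" fits) or by linear forms (the Cox PH baseline).  The package is
aimed at biostatisticians analysing case-I interval-censored outcomes —
screening studies, tumorigenicity experiments, registry data with one
status assessment per subject — who suspect a threshold effect (for
example, a treatment that works differently beyond some age).

What it provides:

* **Sieve maximum likelihood** — a monotone integrated-spline baseline
  hazard (nonnegative coefficients), network or linear effects, and a
  grid search for `zeta`, alternated in a block-ascent profiling loop.
* **Semiparametric-efficient Wald inference** for `(beta, gamma)` via the
  efficient-score projection: each column of `(x, x*1{e>zeta})` is
  regressed, with score weights `Q^2`, on spline bases in `U` and `Z`;
  the information matrix of the residuals yields standard errors,
  confidence intervals and p-values.
* **A permutation test for the existence of a change point** — a
  supremum score statistic over candidate thresholds and indicator
  directions, calibrated by permuting `E`.
* **A synthetic-data generator and replication harness** reproducing the
  structure of the model's simulation studies (bias / SSE / ESE /
  coverage tables, relative errors of `g` and `h`, threshold summaries).

## Worked example

```python
from cpcox import SimConfig, sample_dataset, ChangePointCoxModel, FitConfig

data = sample_dataset(SimConfig(n=1000, case_id=1, seed=7))
fit = ChangePointCoxModel(data, kind="deep-cp").fit(FitConfig(seed=7))
print(fit.summary())
```

```
Change-point partially linear Cox model (current status data)
kind: deep-cp   n = 1000   p = 1   r = 5
log-likelihood (mean): -0.521876   converged: True   outer iterations: 13
change point zeta_hat = 2.0000
     param   estimate       ESE    p-value                 95% CI
    beta_1    -0.8881    0.1557   1.17e-08 [  -1.1932,   -0.5829]
   gamma_1     2.0267    0.1810  4.145e-29 [   1.6720,    2.3814]
```

The generator's true values are `beta = -1`, `gamma = 2`, `zeta = 2`: the
fit recovers the threshold exactly (the grid has gap 0.01), the baseline
treatment effect within one standard error, and the jump effect almost
exactly; both effects are confidently nonzero.

Testing whether a change point exists at all:

```python
from cpcox import permutation_test, TestConfig
res = permutation_test(data.drop_truth(), TestConfig(k=5, B=199, seed=1))
print(res.statistic, res.p_value)   # large statistic, p = 1/200
```

The same workflow is available from the shell for CSV files with columns
`delta,u,x1..xp,z1..zr,e`:

```sh
cpcox simulate --case 1 --n 1000 --seed 7 --out data.csv
cpcox fit --input data.csv --model deep-cp --out fit.json
cpcox test --input data.csv --B 1000 --seed 1 --out test.json
cpcox replicate --case 1 --n 1000 --M 20 --models deep-cp,linear-cp \
      --seed 1 --out study.json
```

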