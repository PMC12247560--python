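# shashnorm

Normative modelling estimates centiles of healthy variation in a phenotype
(for example a regional brain volume) as a function of covariates such as
age and sex, so that an individual measurement can be expressed as a
deviation (z-) score against the reference population.  Multi-site cohorts
add two complications: systematic per-site offsets (batch effects), and
response distributions that are skewed and heavy- or light-tailed, so that
Gaussian centiles misplace exactly the outer centiles one cares about.

`shashnorm` addresses both with hierarchical Bayesian regression over
sinh-arcsinh (SHASH) likelihoods.  It is aimed at biostatisticians and
imaging researchers who need non-Gaussian growth-chart-style references
across pooled scanner sites, and at method developers who want a compact,
fully inspectable implementation with a built-in synthetic cohort
generator for validation.

## The model

The base SHASH law is obtained by pushing a standard Gaussian through the
inverse of the transform

    xi_{eps,delta}(x) = sinh(delta * asinh(x) - eps),

where `eps` controls skew and `delta > 0` tail weight; its density is

    S(x | eps, delta) = delta * C(x) / sqrt(1 + x^2) * phi(xi(x)),
    C(x) = cosh(delta * asinh(x) - eps).

Adding location/scale directly (`SHASH_o`) entangles mu with the skew and
sigma with the tail weight.  `shashnorm` centres on the moment-standardised
reparameterisation `SHASH_b`: using the analytic moments

    m(r) = 2^-r * sum_i C(r,i) (-1)^i exp((r-2i) eps/delta) P((r-2i)/delta),
    P(q) = e^{1/4}/sqrt(8 pi) * (K_{(q+1)/2}(1/4) + K_{(q-1)/2}(1/4)),

with `K` the modified Bessel function of the second kind, samples are first
standardised by the base-law mean `m(1)` and standard deviation
`eta = sqrt(m(2) - m(1)^2)` before mu and sigma are applied:

    B = (xi^-1(Z) - m(1)) / eta * sigma + mu,

so that `E[B] = mu` and `Var(B) = sigma^2` exactly, for every (eps, delta).

The hierarchical regression models, per subject n with design matrix row
`Phi_n` (five cubic B-spline bases of age, raw age, sex):

    mu_n    = Phi_n w_mu + tau_{site(n)},  tau_s = mu_tau + sigma_tau * nu_s
    sigma_n = softplus(Phi_n w_sigma + tau_sigma)
    y_n ~ Sb(mu_n, sigma_n, eps, delta_link(delta_raw))        # variant Sb1

with `delta_link(x) = softplus(10x)/10 + 0.3` keeping the tail parameter
out of its numerically unstable region.  Variant `N` is the Gaussian
likelihood, `So1` the non-standardised SHASH, and `Sb2` regresses eps and
delta themselves on the design matrix (covariate-dependent shape).  The
posterior is sampled with an in-package No-U-Turn sampler (dense mass
matrix, dual-averaging step size, analytic gradients); MAP estimation is
available as a cheap alternative.  Deviation scores invert the generative
transform, centile curves push the Gaussian levels {-3..3} (the
0.1/2.3/15.9/50/84.1/97.7/99.9 percentiles) through it, and fit quality is
summarised by z-score skew/excess kurtosis and 1-vs-1 site AUC.

## Worked example

```python
import numpy as np
import shashnorm as sn

cfg = sn.SimConfig(n_sites=3, n_per_site=200, epsilon=0.5, delta=1.0,
                   w_mu=np.array([0, 0, 0, 0, 0, 0.02, 0.2]), seed=7)
ds = sn.simulate_cohort(cfg)                       # multi-site skewed cohort
cohort = sn.cohort_from_frame(ds.table)
fitted = sn.fit_model(cohort, "response", variant="Sb1", method="map", seed=0)

mu, sigma, eps, dlt = sn.predict_params(fitted, cohort, estimator="map")
y = cohort.df["response"].to_numpy()
z = sn.zscore(y, mu, sigma, eps, dlt)
print("fitted epsilon = %.3f   delta = %.3f" % (eps[0], dlt[0]))
print(sn.moments_report(z).to_string())
print("max |AUC - 0.5| between sites = %.3f"
      % np.nanmax(sn.auc_matrix(z, cohort.site_codes)))
```

prints

```
fitted epsilon = 0.655   delta = 1.079
skew                -0.008452
excess_kurtosis     -0.036145
n                  600.000000
max |AUC - 0.5| between sites = 0.027
```

The generating skew/tail truth was (0.5, 1.0); the fitted shape is close,
the z-scores of the skewed cohort are Gaussian to within sampling noise
(both moments near 0), and the injected site offsets have been absorbed by
the random intercept (site AUC indistinguishable from chance).  Full MCMC
fits replace `method="map"` with `method="mcmc"` (two chains, 1500
iterations, 500 burn-in by default) and report R-hat per parameter.

The same pipeline is exposed as a CLI:

```sh
shashnorm simulate --sites 3 --per-site 200 --seed 7 --out cohort.csv
shashnorm fit cohort.csv --variant Sb1 --method mcmc --out model/
shashnorm zscore model/ cohort.csv --out z.csv
shashnorm centiles model/ --age-min 20 --age-max 80 --out centiles.csv
shashnorm evaluate model/ cohort.csv --out moments.csv --auc-out auc.csv
```

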