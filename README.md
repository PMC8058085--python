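# bayesw

Bayesian joint modelling of **age-at-onset phenotypes** against genome-wide
SNP data.  `bayesw` fits a Weibull accelerated-failure-time model with a
grouped Dirac-spike–and–Gaussian-slab prior over all marker effects
simultaneously, handling right censoring (and optionally left truncation)
exactly in the likelihood.  It is aimed at statistical geneticists who want,
from a single censored time-to-event GWAS fit: SNP heritability on the
log-time scale, per-marker posterior inclusion probabilities, region-level
probabilistic significance (PPWV), and individual genomic predictions with
posterior predictive intervals.

## Model

For individual $i$ with last event-free time $y_i$ and failure indicator
$d_i$, times are Weibull with shape $\alpha$, so that

$$\log Y_i = \mu + \mathbf{x}_i'\boldsymbol\beta + \mathbf{z}_i'\boldsymbol\delta + \epsilon_i,
\qquad \mathrm{Var}(\epsilon_i) = \frac{\pi^2}{6\alpha^2},$$

with $\epsilon_i$ Gumbel, $\mathbf{x}_i$ standardised allele counts and
$\mathbf{z}_i$ covariates.  Each marker effect follows, within its group
$\varphi$,

$$\beta_j \sim \pi^\varphi_0\,\delta_0 + \sum_{k=1}^{L}
\pi^\varphi_k\,\mathcal N\!\left(0,\ C^\varphi_k \sigma^2_{G\varphi}\right),$$

so a marker is either excluded exactly ($\beta_j = 0$) or belongs to an
effect-size class $C_k$.  Gibbs sampling draws $\mu$, $\alpha$,
$\boldsymbol\delta$ and the slab effects by derivative-free adaptive
rejection sampling; spike/slab membership uses adaptive Gauss–Hermite
quadrature marginal likelihoods; everything per-marker runs on sparse
carrier-set algebra, and a bulk-synchronous-parallel schedule (logical
workers, residual-message synchronisation) reproduces the serial chain
bit-for-bit at one worker.  Log-scale SNP heritability is
$h^2 = \sum_\varphi\sigma^2_{G\varphi} / (\sum_\varphi\sigma^2_{G\varphi} + \pi^2/6\alpha^2)$.

See `docs/methods.md` for the full account.

## Worked example

```sh
# 1) simulate a Weibull (theta = 1) phenotype: 1000 individuals,
#    5000 markers, 50 causal, h2 = 0.5
bayesw simulate --n 1000 --m 5000 --p 50 --h2 0.5 --theta 1 \
    --seed 7 --out demo/sim

# 2) fit two slab classes for 800 iterations
bayesw fit --bed demo/sim --pheno demo/sim.pheno \
    --mixtures 0.001,0.01 --iterations 800 --burn-in 400 --thin 5 \
    --seed 1 --out demo/fit

# 3) region-level significance for the fitted effects
bayesw ppwv --betas demo/fit/chain0_betas.csv --bed demo/sim \
    --out demo/ppwv.csv
```

The fit step prints the log-scale heritability with its 95% credible
interval, for example:

```
chain 0: h2 = 0.481 [0.402, 0.554]
```

meaning the markers explain an estimated 48% of the log-time variance
(the generative value here is 0.5).  `demo/fit/chain0_hyperparameters.csv`
holds the thinned chain of $(\alpha, \mu, \sigma^2_G, \boldsymbol\pi)$,
`chain0_betas.csv` the sparse effect samples (sample, marker, mixture,
beta), and `demo/ppwv.csv` the probability that each LD-clump region
explains at least $10^{-5}/10^{-4}/10^{-3}$ of the genetic variance —
regions with PPWV ≥ 0.9 at the $10^{-3}$ threshold are discoveries with
controlled false discovery rate on simulated data.

The same pipeline is available as a library:

```python
from bayesw import SimDesign, simulate_dataset, GroupLayout, HyperParams
from bayesw import GibbsConfig, gibbs_serial
from bayesw.analysis import heritability_log_scale

data, X, truth = simulate_dataset(SimDesign(n_individuals=1000,
                                            n_markers=5000, n_causal=50,
                                            seed=7))
layout = GroupLayout.single_group(X.n_markers, (0.001, 0.01))
samples = gibbs_serial(data, X, HyperParams(), layout,
                       GibbsConfig(iterations=800, burn_in=400, seed=1))
print(heritability_log_scale(samples).mean)
```

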