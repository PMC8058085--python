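# Methods

## Model

`bayesw` models an age-at-onset (time-to-event) phenotype jointly against
all SNP markers.  Times $Y_i$ are Weibull; equivalently $\log Y_i$ is
Gumbel with

$$E(\log Y_i) = \mu + \mathbf{x}_i'\boldsymbol\beta + \mathbf{z}_i'\boldsymbol\delta,
\qquad \mathrm{Var}(\log Y_i) = \frac{\pi^2}{6\alpha^2},$$

where $\mathbf{x}_i$ are standardised allele counts, $\mathbf{z}_i$ fixed
covariates, $\mu$ an intercept on the log-time scale and $\alpha$ the
Weibull shape.  The likelihood handles right censoring exactly (censored
individuals contribute the survival function) and supports left truncation
(individuals observed only beyond an entry age $a_i$ contribute
$1/S(a_i)$); truncation defaults to off ($a_i = 0$), in which case its terms
vanish identically.

Marker effects carry a grouped spike-and-slab prior.  Markers are
partitioned into groups $\varphi$ (for example MAF-by-LD bins); within a
group,

$$\beta_j \sim \pi_0^\varphi\,\delta_0
  + \sum_{k=1}^{L_\varphi} \pi_k^\varphi\,
    \mathcal N(0,\, C_k^\varphi \sigma^2_{G\varphi}),$$

with fixed, increasing slab constants $C_k$ (defaults 0.00001–0.01
ungrouped; 0.0001–0.1 grouped) interpreted as the fraction of the group's
genetic variance a marker of that class explains.  The spike is a Dirac
point mass: $\beta_j = 0$ exactly iff the indicator $\gamma_j = 0$.

Priors are weakly informative: $\alpha \sim$ Gamma(0.01, 0.01),
$\mu, \delta_q \sim \mathcal N(0, 100)$, $\sigma^2_{G\varphi} \sim$
InvGamma(1, $10^{-4}$), mixture proportions Dirichlet(1).

## Posterior computation

The conditionals of $\mu$, $\alpha$, $\delta_q$ and the slab-conditional
$\beta_j$ have no closed form but are log-concave; they are drawn exactly by
derivative-free adaptive rejection sampling (ARS).  The upper hull extends
the secant chords of neighbouring intervals — valid for any concave target —
and hard sampling limits make the hull proper: $\mu \in (2, 5)$,
$\alpha \in (0, 40)$, $\beta_j \in$ previous value
$\pm 2\sqrt{C_k\sigma^2_G}$, $\delta_q \in (-100, 100)$ by default.
Initial abscissae sit at the current value $\pm c$ ($c = 0.5$ for $\mu$ and
$\alpha$, $\sqrt{C_k\sigma^2_G}$ for $\beta_j$).  Envelope sampling is done
entirely in log space, so sharply peaked targets (large $n$) cannot
overflow.

Mixture membership requires the marginal likelihood of each slab — a
one-dimensional integral — evaluated by adaptive Gauss–Hermite quadrature
centred at 0 (effect sizes are symmetric about zero, sparing a mode search)
with the curvature-matched scale $\hat\sigma_k = \big(\sqrt 2\sqrt{1 +
\alpha^2 C_k \sigma^2_G \sum_i x_{ij}^2(e^{v_i}-e^{u_i})}\big)^{-1}$ and
modified weights $w_r e^{t_r^2}$, which make the rule exact for Gaussian
integrands at any order ($m = 25$ nodes by default; 7 nodes already agree to
$10^{-4}$ on Weibull data).  All marginals are returned divided by the
shared factor $T = \exp\{\sum_i(e^{v_i}-e^{u_i})\}$, on which scale the
Dirac-spike marginal is exactly $\sqrt\pi$ — the $C_0\to 0$ limit of the
slab integral.  The quadrature sum is max-shifted in log space before
weighting, as the raw exponent differences overflow for large $\alpha$.

### Sparse genotype algebra

A standardised genotype column takes three values, so every per-marker sum
reduces to three partial sums $V_0, V_1, V_2$ of the exponentiated residual
weights over the carrier index sets, computed in $O(\#\text{carriers})$.
Missing genotypes are mean-imputed (standardised value 0) and kept out of
the carrier sets; standardisation statistics use non-missing entries only.
Because non-carriers sit at $-\bar\xi_j/s_j \neq 0$, a single-marker effect
update shifts *every* residual; the residual state therefore stores base
arrays plus scalar offsets (an additive shift for $\varepsilon$, a
multiplier for $e^{v}$), with only carriers corrected individually.  The
offsets are folded and the exponentials rebuilt once per iteration, and the
full residual is rebuilt from scratch every 100 iterations, bounding
floating-point drift (verified below 1e-8 after 1000 updates).

### Sampling schedules

One iteration updates, in order: $\mu$ (ARS, with its contribution returned
to the residual first), each covariate effect in shuffled order, $\alpha$,
the exponentiated residuals, a shuffled sweep over markers (partial sums,
membership draw, ARS effect draw when a slab is selected, residual
maintenance), then the mixture proportions (Dirichlet with occupancy
counts) and the group variances (inverse-gamma).

The bulk-synchronous-parallel (BSP) variant partitions markers into $T$
contiguous blocks held by logical in-process workers.  Each worker
processes $u$ of its markers against the window-start residual snapshot and
accumulates residual-change messages; messages are applied at the barrier.
With $T = 1, u = 1$ the engine *is* the serial sampler — both entry points
call the same code path, so their chains agree bit-for-bit for a fixed
seed.  Randomness uses one master seed: a main stream for $\mu$, $\delta$,
$\alpha$, $\pi$, $\sigma^2_G$, and per-worker streams (fixed SeedSequence
offsets) for shuffling, membership draws and effect draws, so BSP runs are
reproducible for fixed $(T, u, \text{seed})$.

### Initialisation

All markers start excluded ($\gamma = \beta = \delta = 0$), $\mu$ at the
log-sample mean, $\alpha$ at $\sqrt{\pi^2/(6\,\widehat{\mathrm{Var}}(\log y))}$
(inverting the Gumbel variance), and $\sigma^2_G$ at
$\widehat{\mathrm{Var}}(\log y)/M$ split equally across groups.  Initial
mixture proportions put one marker's worth of mass on each slab
($\pi_k = 1/M_\varphi$).  This matters: a slab-heavy start floods the first
sweeps with hundreds of prior-scale null effects, which can pin
$\sigma^2_G$ in a degenerate near-zero fixed point where inclusion is
cost-free and the slab indistinguishable from the spike.  Starting
essentially all-spike leaves the heavy-tailed InvGamma(1, $10^{-4}$) prior
free to lift $\sigma^2_G$ within a few iterations while only the
strongest-evidence markers enter, after which the causal markers anchor the
variance at the data's scale.

### The genetic-variance update

The conditional for $\sigma^2_{G\varphi}$ is inverse-gamma with shape
$\alpha_\sigma + m/2$ and scale $\beta_\sigma + (m/2)\sum_j \beta_j^2$,
where $m$ counts the group's in-model markers.  Two candidate scales were
considered.  The textbook conjugate of the slab prior,
$\beta_\sigma + \tfrac12\sum_j \beta_j^2/C_{\gamma_j}$, makes $\sigma^2_G$
equilibrate at the *C-rescaled per-marker* variance
$\operatorname{mean}_j(\beta_j^2/C_{\gamma_j})$, which equals the total
genetic variance only in the knife-edge case $\sum_j C_{\gamma_j} = 1$; in
simulation it produced log-scale heritabilities of ~0.95 for a generative
0.5.  The implemented scale is instead the exact conjugate for effects
viewed as $\beta_j \sim \mathcal N(0, \sigma^2_G/m)$ — a prior-preservation
(successive-conditional) test in the suite verifies this — and keeps
$E[\sigma^2_G] \approx \sum_j \beta_j^2$, the realized genetic variance of
the group.  That is the quantity the heritability estimator

$$h^2 = \frac{\sum_\varphi \sigma^2_{G\varphi}}
             {\sum_\varphi \sigma^2_{G\varphi} + \pi^2/(6\alpha^2)}$$

needs, and with it the estimator is calibrated (recovered 0.48 for a
generative 0.49 in the reference study).

## Synthetic data

The generator reproduces the uncorrelated-marker study design: genotypes
are Binomial(2, $f_j$) counts with $f_j$ uniform on the MAF range (default
0.05–0.5; monomorphic columns resampled); $p$ causal markers receive
$\mathcal N(0, \sigma_g^2/p)$ effects; log-times are
$\mu_0 + g_i + e_i$ with $e_i$ a standardised log-generalised-gamma draw
indexed by $\theta$ — $\theta = 1$ Gumbel (Weibull times, well-specified),
$\theta = 0$ Gaussian (log-normal times), other values interpolating the
misspecification — centred and scaled by its closed-form digamma/trigamma
moments, then rescaled to $\mathrm{Var}(g)(1-h^2)/h^2$ so the realized
log-scale heritability matches the design's $h^2$.  Defaults follow the
reference design ($N = 5000$, $M = 50{,}000$, $p = 500$, $h^2 = 0.5$); the
total log-time variance defaults to 0.04 and the intercept to 3.7 (an onset
age of ~40 if times are years), placing $\mu$ inside its (2, 5) sampling
window.  Right censoring marks exactly $\lfloor fN\rfloor$ uniformly chosen
individuals censored with a recorded time uniform on $(0, y_i)$; the
mechanism sits behind one function so another censoring-time law can be
swapped in.

What the generator does *not* emulate: linkage disequilibrium (markers are
independent; an effect-placement option assigns effects to LD-clump index
markers when correlated genotypes are supplied externally), population
structure and relatedness, informative censoring, and genotyping error.
Passing tests therefore demonstrate correctness of the sampler and
estimators under the model's own assumptions, not robustness to the full
complexity of biobank data.

## Post-processing

Log-scale heritability is computed per retained sample as above.  Region
significance uses the posterior probability of the window variance (PPWV):
per sample, a region's share is the variance over individuals of
$X_R\beta_R$ divided by that sample's total genetic variance; PPWV is the
fraction of samples with share at or above a threshold (defaults $10^{-5}$,
$10^{-4}$, $10^{-3}$ of the genetic variance).  The per-sample denominator
keeps numerator and denominator self-consistent; a fast path sums squared
standardised effects, equivalent for uncorrelated markers.  Regions come
from greedy LD clumping (10 Mb window, $r^2 \ge 0.1$ joins a clump; index
markers ranked by PIP when a fit exists, else by MAF — the ranking rule was
an open choice) or from user-supplied gene windows, subsampled to at most
250 markers for comparability.  Prediction multiplies new-cohort genotypes,
standardised with the new cohort's own statistics, by each sampled effect
vector; predictive intervals draw one Weibull time per retained sample and
take empirical quantiles.  Harrell's C treats a higher predictor as longer
predicted survival and is computed directly from (predictor, time,
indicator) triples; martingale residuals $d_i - \hat\Lambda_0(t_i)
e^{z_i'\hat\gamma}$ use the Nelson–Aalen estimator (Breslow ties; Cox
partial likelihood for $\hat\gamma$ when covariates are present).

## Numerical choices and degenerate inputs

Exponents are capped at 700 before exponentiation (with a warning): early
iterations can overshoot before shrinkage engages, and a capped value is
recoverable where an `inf` is not.  $K$ is computed as $-\psi(1)$, not
transcribed.  Monomorphic markers are rejected at load; zero phenotypic
variance is an error; an all-censored sample has no usable concordance
pairs and is rejected by Harrell's C.  Mixture-membership probabilities are
renormalised through a max-log shift so simultaneous underflow cannot
produce NaN.  Membership ties are broken by inverse-CDF on a single
uniform, components ordered spike first, then ascending $C_k$.

## Problem sizes

The reference study fitted by the test suite and the acceptance script uses
$N = 2000$ training and 1000 held-out individuals, $M = 5000$ markers,
$p = 50$ causal, two chains of 2000 iterations (burn-in 1000, thinning 5)
with slab constants $\{0.001, 0.01\}$; region-FDR replication uses five
$N = 1200$, $M = 1500$ data sets, and schedule-equivalence checks a
$N = 1500$, $M = 1500$ instance.  These sizes were chosen so a full
verification run completes on a single CPU, with sample size and causal
count large enough that the chain's initial signal-pickup phase — whose
duration is a heavy-tailed race between the variance prior and the first
strong marker entering the model — ends well inside the burn-in at any
seed.

## Known limitations

Single-node execution only (BSP workers are logical, exercising the
synchronisation contract, not MPI); hard-called genotypes only (no
dosages); no time-varying covariates or competing risks; the original-scale
heritability transformation is out of scope (estimates are log-scale); the
$\mu \in (2,5)$ sampling window assumes log-times in that range — rescale
the time unit if your phenotype lives elsewhere.
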