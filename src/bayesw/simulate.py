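"""Synthetic genotype/phenotype generation for the survival GWAS model.

Phenotypes are produced on the log-time scale as ``log y = mu0 + g + e``
where ``g`` is a sparse genetic value built from standardised allele counts
and ``e`` is a standardised log-generalised-gamma error indexed by ``theta``:
``theta = 1`` gives a Gumbel error (Weibull times, the well-specified case),
``theta = 0`` the Gaussian limit (log-normal times), and other values
interpolate/extrapolate the shape misspecification.  The error is centred
and scaled by its closed-form moments (digamma/trigamma), then rescaled so
that the realised log-scale heritability Var(g)/Var(log y) matches the
design's h2.

Right censoring replaces the recorded time of a uniformly chosen fraction of
individuals by a draw uniform on (0, y_i) with the failure indicator set
to 0, preserving the requested censoring fraction exactly.  The mechanism is
isolated here so an alternative censoring-time law can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import polygamma

from .core import EULER_MASCHERONI, SurvivalData
from .sparse import GenotypeMatrix, default_marker_table

__all__ = [
    "SimDesign",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "apply_censoring",
    "simulate_dataset",
]


@dataclass
class SimDesign:
    """Study design for one synthetic data set.

    Defaults follow the uncorrelated-marker simulation design: 5000
    individuals, 50,000 markers, 500 causal variants, h2 = 0.5, Weibull
    (theta = 1) phenotypes, no censoring.  ``log_scale_variance`` fixes the
    total variance of log times (genetic plus error); ``mu0`` the mean log
    time (3.7 corresponds to a typical onset age of ~40 in years).
    """

    n_individuals: int = 5000
    n_markers: int = 50_000
    n_causal: int = 500
    heritability: float = 0.5
    theta: float = 1.0
    censoring_fraction: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    mu0: float = 3.7
    log_scale_variance: float = 0.04
    marker_spacing_bp: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.heritability < 1:
            raise ValueError("heritability must be in (0, 1)")
        if self.n_causal > self.n_markers:
            raise ValueError("more causal markers than markers")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring fraction must be in [0, 1)")
        if self.theta < 0:
            raise ValueError("generalised-gamma index theta must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of one simulated data set."""

    causal: np.ndarray
    beta: np.ndarray          # length n_markers, zero off the causal set
    genetic_values: np.ndarray
    uncensored_times: np.ndarray
    censoring_times: np.ndarray = field(default=None)


def _rng(design_or_seed) -> np.random.Generator:
    if isinstance(design_or_seed, np.random.Generator):
        return design_or_seed
    return np.random.default_rng(design_or_seed)


def simulate_genotypes(design: SimDesign,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Uncorrelated hard-called genotypes: counts ~ Binomial(2, f_j).

    Allele frequencies are uniform on ``maf_range``; monomorphic columns are
    resampled so every marker is usable after standardisation.
    """
    rng = _rng(design.seed) if rng is None else rng
    n, m = design.n_individuals, design.n_markers
    freqs = rng.uniform(design.maf_range[0], design.maf_range[1], size=m)
    counts = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        col = rng.binomial(2, freqs[j], size=n).astype(np.int8)
        while col.max() == col.min():
            col = rng.binomial(2, freqs[j], size=n).astype(np.int8)
        counts[:, j] = col
    return GenotypeMatrix.from_counts(
        counts, default_marker_table(m, design.marker_spacing_bp))


def _log_gengamma_moments(theta: float) -> tuple[float, float]:
    """Closed-form mean/sd of the raw log-generalised-gamma error term.

    For theta > 0 the raw error is w = log(theta^2 G)/theta with
    G ~ Gamma(theta^-2); mean and variance follow from digamma/trigamma.
    theta -> 0 is the standard-normal limit.
    """
    if theta == 0.0:
        return 0.0, 1.0
    k = theta**-2
    mean = (float(polygamma(0, k)) + math.log(theta**2)) / theta
    sd = math.sqrt(float(polygamma(1, k))) / theta
    return mean, sd


def _draw_raw_error(theta: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if theta == 0.0:
        return rng.standard_normal(n)
    k = theta**-2
    return np.log(theta**2 * rng.gamma(k, 1.0, size=n)) / theta


def simulate_phenotypes(X: GenotypeMatrix, design: SimDesign,
                        rng: np.random.Generator | None = None
                        ) -> tuple[SurvivalData, SimTruth]:
    """Generalised-gamma log-time phenotypes at fixed log-scale heritability.

    Causal effects are N(0, sigma_g^2 / p) at p random markers; the error is
    standardised by closed-form moments and rescaled to
    Var(g) (1 - h2) / h2 so the realised heritability matches h2.
    """
    rng = _rng(design.seed + 1) if rng is None else rng
    m = X.n_markers
    p = design.n_causal
    sigma_g2 = design.heritability * design.log_scale_variance
    causal = np.sort(rng.choice(m, size=p, replace=False))
    beta = np.zeros(m)
    beta[causal] = rng.normal(0.0, math.sqrt(sigma_g2 / p), size=p)
    g = X.dot_beta(beta)
    var_g = float(np.var(g))
    mean_w, sd_w = _log_gengamma_moments(design.theta)
    raw = _draw_raw_error(design.theta, X.n_individuals, rng)
    sd_e = math.sqrt(var_g * (1.0 - design.heritability) / design.heritability)
    e = (raw - mean_w) / sd_w * sd_e
    log_y = design.mu0 + g + e
    times = np.exp(log_y)
    data = SurvivalData.from_times(times, np.ones(X.n_individuals, dtype=int))
    truth = SimTruth(causal=causal, beta=beta, genetic_values=g,
                     uncensored_times=times)
    return data, truth


def apply_censoring(data: SurvivalData, fraction: float,
                    rng: np.random.Generator) -> SurvivalData:
    """Right-censor exactly floor(fraction * n) uniformly chosen individuals.

    Censored individuals get failure 0 and a recorded time uniform on
    (0, y_i); truncation ages and covariates are carried over unchanged.
    """
    if not 0 <= fraction < 1:
        raise ValueError("censoring fraction must be in [0, 1)")
    if fraction == 0:
        return data
    n = data.n
    n_cens = int(math.floor(fraction * n))
    who = rng.choice(n, size=n_cens, replace=False)
    times = np.exp(data.log_time)
    failure = data.failure.copy()
    new_times = times.copy()
    new_times[who] = rng.uniform(0.0, times[who])
    failure[who] = 0
    return SurvivalData.from_times(new_times, failure,
                                   trunc_age=data.trunc_age.copy(),
                                   covariates=data.covariates.copy())


def simulate_dataset(design: SimDesign
                     ) -> tuple[SurvivalData, GenotypeMatrix, SimTruth]:
    """Genotypes + phenotypes + censoring from one seed, with ground truth."""
    rng = np.random.default_rng(design.seed)
    X = simulate_genotypes(design, rng)
    data, truth = simulate_phenotypes(X, design, rng)
    if design.censoring_fraction > 0:
        censored = apply_censoring(data, design.censoring_fraction, rng)
        truth.censoring_times = np.exp(censored.log_time)
        data = censored
    return data, X, truth
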