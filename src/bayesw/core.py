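"""Weibull/Gumbel survival model core: likelihood and conditional log-posteriors.

The model treats the log of a time-to-event outcome as Gumbel-distributed,
which is equivalent to a Weibull accelerated-failure-time model for the time
itself.  Writing ``log Y_i = mu + x_i'beta + z_i'delta + e_i`` with a Gumbel
error, the shape parameter ``alpha`` controls the residual spread through
``Var(log Y_i) = pi^2 / (6 alpha^2)``.  Right censoring enters through the
survival function and left truncation through conditioning on survival to the
entry age ``a_i``; both are handled exactly in the likelihood below.

All algebra is carried out on the log-time scale.  Times are logged once at
construction of :class:`SurvivalData` and never again.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

__all__ = [
    "EULER_MASCHERONI",
    "EXP_CAP",
    "SurvivalData",
    "WeibullParams",
    "Residuals",
    "HyperParams",
    "gumbel_log_moments",
    "log_likelihood",
    "log_post_alpha",
    "log_post_mu",
    "log_post_delta_q",
    "log_post_beta_j",
    "compute_residuals",
]

#: Euler-Mascheroni constant, computed (not transcribed) as -psi(1).
EULER_MASCHERONI: float = float(-digamma(1.0))

#: Cap applied to exponents before calling exp(); extreme early-chain states
#: can overshoot before shrinkage engages, and a capped (warned) exponential
#: is preferable to an inf that poisons the residual vector.
EXP_CAP: float = 700.0


def _capped_exp(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    if np.any(x > EXP_CAP):
        warnings.warn(
            "exponent capped at %.0f during residual exponentiation" % EXP_CAP,
            RuntimeWarning,
            stacklevel=2,
        )
        x = np.minimum(x, EXP_CAP)
    return np.exp(x)


@dataclass
class SurvivalData:
    """Per-individual survival outcome on the log-time scale.

    Parameters
    ----------
    log_time
        ``log y_i`` where ``y_i`` is the last known event-free time in the
        original (strictly positive) units.
    failure
        Event indicator ``d_i`` in {0, 1}: 1 if the event was observed.
    trunc_age
        Left-truncation age ``a_i >= 0`` on the *original* scale; 0 means no
        truncation and contributes nothing to the likelihood.
    covariates
        ``n x q`` matrix of fixed covariates ``z_i`` (may have q = 0).
    """

    log_time: np.ndarray
    failure: np.ndarray
    trunc_age: np.ndarray
    covariates: np.ndarray

    def __post_init__(self) -> None:
        self.log_time = np.asarray(self.log_time, dtype=float)
        self.failure = np.asarray(self.failure)
        n = self.log_time.shape[0]
        if self.trunc_age is None:
            self.trunc_age = np.zeros(n)
        self.trunc_age = np.asarray(self.trunc_age, dtype=float)
        if self.covariates is None:
            self.covariates = np.zeros((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.ndim == 1 and self.covariates.size:
            self.covariates = self.covariates.reshape(-1, 1)
        self.covariates = np.atleast_2d(self.covariates)
        if self.covariates.size == 0:
            self.covariates = np.zeros((n, 0))
        elif self.covariates.shape[0] != n:
            raise ValueError(
                f"covariates have {self.covariates.shape[0]} rows for "
                f"{n} individuals")
        if not np.all(np.isin(self.failure, (0, 1))):
            raise ValueError("failure indicator must be 0 or 1")
        self.failure = self.failure.astype(np.int8)
        if np.any(self.trunc_age < 0):
            raise ValueError("left-truncation ages must be non-negative")
        if np.any(np.log(np.maximum(self.trunc_age, np.finfo(float).tiny))
                  [self.trunc_age > 0] >= self.log_time[self.trunc_age > 0]):
            raise ValueError("left-truncation age must precede the recorded time")

    @classmethod
    def from_times(
        cls,
        time: np.ndarray,
        failure: np.ndarray,
        trunc_age: np.ndarray | None = None,
        covariates: np.ndarray | None = None,
    ) -> "SurvivalData":
        time = np.asarray(time, dtype=float)
        if np.any(time <= 0):
            raise ValueError("times must be strictly positive before logging")
        n = time.shape[0]
        return cls(
            log_time=np.log(time),
            failure=np.asarray(failure),
            trunc_age=np.zeros(n) if trunc_age is None else np.asarray(trunc_age, float),
            covariates=np.zeros((n, 0)) if covariates is None else covariates,
        )

    @property
    def n(self) -> int:
        return self.log_time.shape[0]

    @property
    def n_events(self) -> int:
        """Total number of observed events, d = sum d_i."""
        return int(self.failure.sum())

    @property
    def log_trunc(self) -> np.ndarray:
        """log a_i where a_i > 0; -inf placeholder where untruncated."""
        out = np.full(self.n, -np.inf)
        pos = self.trunc_age > 0
        out[pos] = np.log(self.trunc_age[pos])
        return out


@dataclass
class WeibullParams:
    """Current location-scale parameters of the model."""

    mu: float
    alpha: float
    beta: np.ndarray
    delta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    euler_K: float = EULER_MASCHERONI

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("Weibull shape alpha must be positive")
        self.beta = np.asarray(self.beta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)


@dataclass
class Residuals:
    """Log-scale residuals and their exponentiated transforms.

    ``eps`` holds ``log y_i - mu - x_i'beta - z_i'delta``.  ``exp_event`` is
    ``exp(v_i)`` with ``v_i = alpha * eps_i - K``; ``exp_trunc`` the analogue
    built from the truncation age, exactly 0 where ``a_i = 0``.
    """

    eps: np.ndarray
    exp_event: np.ndarray
    exp_trunc: np.ndarray


def _marker_dot(X, beta: np.ndarray) -> np.ndarray:
    """x_i'beta for either a dense standardized matrix or a GenotypeMatrix."""
    if X is None:
        return 0.0
    if hasattr(X, "dot_beta"):
        return X.dot_beta(beta)
    return np.asarray(X, dtype=float) @ beta


def linear_predictor(data: SurvivalData, params: WeibullParams, X=None) -> np.ndarray:
    lp = params.mu + _marker_dot(X, params.beta)
    if params.delta.size:
        lp = lp + data.covariates @ params.delta
    return np.broadcast_to(np.asarray(lp, float), (data.n,)).copy()


def gumbel_log_moments(mu_lin, alpha: float) -> tuple[np.ndarray, float]:
    """Mean and variance of log Y under the Gumbel reparametrisation.

    The mean equals the linear predictor (the Euler-Mascheroni shift is
    absorbed into the Weibull scale) and the variance is pi^2 / (6 alpha^2),
    independent of the predictor.
    """
    if alpha <= 0:
        raise ValueError("Weibull shape alpha must be positive")
    return np.asarray(mu_lin, dtype=float), np.pi**2 / (6.0 * alpha**2)


def compute_residuals(data: SurvivalData, params: WeibullParams, X=None) -> Residuals:
    """Full (from-scratch) residual build; the oracle for incremental updates."""
    lp = linear_predictor(data, params, X)
    eps = data.log_time - lp
    exp_event = _capped_exp(params.alpha * eps - params.euler_K)
    exp_trunc = np.zeros(data.n)
    pos = data.trunc_age > 0
    if np.any(pos):
        u = params.alpha * (np.log(data.trunc_age[pos]) - lp[pos]) - params.euler_K
        exp_trunc[pos] = _capped_exp(u)
    return Residuals(eps=eps, exp_event=np.atleast_1d(exp_event),
                     exp_trunc=exp_trunc)


def log_likelihood(data: SurvivalData, params: WeibullParams, X=None) -> float:
    """Log of the right-censored, left-truncated Weibull likelihood.

    Event terms enter with a negative sign and truncation terms with a
    positive sign; the constant factors (``alpha^d``, ``-K d``) are retained
    so that absolute values are testable even though they cancel in Gibbs
    ratios.
    """
    r = compute_residuals(data, params, X)
    d = data.n_events
    di = data.failure.astype(float)
    lp = data.log_time - r.eps  # mu + x'beta + z'delta
    ll = (
        d * np.log(params.alpha)
        - params.euler_K * d
        + (params.alpha - 1.0) * float(di @ data.log_time)
        - params.alpha * float(di @ lp)
        - float(r.exp_event.sum())
        + float(r.exp_trunc.sum())
    )
    if not np.isfinite(ll):
        terms = -r.exp_event + r.exp_trunc
        bad = int(np.flatnonzero(~np.isfinite(terms))[0]) if np.any(~np.isfinite(terms)) else -1
        raise FloatingPointError(
            f"non-finite log-likelihood contribution (individual index {bad})"
        )
    return ll


@dataclass
class HyperParams:
    """Prior hyperparameters.

    Defaults are the weakly informative choices used throughout: a Gamma
    (0.01, 0.01) prior for the shape, InvGamma(1, 1e-4) for the genetic
    variance, N(0, 100) for the intercept and covariate effects, and a
    Dirichlet vector of ones over mixture components.
    """

    alpha0: float = 0.01
    kappa0: float = 0.01
    alpha_sigma: float = 1.0
    beta_sigma: float = 1e-4
    sigma2_mu: float = 100.0
    sigma2_delta: float = 100.0
    dirichlet_p: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha0", "kappa0", "alpha_sigma", "beta_sigma",
                     "sigma2_mu", "sigma2_delta", "dirichlet_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")


def log_post_alpha(data: SurvivalData, params: WeibullParams,
                   hyper: HyperParams, X=None):
    """Conditional log-posterior of the shape alpha, up to a constant.

    log p(alpha | ...) = (alpha0 + d - 1) log alpha
                         + alpha [ sum_i d_i eps_i - kappa0 ]
                         + sum_{a_i>0} exp(alpha tau_i - K)
                         - sum_i exp(alpha eps_i - K)
    with eps_i the full residual and tau_i its truncation-age analogue.
    Log-concave in alpha; returns -inf for alpha <= 0.
    """
    lp = linear_predictor(data, params, X)
    eps = data.log_time - lp
    d = data.n_events
    d_eps = float(data.failure.astype(float) @ eps)
    pos = data.trunc_age > 0
    tau = np.log(data.trunc_age[pos]) - lp[pos] if np.any(pos) else np.zeros(0)
    K = params.euler_K

    def logpost(alpha: float) -> float:
        if alpha <= 0:
            return -np.inf
        val = (hyper.alpha0 + d - 1.0) * np.log(alpha) + alpha * (d_eps - hyper.kappa0)
        val += float(np.sum(_capped_exp(alpha * tau - K)))
        val -= float(np.sum(_capped_exp(alpha * eps - K)))
        return val

    return logpost


def log_post_mu(data: SurvivalData, params: WeibullParams,
                hyper: HyperParams, X=None):
    """Conditional log-posterior of the intercept mu, up to a constant.

    Built with mu removed from the residual: with
    ``S = sum_i exp(alpha (log y_i - x'beta - z'delta) - K)`` (and the
    truncation analogue ``S_a``),
    log p(mu | ...) = -alpha d mu + exp(-alpha mu) (S_a - S) - mu^2/(2 s2_mu).
    """
    lp_rest = linear_predictor(data, params, X) - params.mu
    K, alpha = params.euler_K, params.alpha
    s_event = float(np.sum(_capped_exp(alpha * (data.log_time - lp_rest) - K)))
    pos = data.trunc_age > 0
    s_trunc = float(np.sum(
        _capped_exp(alpha * (np.log(data.trunc_age[pos]) - lp_rest[pos]) - K)
    )) if np.any(pos) else 0.0
    d = data.n_events

    def logpost(mu: float) -> float:
        return (-alpha * d * mu
                + np.exp(min(-alpha * mu, EXP_CAP)) * (s_trunc - s_event)
                - mu * mu / (2.0 * hyper.sigma2_mu))

    return logpost


def log_post_delta_q(data: SurvivalData, params: WeibullParams,
                     hyper: HyperParams, q: int, X=None):
    """Conditional log-posterior of covariate effect delta_q, up to a constant.

    Residuals are taken with delta_q added back (removed from the predictor).
    """
    z = data.covariates[:, q]
    lp_rest = linear_predictor(data, params, X) - z * params.delta[q]
    K, alpha = params.euler_K, params.alpha
    e_plus = data.log_time - lp_rest
    pos = data.trunc_age > 0
    t_plus = np.log(data.trunc_age[pos]) - lp_rest[pos] if np.any(pos) else np.zeros(0)
    z_pos = z[pos]
    d_z = float(data.failure.astype(float) @ z)

    def logpost(dq: float) -> float:
        val = -alpha * dq * d_z
        if t_plus.size:
            val += float(np.sum(_capped_exp(alpha * (t_plus - z_pos * dq) - K)))
        val -= float(np.sum(_capped_exp(alpha * (e_plus - z * dq) - K)))
        return val - dq * dq / (2.0 * hyper.sigma2_delta)

    return logpost


def log_post_beta_j(data: SurvivalData, params: WeibullParams,
                    hyper: HyperParams, x_col: np.ndarray, j: int, k: int,
                    c_k: float, sigma2_g: float, X=None):
    """Conditional log-posterior of marker effect beta_j in slab k, dense form.

    This is the reference (dense) target; the Gibbs engine evaluates the same
    function through genotype partial sums.  The Gaussian shrinkage term is
    ``-beta^2 / (2 C_k sigma2_G)``.  Spike effects (k = 0) are exactly zero
    and never sampled.
    """
    if k == 0:
        raise ValueError("spike component effects are identically zero; not sampled")
    x_col = np.asarray(x_col, dtype=float)
    lp_rest = linear_predictor(data, params, X) - x_col * params.beta[j]
    K, alpha = params.euler_K, params.alpha
    v_plus = alpha * (data.log_time - lp_rest) - K
    pos = data.trunc_age > 0
    u_plus = (alpha * (np.log(data.trunc_age[pos]) - lp_rest[pos]) - K
              if np.any(pos) else np.zeros(0))
    x_pos = x_col[pos]
    d_x = float(data.failure.astype(float) @ x_col)
    shrink = 2.0 * c_k * sigma2_g

    def logpost(b: float) -> float:
        val = -alpha * b * d_x
        if u_plus.size:
            val += float(np.sum(_capped_exp(u_plus - alpha * x_pos * b)))
        val -= float(np.sum(_capped_exp(v_plus - alpha * x_col * b)))
        return val - b * b / shrink

    return logpost
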