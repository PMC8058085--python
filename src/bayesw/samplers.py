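"""Derivative-free adaptive rejection sampling and adaptive Gauss-Hermite
marginal likelihoods for spike-and-slab mixture selection.

The four conditional posteriors of the survival model (shape, intercept,
covariate effects, marker effects) are log-concave, so exact draws are
obtained by adaptive rejection sampling (ARS).  The derivative-free variant
is used: the upper hull over an interval is built by extending the secant
chords of the neighbouring intervals, which bounds any concave function from
above without evaluating derivatives.

Mixture-membership probabilities require the marginal likelihood of each slab
component, an intractable one-dimensional integral approximated by adaptive
Gauss-Hermite quadrature centred at 0 (effect sizes are symmetric about
zero, so the mode search is skipped).  All marginals are returned on a common
scale: divided by the shared factor ``T = exp{sum_i [exp(v_i) - exp(u_i)]}``,
which makes the Dirac-spike marginal exactly ``sqrt(pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import roots_hermite

__all__ = [
    "ArsEnvelope",
    "ConcavityError",
    "ars_sample",
    "sampling_bounds",
    "QuadratureRule",
    "MixtureSpec",
    "sigma_hat",
    "marginal_likelihood_slab",
    "log_marginal_slab",
    "marginal_likelihood_spike",
    "inclusion_probabilities",
]

_SQRT_PI = math.sqrt(math.pi)


class ConcavityError(RuntimeError):
    """Raised when the target is detectably non-concave on the envelope."""


# ---------------------------------------------------------------------------
# Derivative-free adaptive rejection sampling
# ---------------------------------------------------------------------------

@dataclass
class ArsEnvelope:
    """Piecewise-linear envelope of a concave log-density.

    ``abscissae`` are the strictly increasing evaluation points inside the
    hard sampling limits; ``logvals`` the target log-density there.  The
    upper hull extends neighbouring secant chords; the lower hull is the
    chord polygon itself (-inf outside the abscissa range).
    """

    abscissae: np.ndarray
    logvals: np.ndarray
    lower_bound: float
    upper_bound: float
    # piecewise-linear upper hull: breakpoints z, and (slope, value-at-left)
    _z: np.ndarray = field(default=None, repr=False)
    _hz: np.ndarray = field(default=None, repr=False)
    _slopes: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.abscissae)
        self.abscissae = np.asarray(self.abscissae, float)[order]
        self.logvals = np.asarray(self.logvals, float)[order]
        if self.abscissae.size < 3:
            raise ValueError("envelope needs at least 3 abscissae")
        if np.any(np.diff(self.abscissae) <= 0):
            raise ValueError("abscissae must be strictly increasing")
        if (self.abscissae[0] < self.lower_bound
                or self.abscissae[-1] > self.upper_bound):
            raise ValueError("abscissae must lie within the sampling limits")
        self._build()

    # -- hull construction --------------------------------------------------
    def _build(self) -> None:
        x, h = self.abscissae, self.logvals
        k = x.size
        sl = np.diff(h) / np.diff(x)  # chord slopes, decreasing if concave
        # Breakpoints of the upper hull and the line on each resulting piece.
        zs = [self.lower_bound]
        slopes = []
        vals = []  # hull value at the left edge of each piece

        def line_at(i: int, xq: float) -> float:
            # chord through (x[i], h[i]) with slope sl[i]
            return h[i] + sl[i] * (xq - x[i])

        # leftmost piece: chord(x0,x1) extended to the lower bound
        slopes.append(sl[0])
        vals.append(line_at(0, self.lower_bound))
        zs.append(x[0])
        for i in range(k - 1):
            left = sl[i - 1] if i >= 1 else None      # chord to the left
            right = sl[i + 1] if i + 2 <= k - 1 else None
            if left is not None and right is not None:
                # intersection of left chord (through x[i]) and right chord
                # (through x[i+1]); both are valid upper bounds on (x_i,x_{i+1})
                denom = left - right
                if abs(denom) < 1e-300:
                    xc = x[i + 1]
                else:
                    xc = (h[i + 1] - h[i] + left * x[i] - right * x[i + 1]) / denom
                xc = min(max(xc, x[i]), x[i + 1])
                slopes.append(left)
                vals.append(h[i])
                zs.append(xc)
                slopes.append(right)
                vals.append(h[i + 1] + right * (xc - x[i + 1]))
                zs.append(x[i + 1])
            else:
                s = right if left is None else left
                anchor = i + 1 if left is None else i
                slopes.append(s)
                vals.append(h[anchor] + s * (x[i] - x[anchor]))
                zs.append(x[i + 1])
        # rightmost piece: chord(x_{k-2},x_{k-1}) extended to the upper bound
        slopes.append(sl[-1])
        vals.append(h[k - 1])
        zs.append(self.upper_bound)
        self._z = np.asarray(zs)
        self._slopes = np.asarray(slopes)
        self._hz = np.asarray(vals)

    # -- hull evaluation ----------------------------------------------------
    def upper(self, xq: float) -> float:
        i = int(np.clip(np.searchsorted(self._z, xq, side="right") - 1,
                        0, self._slopes.size - 1))
        return self._hz[i] + self._slopes[i] * (xq - self._z[i])

    def lower(self, xq: float) -> float:
        x, h = self.abscissae, self.logvals
        if xq < x[0] or xq > x[-1]:
            return -np.inf
        i = int(np.clip(np.searchsorted(x, xq) - 1, 0, x.size - 2))
        w = (xq - x[i]) / (x[i + 1] - x[i])
        return (1 - w) * h[i] + w * h[i + 1]

    def insert(self, xq: float, hq: float) -> None:
        idx = np.searchsorted(self.abscissae, xq)
        self.abscissae = np.insert(self.abscissae, idx, xq)
        self.logvals = np.insert(self.logvals, idx, hq)
        self._build()

    # -- sampling from exp(upper hull) ---------------------------------------
    def sample(self, rng: np.random.Generator) -> float:
        """Inverse-CDF draw from the exponentiated upper hull (log space)."""
        z, s, hz = self._z, self._slopes, self._hz
        left, right = z[:-1], z[1:]
        width = right - left
        sw = s * width
        # log of each piece's integral of exp(hz + s (x - left))
        with np.errstate(divide="ignore", invalid="ignore"):
            logmass = np.where(
                np.abs(sw) < 1e-12,
                hz + np.log(np.maximum(width, 1e-300)),
                np.where(
                    s > 0,
                    hz + sw + np.log1p(-np.exp(-np.abs(sw)))
                    - np.log(np.maximum(np.abs(s), 1e-300)),
                    hz + np.log1p(-np.exp(-np.abs(sw)))
                    - np.log(np.maximum(np.abs(s), 1e-300)),
                ),
            )
        logmass = np.where(width <= 0, -np.inf, logmass)
        shift = float(np.max(logmass))
        if not np.isfinite(shift):
            raise RuntimeError("degenerate ARS envelope (zero mass)")
        mass = np.exp(logmass - shift)
        cdf = np.cumsum(mass)
        i = int(np.searchsorted(cdf / cdf[-1], rng.random()))
        i = min(i, mass.size - 1)
        u = rng.random()
        si, wi = s[i], width[i]
        if abs(si) * wi < 1e-12:
            return float(left[i] + u * wi)
        if si > 0:  # density rises to the right edge; anchor there
            val = math.log(u + (1.0 - u) * math.exp(-si * wi))
            return float(right[i] + val / si)
        val = math.log1p(-u * (1.0 - math.exp(si * wi)))
        return float(left[i] + val / si)


def ars_sample(log_density, init_abscissae, bounds, rng,
               max_rejections: int = 500, tol: float = 1e-8) -> float:
    """One exact draw from ``exp(log_density)`` restricted to ``bounds``.

    ``log_density`` must be concave on the interval.  Rejected proposals are
    added to the envelope, tightening it adaptively.  A detected violation of
    concavity (target above the upper hull, or below the lower hull, beyond
    ``tol``) raises :class:`ConcavityError`.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not hi > lo:
        raise ValueError("empty sampling interval")
    pts = np.unique(np.clip(np.asarray(init_abscissae, float),
                            lo + 1e-10 * (hi - lo), hi - 1e-10 * (hi - lo)))
    if pts.size < 3:
        pts = np.unique(np.concatenate([pts, np.linspace(lo, hi, 5)[1:-1]]))
    vals = np.array([log_density(p) for p in pts])
    keep = np.isfinite(vals)
    if keep.sum() < 3:
        grid = np.linspace(lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo), 25)
        gvals = np.array([log_density(g) for g in grid])
        keep_g = np.isfinite(gvals)
        pts, vals = grid[keep_g], gvals[keep_g]
        if pts.size < 3:
            raise RuntimeError("log-density not finite at enough abscissae")
    else:
        pts, vals = pts[keep], vals[keep]
    env = ArsEnvelope(pts, vals, lo, hi)
    for _ in range(max_rejections):
        x = env.sample(rng)
        ux = env.upper(x)
        lx = env.lower(x)
        logu = math.log(max(rng.random(), 1e-300))
        if logu <= lx - ux:  # squeeze acceptance, no target evaluation
            return x
        hx = log_density(x)
        if hx > ux + tol:
            raise ConcavityError(
                f"target exceeds upper hull at x={x:.6g} ({hx:.6g} > {ux:.6g})")
        if np.isfinite(lx) and hx < lx - tol:
            raise ConcavityError(
                f"target below lower hull at x={x:.6g} ({hx:.6g} < {lx:.6g})")
        if logu <= hx - ux:
            return x
        if np.isfinite(hx):
            env.insert(x, hx)
    raise RuntimeError("ARS failed to accept within max_rejections proposals")


def sampling_bounds(parameter_kind: str, *, prev_beta: float = 0.0,
                    slab_variance: float = 0.0,
                    delta_halfwidth: float = 100.0) -> tuple[float, float]:
    """Hard ARS limits per parameter kind.

    Intercept (2, 5) and shape (0, 40) are fixed wide windows on the
    log-time scale; marker effects adapt to the current slab scale as the
    previous value +/- 2 sqrt(C_k sigma2_G); covariate effects default to a
    configurable wide window around zero.
    """
    if parameter_kind == "mu":
        return (2.0, 5.0)
    if parameter_kind == "alpha":
        return (0.0, 40.0)
    if parameter_kind == "beta":
        half = 2.0 * math.sqrt(slab_variance)
        return (prev_beta - half, prev_beta + half)
    if parameter_kind == "delta":
        return (-delta_halfwidth, delta_halfwidth)
    raise ValueError(f"unknown parameter kind {parameter_kind!r}")


# ---------------------------------------------------------------------------
# Adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadratureRule:
    """Gauss-Hermite nodes/weights of order m (weight function exp(-t^2))."""

    points: np.ndarray
    weights: np.ndarray
    m: int

    @property
    def log_mod_weights(self) -> np.ndarray:
        """log(w_r) + t_r^2: weights for integrating a *plain* function."""
        return np.log(self.weights) + self.points**2


@lru_cache(maxsize=16)
def hermite_rule(m: int = 25) -> QuadratureRule:
    t, w = roots_hermite(m)
    return QuadratureRule(points=t, weights=w, m=m)


@dataclass
class MixtureSpec:
    """Per-group slab variance factors and current mixture proportions.

    ``constants[g]`` is the strictly increasing vector ``(C_1 ... C_L)`` for
    group g; ``pi[g]`` the length-(L+1) proportions starting with the spike.
    """

    constants: list
    pi: list

    def __post_init__(self) -> None:
        self.constants = [np.asarray(c, float) for c in self.constants]
        self.pi = [np.asarray(p, float) for p in self.pi]
        for c, p in zip(self.constants, self.pi):
            if np.any(c <= 0) or np.any(np.diff(c) <= 0):
                raise ValueError("mixture constants must be positive and increasing")
            if p.size != c.size + 1:
                raise ValueError("pi must have one more entry than constants (spike)")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("mixture proportions must be a probability vector")

    @property
    def n_groups(self) -> int:
        return len(self.constants)


def sigma_hat(alpha: float, c_k: float, sigma2_g: float,
              weighted_x2_sum: float) -> float:
    """Quadrature scale: curvature of the slab integrand at 0.

    sigma_hat_k = 1 / (sqrt(2) sqrt(1 + alpha^2 C_k sigma2_G
                                    * sum_i x_ij^2 (exp(v_i) - exp(u_i)))).
    """
    rad = 1.0 + alpha * alpha * c_k * sigma2_g * weighted_x2_sum
    if rad <= 0:
        raise FloatingPointError(
            "negative curvature radicand: residual state is corrupted")
    return 1.0 / (math.sqrt(2.0) * math.sqrt(rad))


def log_marginal_slab(x_col: np.ndarray, wdiff: np.ndarray, dx: float,
                      alpha: float, c_k: float, sigma2_g: float,
                      rule: QuadratureRule) -> float:
    """Log slab marginal on the common (spike = sqrt(pi)) scale, dense form.

    ``wdiff`` holds exp(v_i) - exp(u_i) with the marker's own effect removed;
    ``dx = sum_i d_i x_ij``.  Evaluated in log space with a max-shift before
    the weighted sum, since the exponent differences overflow for large
    alpha.
    """
    x_col = np.asarray(x_col, float)
    wdiff = np.asarray(wdiff, float)
    shat = sigma_hat(alpha, c_k, sigma2_g, float(x_col**2 @ wdiff))
    lam = shat * math.sqrt(2.0) * rule.points * math.sqrt(2.0 * c_k * sigma2_g)
    # exponent of g_k(shat*sqrt2*t_r)/T for each node r
    with np.errstate(over="ignore"):
        inner = wdiff[None, :] * (1.0 - np.exp(
            np.minimum(-alpha * np.outer(lam, x_col), 700.0)))
    expo = (-alpha * lam * dx + inner.sum(axis=1)
            - 2.0 * shat * shat * rule.points**2)
    terms = rule.log_mod_weights + expo
    shift = float(np.max(terms))
    if not np.isfinite(shift):
        bad = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise FloatingPointError(f"non-finite quadrature summand at node {bad}")
    return (math.log(math.sqrt(2.0) * shat) + shift
            + math.log(float(np.sum(np.exp(terms - shift)))))


def marginal_likelihood_slab(x_col, wdiff, dx, alpha, c_k, sigma2_g,
                             rule: QuadratureRule | None = None) -> float:
    """Slab marginal likelihood (common scale); see :func:`log_marginal_slab`."""
    if rule is None:
        rule = hermite_rule(25)
    return math.exp(log_marginal_slab(x_col, wdiff, dx, alpha, c_k,
                                      sigma2_g, rule))


def marginal_likelihood_spike() -> float:
    """Dirac-spike marginal likelihood on the common scale.

    The C_0 -> 0 limit of the slab integral equals
    sqrt(pi) * exp{sum_i [exp(u_i) - exp(v_i)]} times the shared constant;
    divided by the common factor T = exp{sum [exp(v)-exp(u)]} used for all
    slab marginals, it is literally sqrt(pi).
    """
    return _SQRT_PI


def inclusion_probabilities(pi: np.ndarray, log_slab_marginals: np.ndarray
                            ) -> np.ndarray:
    """Posterior mixture-membership probabilities for one marker.

    Entry 0 is the spike probability; entries 1..L the slabs.  Computed via a
    max-log shift so that simultaneous underflow of all marginals still
    yields a proper probability vector (never NaN).
    """
    pi = np.asarray(pi, float)
    logm = np.concatenate([[math.log(_SQRT_PI)],
                           np.asarray(log_slab_marginals, float)])
    with np.errstate(divide="ignore"):
        logp = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf) + logm
    shift = np.max(logp)
    if not np.isfinite(shift):  # all prior mass on impossible components
        raise ValueError("no mixture component has positive prior mass")
    p = np.exp(logp - shift)
    return p / p.sum()
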