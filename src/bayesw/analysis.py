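"""Post-processing: heritability, region significance (PPWV), prediction,
and evaluation metrics.

Log-scale SNP heritability is the fraction of log-time variance attributable
to markers, h2 = sum_g sigma2_G(g) / (sum_g sigma2_G(g) + pi^2/(6 alpha^2)),
evaluated per retained posterior sample.  Region significance uses the
posterior probability of the window variance (PPWV): the posterior
probability that a region explains at least a stated fraction of the total
genetic variance.  Genomic prediction multiplies new-cohort standardised
genotypes by each sampled effect vector; posterior predictive intervals draw
one Weibull time per retained sample and take empirical quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EULER_MASCHERONI
from .gibbs import PosteriorSamples
from .sparse import GenotypeMatrix

__all__ = [
    "RegionSet",
    "PPWVResult",
    "HeritabilityEstimate",
    "heritability_log_scale",
    "ld_clump",
    "ppwv",
    "region_cap_subsample",
    "predict_genetic_values",
    "posterior_predictive_interval",
    "precision_recall",
    "fdr_vs_pip",
    "harrell_c",
    "martingale_residuals",
]


@dataclass
class RegionSet:
    """Named marker-index groupings (LD clumps, gene windows, or custom)."""

    names: list
    indices: list
    provenance: str = "custom"

    def __post_init__(self) -> None:
        self.indices = [np.asarray(ix, dtype=np.int64) for ix in self.indices]
        if len(self.names) != len(self.indices):
            raise ValueError("names and indices must align")
        if self.provenance != "gene_map":
            seen = np.concatenate(self.indices) if self.indices else np.zeros(0)
            if seen.size != np.unique(seen).size:
                raise ValueError(
                    "regions may overlap only for gene_map provenance")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class PPWVResult:
    region: str
    threshold: float
    prob: float


@dataclass
class HeritabilityEstimate:
    samples: np.ndarray
    mean: float
    ci_low: float
    ci_high: float


def heritability_log_scale(samples: PosteriorSamples) -> HeritabilityEstimate:
    """Posterior of the log-scale SNP heritability.

    Per retained sample, genetic variance is the sum of the group variances
    and the error variance is the Gumbel term pi^2 / (6 alpha^2).
    """
    sg = samples.sigma2_g.sum(axis=1)
    err = math.pi**2 / (6.0 * samples.alpha**2)
    h2 = sg / (sg + err)
    lo, hi = np.percentile(h2, [2.5, 97.5]) if h2.size else (np.nan, np.nan)
    return HeritabilityEstimate(samples=h2, mean=float(h2.mean()),
                                ci_low=float(lo), ci_high=float(hi))


def ld_clump(X: GenotypeMatrix, window_bp: float = 10e6,
             r2_threshold: float = 0.1,
             rank: np.ndarray | None = None) -> RegionSet:
    """Greedy LD clumping: every marker ends up in exactly one clump.

    Index SNPs are chosen in decreasing order of ``rank`` (posterior
    inclusion probability when a fit is available, otherwise minor allele
    frequency); markers within ``window_bp`` of an index with r^2 >=
    ``r2_threshold`` join its clump and are removed from consideration, so
    the surviving inter-index correlations are below the threshold.
    """
    m = X.n_markers
    pos = X.markers["pos"].to_numpy()
    chrom = X.markers["chrom"].to_numpy()
    if rank is None:
        rank = X.maf
    order = np.argsort(-np.asarray(rank, float), kind="stable")
    unassigned = np.ones(m, dtype=bool)
    names, indices = [], []
    std_cache: dict[int, np.ndarray] = {}

    def std_col(j):
        col = std_cache.get(j)
        if col is None:
            col = X.standardized_col(j)
            std_cache[j] = col
        return col

    for j in order:
        if not unassigned[j]:
            continue
        near = np.flatnonzero(
            unassigned & (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= window_bp))
        near = near[near != j]
        members = [j]
        if near.size and r2_threshold < 1.0:
            xj = std_col(j)
            block = np.column_stack([std_col(i) for i in near])
            r2 = (xj @ block / X.n_individuals) ** 2
            members.extend(near[r2 >= r2_threshold].tolist())
        for i in members:
            unassigned[i] = False
        names.append(str(X.ids[j]))
        indices.append(np.asarray(sorted(members), dtype=np.int64))
        std_cache.clear()
    return RegionSet(names=names, indices=indices, provenance="ld_clump")


DEFAULT_PPWV_THRESHOLDS = (1e-5, 1e-4, 1e-3)


def ppwv(samples: PosteriorSamples, X: GenotypeMatrix, regions: RegionSet,
         thresholds=DEFAULT_PPWV_THRESHOLDS,
         method: str = "genotypic") -> list[PPWVResult]:
    """Posterior probability that each region explains at least a threshold
    share of the total genetic variance.

    Per retained sample the region's genetic variance is the variance over
    individuals of ``X_region beta_region`` and the denominator is that
    sample's total genetic variance (self-consistent per-sample scaling).
    ``method='independent'`` uses the sum of squared standardised effects —
    equivalent for uncorrelated markers and much faster.
    """
    for name, ix in zip(regions.names, regions.indices):
        if ix.size == 0:
            raise ValueError(f"region {name!r} is empty")
    bmat = samples.beta_matrix()           # (S, M)
    s_count = samples.n_samples
    if method == "independent":
        total = np.maximum((bmat**2).sum(axis=1), 1e-300)
        shares = np.empty((len(regions), s_count))
        for r, ix in enumerate(regions.indices):
            shares[r] = (bmat[:, ix]**2).sum(axis=1) / total
    elif method == "genotypic":
        g_tot = X.toarray() @ bmat.T        # (n, S); only nonzero betas matter
        total = np.maximum(g_tot.var(axis=0), 1e-300)
        shares = np.empty((len(regions), s_count))
        nonzero_any = np.zeros(samples.n_markers, dtype=bool)
        nonzero_any[np.unique(samples.beta_marker)] = True
        for r, ix in enumerate(regions.indices):
            if not nonzero_any[ix].any():
                shares[r] = 0.0
                continue
            xr = np.column_stack([X.standardized_col(j) for j in ix])
            gr = xr @ bmat[:, ix].T
            shares[r] = gr.var(axis=0) / total
    else:
        raise ValueError("method must be 'genotypic' or 'independent'")
    out = []
    for r, name in enumerate(regions.names):
        for thr in thresholds:
            out.append(PPWVResult(region=name, threshold=float(thr),
                                  prob=float(np.mean(shares[r] >= thr))))
    return out


def region_cap_subsample(region: np.ndarray, cap: int = 250,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Randomly keep at most ``cap`` markers of a region (gene windows can
    contain far more markers than LD clumps; capping keeps them comparable)."""
    region = np.asarray(region, dtype=np.int64)
    if region.size <= cap:
        return region
    rng = np.random.default_rng() if rng is None else rng
    return np.sort(rng.choice(region, size=cap, replace=False))


def predict_genetic_values(samples: PosteriorSamples, X_new
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample genetic values on a new cohort plus the posterior-mean
    predictor.

    ``X_new`` is standardised with the new cohort's own means/SDs (a
    GenotypeMatrix standardises itself; a dense array is taken as given).
    Returns (g_samples with shape (S, n_new), posterior-mean per individual).
    """
    xs = X_new.toarray() if isinstance(X_new, GenotypeMatrix) else np.asarray(X_new, float)
    if xs.shape[1] != samples.n_markers:
        raise ValueError(
            f"marker mismatch: chain has {samples.n_markers} markers, "
            f"new cohort has {xs.shape[1]}")
    g = samples.beta_matrix() @ xs.T
    return g, g.mean(axis=0)


def posterior_predictive_interval(samples: PosteriorSamples, X_new,
                                  covariates: np.ndarray | None = None,
                                  level: float = 0.95,
                                  rng: np.random.Generator | None = None
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual posterior predictive time interval.

    For each retained sample one Weibull time is drawn from the implied
    log-time law ``log t = mu + g + z'delta + (log E + K)/alpha`` with
    E ~ Exp(1); the interval is the empirical central ``level`` quantile
    band of those draws, on the original time scale.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    g, _ = predict_genetic_values(samples, X_new)
    s, n = g.shape
    lp = g + samples.mu[:, None]
    if covariates is not None and samples.delta.shape[1]:
        lp = lp + (np.asarray(covariates, float) @ samples.delta.T).T
    log_e = np.log(rng.standard_exponential((s, n)))
    log_t = lp + (log_e + EULER_MASCHERONI) / samples.alpha[:, None]
    qlo, qhi = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    lo, hi = np.quantile(np.exp(log_t), [qlo, qhi], axis=0)
    return lo, hi


def precision_recall(scores: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Precision (1 - FDR) and recall at every distinct score cut."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    n_pos = truth.sum()
    cuts = np.unique(scores)[::-1]
    rows = []
    for c in cuts:
        sel = scores >= c
        tp = int((sel & truth).sum())
        denom = int(sel.sum())
        rows.append((float(c),
                     tp / denom if denom else np.nan,
                     tp / n_pos if n_pos else np.nan))
    return pd.DataFrame(rows, columns=["cut", "precision", "recall"])


def fdr_vs_pip(pip: np.ndarray, truth: np.ndarray,
               grid: np.ndarray) -> pd.DataFrame:
    """False discovery rate among markers selected at each PIP cut.

    Cuts above the largest PIP select nothing and are reported as absent
    (dropped rather than NaN-filled).
    """
    pip = np.asarray(pip, float)
    truth = np.asarray(truth, bool)
    rows = []
    for c in np.asarray(grid, float):
        sel = pip >= c
        n_sel = int(sel.sum())
        if n_sel == 0:
            continue
        fdr = float((sel & ~truth).sum()) / n_sel
        rows.append((float(c), fdr, n_sel))
    return pd.DataFrame(rows, columns=["cut", "fdr", "n_selected"])


def harrell_c(predictor: np.ndarray, times: np.ndarray,
              failure: np.ndarray) -> float:
    """Harrell's concordance: higher predictor means longer predicted
    survival; pairs are usable when the earlier time is an observed event."""
    from lifelines.utils import concordance_index

    failure = np.asarray(failure)
    if failure.sum() == 0:
        raise ValueError("no usable pairs: all observations censored")
    return float(concordance_index(np.asarray(times, float),
                                   np.asarray(predictor, float), failure))


def martingale_residuals(times: np.ndarray, failure: np.ndarray,
                         covariates: np.ndarray | None = None) -> np.ndarray:
    """d_i - Lambda0(t_i) exp(z_i' gamma): observed minus expected events.

    Without covariates, Lambda0 is the Nelson-Aalen estimator.  With
    covariates, gamma comes from a Cox partial-likelihood fit and the
    residuals use Breslow tie handling (lifelines' martingale residuals).
    """
    times = np.asarray(times, float)
    failure = np.asarray(failure, int)
    if covariates is None or np.size(covariates) == 0:
        from lifelines import NelsonAalenFitter

        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times, event_observed=failure)
        cumhaz = naf.cumulative_hazard_at_times(times).to_numpy()
        return failure - cumhaz
    from lifelines import CoxPHFitter

    cov = np.atleast_2d(np.asarray(covariates, float))
    if cov.shape[0] != times.shape[0]:
        cov = cov.T
    df = pd.DataFrame(cov, columns=[f"z{i}" for i in range(cov.shape[1])])
    df["time"] = times
    df["event"] = failure
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    res = cph.compute_residuals(df, kind="martingale")
    return res["martingale"].to_numpy()[np.argsort(res.index.to_numpy())]
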