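"""Gamma-tail p-values, Fisher combination and stable-site calling.

Both stability features are non-negative with right-tailed distributions, so
each marginal is modelled with a gamma distribution fitted by maximum
likelihood over the filtered sites. Stability evidence is the *upper* tail of
the recurrence fit (seen unusually often) and the *lower* tail of the
phosphorylation-change fit (moves unusually little). The two p-values are
combined with Fisher's method, -2 Σ ln p ~ χ² with 4 degrees of freedom, and
sites with combined P below a threshold (default 0.01) are called stably
phosphorylated (SPS).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .features import StabilityFeatures, compute_features
from .io import Collection, SiteId

logger = logging.getLogger(__name__)

#: floor applied to component p-values before taking logs
P_FLOOR = 1e-300


class GammaFitError(RuntimeError):
    """Raised when the gamma maximum-likelihood fit cannot converge."""


@dataclass(frozen=True)
class GammaFit:
    """Fitted gamma marginal with shape ``alpha`` and *rate* ``beta``."""

    alpha: float
    beta: float
    n: int
    loglik: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if not math.isfinite(self.alpha / self.beta):
            raise ValueError("fitted mean alpha/beta is not finite")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta


@dataclass(frozen=True)
class StabilityResult:
    """Per-site stability statistics and the SPS call."""

    site: SiteId
    features: StabilityFeatures
    p_recurrence: float
    p_change: float
    p_combined: float
    is_sps: bool


def fit_gamma(values: Iterable[float]) -> GammaFit:
    """Maximum-likelihood gamma fit with method-of-moments initialization
    (alpha0 = mean²/var, beta0 = mean/var)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 10:
        raise ValueError(f"need >= 10 values to fit a gamma, got {vals.size}")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values in gamma fit input")
    if np.any(vals <= 0):
        raise ValueError("gamma fit requires strictly positive values")
    m = float(vals.mean())
    v = float(vals.var(ddof=1))
    if v <= 0:
        raise GammaFitError("constant input: gamma fit cannot converge (zero variance)")
    alpha0 = m * m / v
    scale0 = v / m
    try:
        alpha, loc, scale = stats.gamma.fit(vals, alpha0, floc=0, scale=scale0)
    except Exception as exc:  # pragma: no cover - scipy raises rarely here
        raise GammaFitError(f"gamma MLE failed: {exc}") from exc
    if not (np.isfinite(alpha) and np.isfinite(scale) and alpha > 0 and scale > 0):
        raise GammaFitError(
            f"gamma MLE did not converge (alpha={alpha}, scale={scale}, "
            f"n={vals.size}, mean={m:.4g}, var={v:.4g})"
        )
    loglik = float(stats.gamma.logpdf(vals, alpha, scale=scale).sum())
    return GammaFit(alpha=float(alpha), beta=1.0 / float(scale), n=vals.size, loglik=loglik)


def gamma_upper_tail(fit: GammaFit, x: float) -> float:
    """P(X > x) under the fitted gamma: the recurrence stability p-value."""
    if x < 0:
        raise ValueError("x must be non-negative")
    return float(stats.gamma.sf(x, fit.alpha, scale=1.0 / fit.beta))


def gamma_lower_tail(fit: GammaFit, x: float) -> float:
    """P(X <= x) under the fitted gamma: the phosphorylation-change p-value.

    Exact complement of :func:`gamma_upper_tail`.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    return float(stats.gamma.cdf(x, fit.alpha, scale=1.0 / fit.beta))


def fisher_combine(pvalues) -> float | np.ndarray:
    """Combine p-values with Fisher's method.

    For a length-k vector returns the survival probability of a chi-square
    with 2k degrees of freedom at -2 Σ ln p. A 2-D array of shape (m, k)
    combines each row, returning a length-m array. Component p-values must be
    in (0, 1]; they are floored at 1e-300 before logs.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim not in (1, 2) or p.shape[-1] < 1:
        raise ValueError("pvalues must be a non-empty vector or (m, k) array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = p.shape[-1]
    stat = -2.0 * np.sum(np.log(np.maximum(p, P_FLOOR)), axis=-1)
    combined = stats.chi2.sf(stat, 2 * k)
    if p.ndim == 1:
        return float(combined)
    return combined


def fit_stability_models(
    features: Sequence[StabilityFeatures],
) -> tuple[GammaFit, GammaFit, int]:
    """Fit the gamma marginals for recurrence (X1) and phosphorylation change
    (X2) over the filtered sites.

    Exact-zero phosphorylation changes (perfectly stable sites) lie outside
    the gamma support; they are replaced by half the smallest positive
    observed value for fitting and evaluation, with the count logged.
    Returns (recurrence fit, change fit, number of zeros replaced).
    """
    x1 = np.array([f.recurrence for f in features], dtype=float)
    x2 = np.array([f.phospho_change for f in features], dtype=float)
    n_zero = int(np.sum(x2 == 0.0))
    if n_zero:
        positive = x2[x2 > 0]
        if positive.size == 0:
            raise GammaFitError("all phospho_change values are zero; cannot fit gamma")
        x2 = np.where(x2 == 0.0, positive.min() / 2.0, x2)
        logger.warning(
            "replaced %d exact-zero phospho_change value(s) by half the "
            "smallest positive value before gamma fitting",
            n_zero,
        )
    return fit_gamma(x1), fit_gamma(x2), n_zero


def call_sps(
    features: Sequence[StabilityFeatures],
    threshold: float = 0.01,
    fits: tuple[GammaFit, GammaFit] | None = None,
) -> list[StabilityResult]:
    """Assign stability p-values to every filtered site and call SPSs.

    p_recurrence is the upper tail of the recurrence fit at the site's
    recurrence; p_change the lower tail of the change fit at the site's
    phosphorylation change (zeros evaluated at half the smallest positive
    value, mirroring the fitting rule); p_combined their Fisher combination.
    ``is_sps`` is strict: p_combined < threshold.
    """
    if not features:
        raise ValueError("features must be non-empty")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if fits is None:
        fit_x1, fit_x2, _ = fit_stability_models(features)
    else:
        fit_x1, fit_x2 = fits
    x2_all = np.array([f.phospho_change for f in features])
    positive = x2_all[x2_all > 0]
    zero_sub = positive.min() / 2.0 if positive.size else None
    results = []
    for f in features:
        p1 = max(gamma_upper_tail(fit_x1, float(f.recurrence)), P_FLOOR)
        x2 = f.phospho_change if f.phospho_change > 0 else zero_sub
        if x2 is None:
            raise GammaFitError("cannot evaluate p_change: no positive values")
        p2 = max(gamma_lower_tail(fit_x2, x2), P_FLOOR)
        pc = max(float(fisher_combine([p1, p2])), P_FLOOR)
        results.append(
            StabilityResult(
                site=f.site,
                features=f,
                p_recurrence=p1,
                p_change=p2,
                p_combined=pc,
                is_sps=pc < threshold,
            )
        )
    return results


def feature_correlation(features: Sequence[StabilityFeatures]) -> float:
    """Pearson correlation between recurrence and phosphorylation change over
    the filtered sites (a diagnostic: the framework combines the two tails
    with Fisher's method, which formally assumes independence)."""
    x1 = np.array([f.recurrence for f in features], dtype=float)
    x2 = np.array([f.phospho_change for f in features], dtype=float)
    return float(stats.pearsonr(x1, x2).statistic)


def run_identification(
    collection: Collection,
    fraction: float = 0.20,
    threshold: float = 0.01,
) -> dict:
    """Run the full identification pipeline on a collection.

    Returns a dict with keys ``features``, ``results``, ``fit_recurrence``,
    ``fit_change``, ``n_zero_replaced``, ``feature_correlation``, ``n_sps``.
    """
    feats = compute_features(collection, fraction)
    fit_x1, fit_x2, n_zero = fit_stability_models(feats)
    results = call_sps(feats, threshold, fits=(fit_x1, fit_x2))
    return {
        "features": feats,
        "results": results,
        "fit_recurrence": fit_x1,
        "fit_change": fit_x2,
        "n_zero_replaced": n_zero,
        "feature_correlation": feature_correlation(feats),
        "n_sps": sum(r.is_sps for r in results),
    }


def subsample_reproducibility(
    collection: Collection,
    keep_fraction: float = 0.8,
    repeats: int = 10,
    seed: int = 0,
    fraction: float = 0.20,
    threshold: float = 0.01,
) -> np.ndarray:
    """Reproducibility of the stability statistic under dataset subsampling.

    Repeats times, a random floor(keep_fraction x D) subset of datasets is
    drawn (without replacement within each repeat) and the full pipeline is
    re-run; the returned repeats x repeats symmetric matrix holds the Pearson
    correlation of -log10 combined p over the sites shared by each pair of
    subsamples.
    """
    D = collection.n_datasets
    if D < 3:
        raise ValueError("need at least 3 datasets for subsampling")
    if not (0 < keep_fraction < 1):
        raise ValueError("keep_fraction must be in (0, 1)")
    m = max(2, int(math.floor(keep_fraction * D)))
    if m < 2:
        raise ValueError("subsample leaves fewer than 2 datasets")
    rng = np.random.default_rng(seed)
    stat_maps: list[dict[SiteId, float]] = []
    for _ in range(repeats):
        idx = rng.choice(D, size=m, replace=False)
        sub = Collection(datasets=[collection.datasets[i] for i in sorted(idx)])
        feats = compute_features(sub, fraction)
        results = call_sps(feats, threshold)
        stat_maps.append({r.site: -math.log10(r.p_combined) for r in results})
    corr = np.eye(repeats)
    for i in range(repeats):
        for j in range(i + 1, repeats):
            common = sorted(set(stat_maps[i]) & set(stat_maps[j]), key=str)
            if len(common) < 3:
                raise ValueError(
                    f"subsamples {i} and {j} share fewer than 3 filtered sites"
                )
            a = np.array([stat_maps[i][s] for s in common])
            b = np.array([stat_maps[j][s] for s in common])
            corr[i, j] = corr[j, i] = float(stats.pearsonr(a, b).statistic)
    return corr
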