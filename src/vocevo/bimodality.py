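"""Two-component Gaussian mixture bimodality analysis.

Several USV features (peak-frequency maximum, syllable duration) are
bimodal: the population splits into "low"/"high" or "short"/"long" calls.
This module fits a two-component univariate Gaussian mixture by EM,
quantifies the separation with Ashman's D

    D = sqrt(2) |mu1 - mu2| / sqrt(sigma1^2 + sigma2^2),

(D > 2 indicating well-separated modes), and splits observations at the
intersection of the two weighted component densities — the point where
w1 N(x; mu1, sigma1) = w2 N(x; mu2, sigma2) between the two means.  A
fixed physical cutoff (e.g. 100 kHz for high-Fq_max calls, "high" strictly
exceeding the threshold) is available as an alternative splitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

__all__ = [
    "Gauss2Fit",
    "BimodalSplit",
    "TwoGaussianBimodality",
    "fit_two_gaussians",
    "ashman_d",
    "mixture_intersection",
    "split_by_cutoff",
    "fixed_cutoff_split",
]

ASHMAN_BIMODAL_THRESHOLD = 2.0


@dataclass(frozen=True)
class Gauss2Fit:
    """Two-component univariate Gaussian mixture (mu1 <= mu2)."""

    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    loglik: float
    converged: bool
    seed: int


@dataclass
class BimodalSplit:
    """Low/high labels at a cutoff, with per-group high-label ratios."""

    cutoff: float
    labels: np.ndarray                    # "low" / "high" per observation
    ashman_d: float | None = None
    per_group_ratio: pd.DataFrame | None = None


def fit_two_gaussians(values, n_starts: int = 10, seed: int = 0,
                      tol: float = 1e-6, max_iter: int = 500) -> Gauss2Fit:
    """Best-of-restarts EM fit of a two-Gaussian mixture.

    One start is anchored at the 25th/75th percentiles of the data, the
    remaining ``n_starts - 1`` use random responsibilities; the fit with
    the highest log-likelihood wins.  Component standard deviations are
    floored at 1e-6 of the data range to prevent variance collapse.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 finite observations, got {x.size}")
    rng_span = float(np.ptp(x))
    if rng_span == 0:
        raise ValueError("degenerate data: all observations are equal")
    reg = max((1e-6 * rng_span) ** 2, 1e-12)
    X = x.reshape(-1, 1)
    anchors = np.percentile(x, [25, 75]).reshape(-1, 1)
    best = None
    for start in range(max(1, int(n_starts))):
        kwargs = dict(n_components=2, covariance_type="full", tol=tol,
                      max_iter=max_iter, reg_covar=reg, n_init=1,
                      random_state=np.random.SeedSequence(
                          [seed, start]).generate_state(1)[0] % (2**31))
        if start == 0:
            gm = GaussianMixture(means_init=anchors, **kwargs)
        else:
            gm = GaussianMixture(init_params="random", **kwargs)
        gm.fit(X)
        score = gm.lower_bound_
        if best is None or score > best[0]:
            best = (score, gm)
    gm = best[1]
    order = np.argsort(gm.means_.ravel())
    mu = gm.means_.ravel()[order]
    sigma = np.sqrt(gm.covariances_.ravel()[order])
    w = gm.weights_[order]
    loglik = float(gm.score(X) * x.size)
    return Gauss2Fit(w1=float(w[0]), w2=float(w[1]),
                     mu1=float(mu[0]), mu2=float(mu[1]),
                     sigma1=float(sigma[0]), sigma2=float(sigma[1]),
                     loglik=loglik, converged=bool(gm.converged_), seed=seed)


def ashman_d(fit: Gauss2Fit) -> float:
    """Ashman's D separation score of the fitted mixture."""
    return float(np.sqrt(2.0) * abs(fit.mu1 - fit.mu2)
                 / np.sqrt(fit.sigma1**2 + fit.sigma2**2))


def mixture_intersection(fit: Gauss2Fit, weighted: bool = True
                         ) -> float | None:
    """Cutoff where the two (weighted) component densities intersect.

    Solves ``w1 phi(x; mu1, s1) = w2 phi(x; mu2, s2)`` — a quadratic in x
    after taking logs — and returns the root strictly between the two
    means, or None when no such root exists.  With ``weighted=False`` the
    raw densities are intersected (w1 = w2).
    """
    if not fit.mu1 < fit.mu2:
        raise ValueError("mixture_intersection requires mu1 < mu2")
    w1, w2 = (fit.w1, fit.w2) if weighted else (1.0, 1.0)
    s1, s2 = fit.sigma1, fit.sigma2
    mu1, mu2 = fit.mu1, fit.mu2
    # log w1 - log s1 - (x-mu1)^2/(2 s1^2) = log w2 - log s2 - (x-mu2)^2/(2 s2^2)
    a = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    b = mu1 / s1**2 - mu2 / s2**2
    c = (mu2**2 / (2 * s2**2) - mu1**2 / (2 * s1**2)
         + np.log((w1 * s2) / (w2 * s1)))
    if abs(a) < 1e-300:  # equal sigmas: linear special case
        if b == 0:
            return None
        roots = np.array([-c / b])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            return None
        roots = np.array([(-b - np.sqrt(disc)) / (2 * a),
                          (-b + np.sqrt(disc)) / (2 * a)])
    inside = roots[(roots > mu1) & (roots < mu2)]
    if inside.size == 0:
        return None
    return float(inside[0])


def split_by_cutoff(table: pd.DataFrame, feature: str, cutoff: float,
                    by: list[str] | None = None,
                    strict: bool = True) -> BimodalSplit:
    """Label observations low/high at a cutoff and compute group ratios.

    ``strict=True`` labels "high" only values strictly exceeding the
    cutoff.  With ``by`` (e.g. ``["animal_id", "class"]``) a per-group
    high-label ratio table is attached; groups with zero observations are
    simply absent from it.
    """
    values = table[feature].to_numpy(dtype=float)
    if strict:
        labels = np.where(values > cutoff, "high", "low")
    else:
        labels = np.where(values >= cutoff, "high", "low")
    result = BimodalSplit(cutoff=float(cutoff), labels=labels)
    if by:
        tmp = table[by].copy()
        tmp["__high"] = labels == "high"
        grp = tmp.groupby(by, observed=True)["__high"]
        ratios = grp.mean().rename("high_ratio").reset_index()
        ratios["low_ratio"] = 1.0 - ratios["high_ratio"]
        ratios["n"] = grp.size().to_numpy()
        result.per_group_ratio = ratios
    return result


def fixed_cutoff_split(values, threshold: float = 100.0) -> np.ndarray:
    """Labels at a fixed physical threshold ("high" = strictly exceeding).

    The conventional adult high-Fq_max cutoff is 100 kHz.
    """
    values = np.asarray(values, dtype=float)
    return np.where(values > threshold, "high", "low")


class TwoGaussianBimodality(BaseEstimator):
    """Fit-and-split estimator for one bimodal feature.

    ``fit`` runs EM, computes Ashman's D and — when ``D > 2`` (the
    conventional good-separation criterion) — the weighted-density
    intersection cutoff.  ``predict`` labels new values low/high at the
    fitted cutoff.  Features with ``D <= 2`` are reported unimodal and not
    split (``cutoff_`` is None, ``predict`` raises).

    Attributes (after fit)
    ----------------------
    w1_, w2_, mu1_, mu2_, sigma1_, sigma2_, loglik_, converged_ : mixture
    ashman_d_ : separation score
    is_bimodal_ : ``ashman_d_ > 2``
    cutoff_ : intersection cutoff, or None when unimodal/undefined
    """

    def __init__(self, n_starts: int = 10, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 500, weighted_cutoff: bool = True,
                 bimodal_threshold: float = ASHMAN_BIMODAL_THRESHOLD):
        self.n_starts = n_starts
        self.seed = seed
        self.tol = tol
        self.max_iter = max_iter
        self.weighted_cutoff = weighted_cutoff
        self.bimodal_threshold = bimodal_threshold

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        fit = fit_two_gaussians(x, n_starts=self.n_starts, seed=self.seed,
                                tol=self.tol, max_iter=self.max_iter)
        self.fit_ = fit
        self.w1_, self.w2_ = fit.w1, fit.w2
        self.mu1_, self.mu2_ = fit.mu1, fit.mu2
        self.sigma1_, self.sigma2_ = fit.sigma1, fit.sigma2
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.ashman_d_ = ashman_d(fit)
        self.is_bimodal_ = self.ashman_d_ > self.bimodal_threshold
        self.cutoff_ = (mixture_intersection(fit, self.weighted_cutoff)
                        if self.is_bimodal_ else None)
        return self

    def predict(self, X) -> np.ndarray:
        if getattr(self, "cutoff_", None) is None:
            raise ValueError(
                "no cutoff available: feature is unimodal (Ashman's D <= "
                f"{self.bimodal_threshold}) or the densities do not "
                "intersect between the means")
        x = np.asarray(X, dtype=float).ravel()
        return np.where(x > self.cutoff_, "high", "low")

    def to_json_dict(self) -> dict:
        """Fit parameters in the shape written by the CLI."""
        return {
            "w": [self.w1_, self.w2_], "mu": [self.mu1_, self.mu2_],
            "sigma": [self.sigma1_, self.sigma2_], "loglik": self.loglik_,
            "ashman_d": self.ashman_d_, "cutoff": self.cutoff_,
            "is_bimodal": bool(self.is_bimodal_), "seed": self.seed,
        }
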