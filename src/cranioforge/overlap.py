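"""Bayesian probabilistic overlap of group morphospaces.

Each group's trait cloud (here PC1, PC2 and log10 centroid size) is modelled
as multivariate normal.  Under the noninformative prior
p(mu, Sigma) ~ |Sigma|^-((d+1)/2) the posterior is conjugate:
Sigma ~ inverse-Wishart(n-1, centred cross-product matrix) and
mu | Sigma ~ Normal(sample mean, Sigma/n).  The overlap of group A onto
group B is the probability that a random draw from A's distribution falls
inside B's alpha-probability ellipsoid (the "niche region"); propagating the
posterior of both groups yields a posterior distribution of overlap
probabilities, summarized by its mean and 95% credible interval.  Overlap is
directional: overlap(A, B) != overlap(B, A) in general.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class OverlapPosterior:
    """Posterior overlap draws for one ordered group pair (A onto B)."""

    pair: tuple
    draws: np.ndarray  # overlap probabilities in [0, 1], length n_posterior
    alpha: float

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def ci(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.draws, [2.5, 97.5])
        return float(lo), float(hi)


def posterior_mvn_draws(
    X_g: np.ndarray, n_posterior: int, random_state=None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw (mean, covariance) pairs from the conjugate MVN posterior."""
    X = np.atleast_2d(np.asarray(X_g, dtype=float))
    n, d = X.shape
    if n <= d:
        raise ValueError(f"insufficient group size: n={n} must exceed trait dimension d={d}")
    rng = np.random.default_rng(random_state)
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    iw = sps.invwishart(df=n - 1, scale=S)
    draws = []
    for _ in range(n_posterior):
        Sigma = np.atleast_2d(iw.rvs(random_state=rng))
        L = np.linalg.cholesky(Sigma / n)
        mu = xbar + L @ rng.standard_normal(d)
        draws.append((mu, Sigma))
    return draws


def overlap_probability(
    mean_a: np.ndarray,
    cov_a: np.ndarray,
    mean_b: np.ndarray,
    cov_b: np.ndarray,
    alpha: float = 0.95,
    n_mc: int = 10_000,
    random_state=None,
) -> float:
    """Monte-Carlo Pr(X in B's alpha-region) for X ~ Normal(mean_a, cov_a).

    The niche region of B is the set of points whose squared Mahalanobis
    distance from mean_b under cov_b is at most the chi-square(d) alpha
    quantile.  With a fixed seed the estimate is monotone increasing in alpha
    because only the threshold changes.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    mean_a = np.atleast_1d(np.asarray(mean_a, dtype=float))
    mean_b = np.atleast_1d(np.asarray(mean_b, dtype=float))
    cov_a = np.atleast_2d(np.asarray(cov_a, dtype=float))
    cov_b = np.atleast_2d(np.asarray(cov_b, dtype=float))
    d = mean_a.size
    rng = np.random.default_rng(random_state)
    try:
        La = np.linalg.cholesky(cov_a)
        np.linalg.cholesky(cov_b)
    except np.linalg.LinAlgError:
        raise ValueError("covariance matrices must be positive-definite") from None
    X = mean_a + rng.standard_normal((n_mc, d)) @ La.T
    d2 = _mahal_sq(X, mean_b, cov_b)
    return float(np.mean(d2 <= sps.chi2.ppf(alpha, d)))


def _mahal_sq(X: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(Sigma)
    from scipy.linalg import solve_triangular

    y = solve_triangular(L, (X - mu).T, lower=True)
    return np.sum(y**2, axis=0)


class MorphospaceOverlap:
    """Posterior morphospace overlap for all ordered group pairs.

    Parameters: ``alpha`` (niche-region probability level), ``n_posterior``
    (posterior iterations, 3000 by default), ``n_mc`` (Monte-Carlo draws per
    overlap evaluation), ``random_state``.  After ``fit(X, groups)`` the
    attribute ``results_`` maps each ordered pair to an
    :class:`OverlapPosterior`.
    """

    def __init__(self, alpha: float = 0.95, n_posterior: int = 3000, n_mc: int = 10_000, random_state=None):
        self.alpha = alpha
        self.n_posterior = n_posterior
        self.n_mc = n_mc
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha, "n_posterior": self.n_posterior,
            "n_mc": self.n_mc, "random_state": self.random_state,
        }

    def set_params(self, **params) -> "MorphospaceOverlap":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, groups: Sequence) -> "MorphospaceOverlap":
        X = np.asarray(X, dtype=float)
        groups = np.asarray([str(g) for g in groups])
        per_group = {lv: X[groups == lv] for lv in dict.fromkeys(groups)}
        self.results_ = overlap_matrix(
            per_group, alpha=self.alpha, n_posterior=self.n_posterior,
            n_mc=self.n_mc, random_state=self.random_state,
        )
        return self


def overlap_matrix(
    dataset: Mapping[str, np.ndarray],
    alpha: float = 0.95,
    n_posterior: int = 3000,
    n_mc: int = 10_000,
    random_state=None,
) -> dict[tuple, OverlapPosterior]:
    """Posterior overlap draws for every ordered pair of groups.

    Per posterior iteration, one (mu, Sigma) is drawn for every group and the
    Monte-Carlo sample of each group is reused against every other group's
    niche region, so all pairwise overlaps within an iteration share the same
    parameter draw.
    """
    rng = np.random.default_rng(random_state)
    names = list(dataset.keys())
    stats = {}
    d = None
    for name in names:
        X = np.atleast_2d(np.asarray(dataset[name], dtype=float))
        n, dd = X.shape
        d = dd if d is None else d
        if dd != d:
            raise ValueError("all groups must share the trait dimension")
        if n <= d:
            raise ValueError(f"insufficient group size for group {name!r}: n={n} <= d={d}")
        xbar = X.mean(axis=0)
        S = (X - xbar).T @ (X - xbar)
        stats[name] = (n, xbar, sps.invwishart(df=n - 1, scale=S))
    thresh = float(sps.chi2.ppf(alpha, d))

    pairs = [(a, b) for a in names for b in names if a != b]
    draws = {p: np.empty(n_posterior) for p in pairs}
    from scipy.linalg import solve_triangular

    for it in range(n_posterior):
        params = {}
        samples = {}
        for name in names:
            n, xbar, iw = stats[name]
            Sigma = np.atleast_2d(iw.rvs(random_state=rng))
            Ln = np.linalg.cholesky(Sigma / n)
            mu = xbar + Ln @ rng.standard_normal(d)
            params[name] = (mu, Sigma, np.linalg.cholesky(Sigma))
            samples[name] = mu + rng.standard_normal((n_mc, d)) @ params[name][2].T
        for a, b in pairs:
            mu_b, Sigma_b, Lb = params[b]
            y = solve_triangular(Lb, (samples[a] - mu_b).T, lower=True)
            draws[(a, b)][it] = np.mean(np.sum(y**2, axis=0) <= thresh)

    return {p: OverlapPosterior(pair=p, draws=draws[p], alpha=alpha) for p in pairs}
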