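"""Multivariate shape statistics.

* covariance-matrix PCA with a deterministic sign convention and a Monte
  Carlo (column-permutation) test of axis significance;
* Procrustes ANOVA: sequential (Type I) decomposition of a multivariate
  response with trace-based sums of squares and residual-randomization
  permutation (RRPP) p-values and effect sizes;
* pairwise group contrasts on mean vectors (for Procrustes coordinates the
  statistic is the Procrustes distance between group mean shapes) with
  permutation p-values and multiple-testing correction.

The trace-based SS makes every statistic invariant to rotation of the
response space, which is what licenses running the ANOVA on Procrustes
coordinates or on PC scores interchangeably.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TERMS_DEFAULT = ("group", "sex", "size", "group:size", "sex:size")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # variances per axis, non-increasing
    proportion: np.ndarray  # fraction of total variance per axis
    loadings: np.ndarray  # (p, k)
    mean: np.ndarray
    axis_p: Optional[np.ndarray] = None
    dropped_ids: list = field(default_factory=list)


class ShapePCA:
    """PCA of a specimen-by-variable matrix on the covariance matrix.

    Sign convention: the largest-magnitude entry of each loading column is
    positive, so axes are reproducible across runs and platforms.  Rows with
    missing cells are dropped with their ids logged.
    """

    def __init__(self, n_components: Optional[int] = None):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "ShapePCA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, ids: Optional[Sequence] = None) -> "ShapePCA":
        X = np.asarray(X, dtype=float)
        keep = ~np.any(np.isnan(X), axis=1)
        self.dropped_ids_ = (
            [ids[i] for i in np.flatnonzero(~keep)] if ids is not None else list(np.flatnonzero(~keep))
        )
        if self.dropped_ids_:
            logger.info("PCA dropped %d rows with missing cells: %s", len(self.dropped_ids_), self.dropped_ids_)
        X = X[keep]
        n, p = X.shape
        if n < 3:
            raise ValueError(f"PCA needs at least 3 complete rows, got {n}")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        eig = s**2 / (n - 1)
        k = min(n - 1, p)
        eig, Vt, U, s = eig[:k], Vt[:k], U[:, :k], s[:k]
        # deterministic signs
        flip = np.where(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)] < 0, -1.0, 1.0)
        Vt = Vt * flip[:, None]
        if self.n_components is not None:
            keep_k = min(self.n_components, k)
            eig, Vt = eig[:keep_k], Vt[:keep_k]
        self.loadings_ = Vt.T
        self.eigenvalues_ = eig
        total = np.sum(s**2 / (n - 1))
        self.proportion_ = eig / total
        self.scores_ = Xc @ self.loadings_
        self.n_samples_ = n
        self._fitted_X = X
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.loadings_

    def fit_transform(self, X: np.ndarray, ids: Optional[Sequence] = None) -> np.ndarray:
        return self.fit(X, ids).scores_

    def result(self) -> PcaResult:
        return PcaResult(
            scores=self.scores_,
            eigenvalues=self.eigenvalues_,
            proportion=self.proportion_,
            loadings=self.loadings_,
            mean=self.mean_,
            axis_p=getattr(self, "axis_p_", None),
            dropped_ids=self.dropped_ids_,
        )

    def axis_significance(self, n_perm: int = 999, random_state=None) -> np.ndarray:
        self.axis_p_ = axis_significance(self._fitted_X, n_perm=n_perm, random_state=random_state)
        return self.axis_p_


def pca(X: np.ndarray, matrix_type: str = "covariance", ids=None) -> PcaResult:
    """Functional wrapper around :class:`ShapePCA` (covariance matrix only)."""
    if matrix_type != "covariance":
        raise ValueError("only covariance-matrix PCA is supported")
    return ShapePCA().fit(X, ids=ids).result()


def _eig_proportions(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    lam = s**2
    k = min(X.shape[0] - 1, X.shape[1])
    return lam[:k] / lam.sum()


def axis_significance(X: np.ndarray, n_perm: int = 999, random_state=None) -> np.ndarray:
    """Monte Carlo test of PCA axis significance.

    The null destroys inter-variable covariance by permuting each column of X
    independently; p_k = (1 + #{permuted proportion_k >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(random_state)
    obs = _eig_proportions(X)
    exceed = np.zeros_like(obs)
    Xp = X.copy()
    for _ in range(n_perm):
        for j in range(X.shape[1]):
            Xp[:, j] = X[rng.permutation(X.shape[0]), j]
        exceed += _eig_proportions(Xp) >= obs
    return (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Procrustes ANOVA (RRPP)
# ---------------------------------------------------------------------------

def _term_columns(term: str, data: pd.DataFrame) -> np.ndarray:
    """Design columns (no intercept) for one model term."""
    parts = term.split(":")
    cols = None
    for part in parts:
        v = data[part]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, drop_first=True).to_numpy(dtype=float)
            block = dummies
        else:
            block = v.to_numpy(dtype=float)[:, None]
        cols = block if cols is None else _interact(cols, block)
    return cols


def _interact(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.concatenate([A * B[:, [j]] for j in range(B.shape[1])], axis=1)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def procrustes_anova(
    Y: np.ndarray,
    data: pd.DataFrame,
    model_terms: Sequence[str] = TERMS_DEFAULT,
    n_perm: int = 999,
    random_state=None,
) -> pd.DataFrame:
    """Sequential multivariate ANOVA with RRPP permutation inference.

    ``Y`` is the (n, p) response (Procrustes coordinates or PC scores, p = 1
    allowed); ``data`` supplies the predictor columns named in
    ``model_terms`` (``size`` is log10 centroid size).  Terms are fitted
    sequentially in the given order (Type I).  For each term, SS is the trace
    of the difference of residual cross-product matrices of nested fits;
    permutation p-values come from randomizing reduced-model residuals; Z is
    the effect size as a standard deviate of log F among the permuted
    distribution.

    Returns a tidy table with rows per term plus Residuals and Total.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if len(data) != n:
        raise ValueError("response and design have different numbers of rows")
    rng = np.random.default_rng(random_state)

    designs = [np.ones((n, 1))]
    ranks = [1]
    for term in model_terms:
        cols = _term_columns(term, data.reset_index(drop=True))
        X = np.concatenate([designs[-1], cols], axis=1)
        r = np.linalg.matrix_rank(X)
        if r == ranks[-1]:
            raise ValueError(f"rank-deficient design: term {term!r} is aliased with earlier terms")
        designs.append(X)
        ranks.append(r)
    hats = [_hat(X) for X in designs]
    df_terms = np.diff(ranks)
    df_resid = n - ranks[-1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    I = np.eye(n)

    def ss(A: np.ndarray, Ymat: np.ndarray) -> float:
        return float(np.sum((A @ Ymat) * Ymat))

    ss_total = ss(I - hats[0], Y)
    ss_terms = np.array([ss(hats[j + 1] - hats[j], Y) for j in range(len(model_terms))])
    rss = ss(I - hats[-1], Y)
    # a numerically constant response has no variation to decompose
    degenerate = ss_total <= 1e-12 * n
    if degenerate:
        ss_terms = np.zeros_like(ss_terms)
        rss, ss_total = 0.0, 1.0
    ms_terms = ss_terms / df_terms
    ms_resid = rss / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = np.where(ms_terms > 0, ms_terms / ms_resid, 0.0)

    # RRPP: permute reduced-model residuals per term
    p_vals = np.ones(len(model_terms))
    z_vals = np.zeros(len(model_terms))
    for j in range(len(model_terms) if not degenerate else 0):
        Hred, Hfull = hats[j], hats[j + 1]
        fitted = Hred @ Y
        resid = Y - fitted
        f_perm = np.empty(n_perm)
        D = Hfull - Hred
        R_full = I - hats[-1]
        for b in range(n_perm):
            Yb = fitted + resid[rng.permutation(n)]
            ssb = ss(D, Yb)
            rssb = ss(R_full, Yb)
            f_perm[b] = (ssb / df_terms[j]) / (rssb / df_resid)
        p_vals[j] = (1.0 + np.sum(f_perm >= f_obs[j])) / (n_perm + 1.0)
        log_all = np.log(np.maximum(np.append(f_perm, f_obs[j]), 1e-300))
        sd = log_all.std(ddof=1)
        z_vals[j] = (np.log(max(f_obs[j], 1e-300)) - log_all.mean()) / sd if sd > 0 else 0.0

    rows = []
    for j, term in enumerate(model_terms):
        rows.append(
            dict(term=term, Df=int(df_terms[j]), SS=ss_terms[j], MS=ms_terms[j],
                 Rsq=ss_terms[j] / ss_total, F=f_obs[j], Z=z_vals[j], P=p_vals[j])
        )
    rows.append(dict(term="Residuals", Df=int(df_resid), SS=rss, MS=ms_resid,
                     Rsq=rss / ss_total, F=np.nan, Z=np.nan, P=np.nan))
    rows.append(dict(term="Total", Df=int(n - 1), SS=ss_total, MS=np.nan,
                     Rsq=1.0, F=np.nan, Z=np.nan, P=np.nan))
    return pd.DataFrame(rows)


class ProcrustesANOVA:
    """Estimator wrapper: ``fit(Y, data)`` stores ``anova_table_``."""

    def __init__(self, model_terms: Sequence[str] = TERMS_DEFAULT, n_perm: int = 999, random_state=None):
        self.model_terms = tuple(model_terms)
        self.n_perm = n_perm
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"model_terms": self.model_terms, "n_perm": self.n_perm, "random_state": self.random_state}

    def set_params(self, **params) -> "ProcrustesANOVA":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, Y: np.ndarray, data: pd.DataFrame) -> "ProcrustesANOVA":
        self.anova_table_ = procrustes_anova(
            Y, data, model_terms=self.model_terms, n_perm=self.n_perm, random_state=self.random_state
        )
        return self


# ---------------------------------------------------------------------------
# Pairwise contrasts
# ---------------------------------------------------------------------------

@dataclass
class PairwiseResult:
    pair: tuple
    statistic: float  # Euclidean distance between group mean vectors
    p_raw: float
    p_adj: float


def pairwise_groups(
    Y: np.ndarray,
    groups: Sequence,
    adjust: str = "holm",
    n_perm: int = 999,
    random_state=None,
) -> list[PairwiseResult]:
    """Permutation tests on distances between group mean vectors.

    For Procrustes coordinates the distance between group mean vectors is the
    Procrustes distance between mean shapes.  ``adjust`` in {holm,
    bonferroni, none} corrects over all pairs.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray([str(g) for g in groups])
    rng = np.random.default_rng(random_state)
    levels, counts = np.unique(groups, return_counts=True)
    small = levels[counts < 2]
    if small.size:
        logger.warning("excluding groups with < 2 members: %s", list(small))
        keep = ~np.isin(groups, small)
        Y, groups = Y[keep], groups[keep]
        levels = levels[counts >= 2]
    if levels.size < 2:
        raise ValueError("need at least 2 groups with >= 2 members")

    def pair_dists(g: np.ndarray) -> np.ndarray:
        means = np.stack([Y[g == lv].mean(axis=0) for lv in levels])
        return np.array([
            np.linalg.norm(means[a] - means[b])
            for a, b in itertools.combinations(range(levels.size), 2)
        ])

    d_obs = pair_dists(groups)
    exceed = np.zeros_like(d_obs)
    for _ in range(n_perm):
        exceed += pair_dists(groups[rng.permutation(groups.size)]) >= d_obs
    p_raw = (1.0 + exceed) / (n_perm + 1.0)
    if adjust == "none":
        p_adj = p_raw.copy()
    else:
        p_adj = multipletests(p_raw, method=adjust)[1]
    pairs = list(itertools.combinations(levels, 2))
    return [
        PairwiseResult(pair=pairs[i], statistic=float(d_obs[i]), p_raw=float(p_raw[i]), p_adj=float(p_adj[i]))
        for i in range(len(pairs))
    ]


def pairwise_to_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dict(group_a=r.pair[0], group_b=r.pair[1], statistic=r.statistic, p_raw=r.p_raw, p_adj=r.p_adj)
         for r in results]
    )
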