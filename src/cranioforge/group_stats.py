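"""Univariate group statistics: ANCOVA, post-hoc contrasts, admixture models.

Parametric sequential (Type I) ANCOVA is used for the univariate traits
(bite-force quotient, per-suture length ratios, PC scores, centroid size);
permutation inference is reserved for the multivariate shape data in
:mod:`cranioforge.shape_stats`.  Post-hoc contrasts are t-tests on adjusted
(least-squares) group means at the covariate mean, balanced over the other
factor levels, with Holm correction by default.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .datatypes import AdmixtureClass
from .shape_stats import PairwiseResult

logger = logging.getLogger(__name__)


@dataclass
class AncovaSpec:
    """Model specification for one univariate trait."""

    response: str
    factors: Sequence[str] = ("group", "sex")
    covariates: Sequence[str] = ()
    posthoc_adjust: str = "holm"

    def __post_init__(self) -> None:
        if "group" not in self.factors:
            raise ValueError("group must be among the factors")


@dataclass
class AncovaFit:
    """Fitted ANCOVA: sequential ANOVA table, adjusted means, model handle."""

    spec: AncovaSpec
    table: pd.DataFrame
    adjusted_means: pd.Series
    model: object
    data: pd.DataFrame
    group_levels: list[str] = field(default_factory=list)


def _term_label(name: str, factors: Sequence[str]) -> str:
    return f"C({name})" if name in factors else name


def ancova(table: pd.DataFrame, spec: AncovaSpec) -> AncovaFit:
    """Sequential least-squares ANCOVA of one trait on group (+ sex, size).

    Rows with missing values in any model column are dropped; specimens with
    UNKNOWN sex are excluded whenever sex is in the model (count logged).
    Terms enter in the order: group, remaining factors, covariates.
    """
    cols = [spec.response, *spec.factors, *spec.covariates]
    df = table.loc[:, [c for c in dict.fromkeys(cols)]].copy()
    n0 = len(df)
    df = df.dropna()
    if "sex" in spec.factors:
        n_unknown = int((df["sex"] == "UNKNOWN").sum())
        if n_unknown:
            logger.info("excluding %d specimens with UNKNOWN sex from %s model", n_unknown, spec.response)
        df = df[df["sex"] != "UNKNOWN"]
    if len(df) < n0:
        logger.info("%s model uses %d of %d rows (complete cases)", spec.response, len(df), n0)

    counts = df["group"].value_counts()
    empty = [g for g in counts.index if counts[g] == 0]
    if empty:
        logger.warning("dropping empty group levels: %s", empty)
    if df["group"].nunique() < 2:
        raise ValueError("ANCOVA needs at least 2 non-empty groups")

    ordered_terms = ["group"] + [f for f in spec.factors if f != "group"] + list(spec.covariates)
    rhs = " + ".join(_term_label(t, spec.factors) for t in ordered_terms)
    model = smf.ols(f"{spec.response} ~ {rhs}", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=1)

    rows = []
    for term, label in zip(ordered_terms, (_term_label(t, spec.factors) for t in ordered_terms)):
        r = aov.loc[label]
        rows.append(dict(term=term, Df=int(r["df"]), SS=r["sum_sq"], MS=r["sum_sq"] / r["df"],
                         F=r["F"], P=r["PR(>F)"]))
    resid = aov.loc["Residual"]
    rows.append(dict(term="Residuals", Df=int(resid["df"]), SS=resid["sum_sq"],
                     MS=resid["sum_sq"] / resid["df"], F=np.nan, P=np.nan))
    out = pd.DataFrame(rows)
    ss_total = out["SS"].sum()
    if ss_total <= 1e-12 * len(df):  # numerically constant response
        out.loc[out["term"] != "Residuals", "F"] = 0.0
        out.loc[out["term"] != "Residuals", "P"] = 1.0
        out["Rsq"] = 0.0
    else:
        out["Rsq"] = out["SS"] / ss_total

    adjusted = _adjusted_means(model, df, spec)
    return AncovaFit(spec=spec, table=out, adjusted_means=adjusted, model=model, data=df,
                     group_levels=sorted(df["group"].unique()))


def _prediction_grid(df: pd.DataFrame, spec: AncovaSpec, group: str) -> pd.DataFrame:
    """Balanced grid over non-group factor levels at covariate means."""
    other = [f for f in spec.factors if f != "group"]
    levels = [sorted(df[f].unique()) for f in other]
    combos = list(itertools.product(*levels)) if other else [()]
    rows = []
    for combo in combos:
        row = {"group": group}
        row.update(dict(zip(other, combo)))
        for c in spec.covariates:
            row[c] = df[c].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def _adjusted_means(model, df: pd.DataFrame, spec: AncovaSpec) -> pd.Series:
    means = {}
    for g in sorted(df["group"].unique()):
        grid = _prediction_grid(df, spec, g)
        means[g] = float(model.predict(grid).mean())
    return pd.Series(means, name="adjusted_mean")


def posthoc_pairs(fit: AncovaFit, adjust: Optional[str] = None) -> list[PairwiseResult]:
    """All pairwise t-tests on adjusted group-mean differences.

    The contrast vector for each pair averages the design rows of the
    balanced prediction grid, so the t-statistic tests the difference of
    least-squares means with the residual df of the fitted model.
    """
    adjust = adjust or fit.spec.posthoc_adjust
    model, df, spec = fit.model, fit.data, fit.spec
    design_info = model.model.data.design_info
    from patsy import dmatrix

    cvec = {}
    for g in fit.group_levels:
        grid = _prediction_grid(df, spec, g)
        M = np.asarray(dmatrix(design_info, grid))
        cvec[g] = M.mean(axis=0)

    V = model.cov_params().to_numpy()
    beta = model.params.to_numpy()
    dof = model.df_resid
    pairs = list(itertools.combinations(fit.group_levels, 2))
    stats, p_raw = [], []
    for a, b in pairs:
        c = cvec[a] - cvec[b]
        diff = float(c @ beta)
        se = float(np.sqrt(c @ V @ c))
        t = diff / se if se > 0 else 0.0
        p = 2 * sps.t.sf(abs(t), dof) if se > 0 else 1.0
        stats.append(diff)
        p_raw.append(p)
    p_raw = np.asarray(p_raw)
    p_adj = p_raw.copy() if adjust == "none" else multipletests(p_raw, method=adjust)[1]
    return [
        PairwiseResult(pair=pairs[i], statistic=stats[i], p_raw=float(p_raw[i]), p_adj=float(p_adj[i]))
        for i in range(len(pairs))
    ]


def classify_admixture(q: float) -> AdmixtureClass:
    """Genotype class from admixture proportion Q (fraction red-squirrel ancestry).

    Thresholds are inclusive: Q >= 0.90 pure red, Q <= 0.10 pure Douglas,
    otherwise hybrid.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"admixture Q must lie in [0, 1], got {q}")
    if q >= 0.90:
        return AdmixtureClass.PURE_RED
    if q <= 0.10:
        return AdmixtureClass.PURE_DOUGLAS
    return AdmixtureClass.HYBRID


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def regress_on_admixture(trait: Sequence[float], q: Sequence[float]) -> RegressionResult:
    """Simple OLS of a trait on hybrid admixture score, parametric F-test p."""
    y = np.asarray(trait, dtype=float)
    x = np.asarray(q, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(x))
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise ValueError(f"admixture regression needs n >= 3, got {y.size}")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant admixture score: regression is singular")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), p=float(res.pvalue), n=int(y.size),
    )


def hybrid_q_summary(q_values: Sequence[float]) -> dict:
    """Mean hybrid Q with its normal-theory 95% confidence half-width."""
    q = np.asarray(q_values, dtype=float)
    q = q[~np.isnan(q)]
    n = q.size
    mean = float(q.mean())
    half = float(sps.t.ppf(0.975, n - 1) * q.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {"n": int(n), "mean_q": mean, "ci95_halfwidth": half,
            "min_q": float(q.min()), "max_q": float(q.max())}
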