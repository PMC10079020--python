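"""Bite-force estimation from incisor geometry.

Maximal bite force of a rodent incisor is proxied by the incisor strength
index ``Zi = ap^2 * ml / 6`` (the section modulus of a rectangular beam of
antero-posterior depth ``ap`` and medio-lateral width ``ml``), converted to
log10 Newtons through a published rodent calibration, and size-corrected to a
bite force quotient (BFQ): the residual of an ordinary least-squares fit of
log10 bite force on log10 body mass over the analyzed sample.  The regression
is refit per dataset; the original study's coefficients are kept only as a
reference constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import CalibrationParams, IncisorMeasurement


@dataclass
class BfqFit:
    """OLS fit metadata for the size-correction regression."""

    slope: float
    intercept: float
    r2: float
    n: int


def compute_zi(m: IncisorMeasurement) -> float:
    """Incisor strength index Zi = ap^2 * ml / 6 in mm^3."""
    if m.ap_length <= 0 or m.ml_width <= 0:
        raise ValueError(f"{m.specimen_id}: incisor dimensions must be positive")
    return m.ap_length**2 * m.ml_width / 6.0


def calibrate_bite_force(zi: float, cal: CalibrationParams | None = None) -> float:
    """log10 bite force (N) from Zi via the rodent calibration line."""
    if zi <= 0:
        raise ValueError(f"Zi must be positive, got {zi}")
    cal = cal or CalibrationParams()
    return cal.zi_slope * np.log10(zi) + cal.zi_intercept


class BiteForceQuotient:
    """Size correction of log10 bite force by regression on log10 body mass.

    scikit-learn style: ``fit`` estimates the allometric OLS line on the
    supplied sample, ``transform`` returns residuals (the BFQ).  Fitted
    attributes: ``slope_``, ``intercept_``, ``r2_``, ``n_``.
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "BiteForceQuotient":
        return self

    def fit(self, log10_force: Sequence[float], body_mass: Sequence[float]) -> "BiteForceQuotient":
        y = np.asarray(log10_force, dtype=float)
        mass = np.asarray(body_mass, dtype=float)
        if y.shape != mass.shape or y.ndim != 1:
            raise ValueError("log10_force and body_mass must be 1-D and equal length")
        if y.size < 3:
            raise ValueError(f"need >= 3 specimens with mass for the BFQ regression, got {y.size}")
        if np.any(mass <= 0):
            raise ValueError("body masses must be positive")
        x = np.log10(mass)
        if np.ptp(x) == 0:
            raise np.linalg.LinAlgError("all body masses equal: BFQ regression is singular")
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.intercept_, self.slope_ = float(beta[0]), float(beta[1])
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_ = int(y.size)
        return self

    def transform(self, log10_force: Sequence[float], body_mass: Sequence[float]) -> np.ndarray:
        y = np.asarray(log10_force, dtype=float)
        x = np.log10(np.asarray(body_mass, dtype=float))
        return y - (self.intercept_ + self.slope_ * x)

    def fit_transform(self, log10_force: Sequence[float], body_mass: Sequence[float]) -> np.ndarray:
        return self.fit(log10_force, body_mass).transform(log10_force, body_mass)

    @property
    def fit_metadata(self) -> BfqFit:
        return BfqFit(self.slope_, self.intercept_, self.r2_, self.n_)


def compute_bfq(
    log10_force: Sequence[float], body_mass: Sequence[float]
) -> tuple[np.ndarray, BfqFit]:
    """BFQ residuals in input order plus the fitted slope/intercept/R^2."""
    est = BiteForceQuotient().fit(log10_force, body_mass)
    return est.transform(log10_force, body_mass), est.fit_metadata
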