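"""Candidate-discrimination statistics for calculated vs experimental shifts.

For each candidate table the pipeline computes:

* per-position residues  RS_i = |delta_exp_i - delta_calc_i|  and their mean
  (MAE);
* the linear adjustment  delta_calc = a * delta_exp + b  removing the
  systematic bias of the level of theory, and the corrected error
  CMAE = mean |(delta_calc - b)/a - delta_exp|;
* leave-one-out cross-validation of the shift regression: PRESS, its
  dispersion s_PRESS, and the predictivity Q^2 = 1 - PRESS/TSS.

Two regression directions exist.  The adjustment (a, b, CMAE) always regresses
calculated on experimental.  The predictive statistics (R^2, s, F, PRESS,
s_PRESS, Q^2) default to the regression that predicts the *experimental* shift
from the calculated one — cross-validation then answers the operative
question, "how well does this candidate's calculation predict the measured
spectrum?" — but the other direction is available via ``response="calc"``.

The LOO statistics are computed with the exact leverage identity
e_loo_i = e_i / (1 - h_ii); tests verify it against literal per-point refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .shift_data import ShiftTable, Nucleus, ValidationError

__all__ = [
    "FitResult",
    "CrossValResult",
    "CandidateScore",
    "residuals",
    "mae",
    "linear_fit",
    "corrected_shifts",
    "cmae",
    "loo_cross_validation",
    "evaluate_candidate",
]

Response = Literal["calc", "exp"]
SPressVariant = Literal["sqrt_over_dof", "sqrt_of_ratio"]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class FitResult:
    """Ordinary least-squares line through n shift pairs.

    ``a`` is the slope and ``b`` the intercept (ppm) of the fitted line;
    ``response`` records which variable was regressed on which.  ``s`` is the
    residual standard deviation sqrt(SSE/(n-2)) and ``f_stat`` the regression
    F with (1, n-2) degrees of freedom.
    """

    a: float
    b: float
    r2: float
    s: float
    f_stat: float
    sse: float
    tss: float
    n: int
    response: Response = "calc"

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) + self.b


@dataclass(frozen=True)
class CrossValResult:
    """Leave-one-out diagnostics of a shift regression."""

    press: float
    s_press: float
    q2: float
    k: int
    loo_predictions: tuple[float, ...]
    response: Response = "exp"
    sse: float = 0.0
    tss: float = 0.0


@dataclass(frozen=True)
class CandidateScore:
    """Full statistic bundle for one candidate table (one report row)."""

    candidate: str
    nucleus: Nucleus
    method: str
    compound: str
    rs: tuple[float, ...]
    mae: float
    cmae: float
    fit: FitResult            # adjustment fit, calculated on experimental
    pred_fit: FitResult       # fit of the predictive direction (R^2, s, F)
    cv: CrossValResult

    @property
    def q2(self) -> float:
        return self.cv.q2


def _xy(table: ShiftTable, response: Response) -> tuple[np.ndarray, np.ndarray]:
    e = np.asarray(table.delta_exp, dtype=float)
    c = np.asarray(table.delta_calc, dtype=float)
    return (e, c) if response == "calc" else (c, e)


def residuals(table: ShiftTable) -> np.ndarray:
    """Per-position residues RS_i = |delta_exp_i - delta_calc_i| (ppm)."""
    e, c = np.asarray(table.delta_exp), np.asarray(table.delta_calc)
    return np.abs(e - c)


def mae(table: ShiftTable) -> float:
    """Mean absolute error of the raw calculated shifts (ppm)."""
    return float(np.mean(residuals(table)))


def linear_fit(table: ShiftTable, response: Response = "calc") -> FitResult:
    """Least-squares line through the shift pairs.

    With the default ``response="calc"`` this is the linear adjustment
    delta_calc = a * delta_exp + b.
    """
    x, y = _xy(table, response)
    n = len(x)
    if np.ptp(x) < _DEGENERATE_TOL:
        raise ValidationError("degenerate predictor: zero variance")
    res = sps.linregress(x, y)
    yhat = res.slope * x + res.intercept
    sse = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else 1.0
    msr = tss - sse
    mse = sse / (n - 2)
    f_stat = float(msr / mse) if mse > 0 else float("inf")
    return FitResult(
        a=float(res.slope), b=float(res.intercept), r2=float(r2),
        s=float(np.sqrt(mse)), f_stat=f_stat, sse=sse, tss=tss, n=n,
        response=response,
    )


def corrected_shifts(table: ShiftTable, fit: FitResult | None = None) -> np.ndarray:
    """Calculated shifts mapped back through the inverse adjustment,
    delta_corr_i = (delta_calc_i - b) / a."""
    if fit is None:
        fit = linear_fit(table, response="calc")
    if fit.response != "calc":
        raise ValueError("corrected_shifts needs the calculated-on-experimental fit")
    if abs(fit.a) < _DEGENERATE_TOL:
        raise ValidationError("zero slope: adjustment is not invertible")
    return (np.asarray(table.delta_calc, dtype=float) - fit.b) / fit.a


def cmae(table: ShiftTable, fit: FitResult | None = None) -> float:
    """Corrected mean absolute error, mean |delta_corr - delta_exp| (ppm)."""
    corr = corrected_shifts(table, fit)
    return float(np.mean(np.abs(corr - np.asarray(table.delta_exp))))


def loo_cross_validation(
    table: ShiftTable,
    k: int = 1,
    response: Response = "exp",
    s_press_variant: SPressVariant = "sqrt_over_dof",
) -> CrossValResult:
    """Leave-one-out cross-validation of the shift regression.

    Each observation is predicted by the line refitted to the other n-1
    points; PRESS is the sum of squared prediction errors and
    Q^2 = 1 - PRESS / sum((y - ybar)^2) with y the response variable.

    ``s_press_variant`` selects the dispersion convention:
    ``"sqrt_over_dof"`` (default) computes sqrt(PRESS)/(n-k-1);
    ``"sqrt_of_ratio"`` computes sqrt(PRESS/(n-k-1)).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    x, y = _xy(table, response)
    n = len(x)
    if n - k - 1 <= 0:
        raise ValidationError(f"n={n} too small for k={k}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx < _DEGENERATE_TOL:
        raise ValidationError("degenerate predictor: zero variance")
    fit = linear_fit(table, response=response)
    resid = y - fit.predict(x)
    leverage = 1.0 / n + (x - x.mean()) ** 2 / sxx
    if np.any(leverage >= 1.0 - 1e-10):
        raise ValidationError("an omitted point leaves a degenerate predictor")
    loo_resid = resid / (1.0 - leverage)
    press = float(np.sum(loo_resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss
    if s_press_variant == "sqrt_over_dof":
        s_press = float(np.sqrt(press) / (n - k - 1))
    elif s_press_variant == "sqrt_of_ratio":
        s_press = float(np.sqrt(press / (n - k - 1)))
    else:
        raise ValueError(f"unknown s_press_variant: {s_press_variant!r}")
    return CrossValResult(
        press=press, s_press=s_press, q2=float(q2), k=k,
        loo_predictions=tuple(float(v) for v in (y - loo_resid)),
        response=response, sse=fit.sse, tss=tss,
    )


def evaluate_candidate(
    table: ShiftTable,
    k: int = 1,
    response: Response = "exp",
    s_press_variant: SPressVariant = "sqrt_over_dof",
) -> CandidateScore:
    """Bundle residues, MAE/CMAE, the adjustment fit and LOO diagnostics.

    ``response`` controls only the predictive statistics (R^2, s, F, PRESS,
    s_PRESS, Q^2); the adjustment parameters a, b and CMAE always come from
    the calculated-on-experimental fit.
    """
    adj = linear_fit(table, response="calc")
    pred = adj if response == "calc" else linear_fit(table, response=response)
    cv = loo_cross_validation(table, k=k, response=response,
                              s_press_variant=s_press_variant)
    return CandidateScore(
        candidate=table.candidate, nucleus=table.nucleus, method=table.method,
        compound=table.compound,
        rs=tuple(float(v) for v in residuals(table)),
        mae=mae(table), cmae=cmae(table, adj),
        fit=adj, pred_fit=pred, cv=cv,
    )
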