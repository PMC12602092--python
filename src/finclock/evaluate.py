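"""Clock scoring: agreement metrics and the relative-error-versus-age trend."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ClockEvaluation:
    r2: float
    mae_years: float
    mdae_years: float
    r2_identity: float  # 1 - SS_res/SS_tot about the 1:1 line


def evaluate_predictions(pred, true, r2_definition: str = "pearson") -> tuple[float, float, float]:
    """(r2, MAE, MDAE) between predicted and otolith-derived ages.

    ``r2`` is the squared Pearson correlation of predicted versus true age
    (the regression-agreement reading); pass ``r2_definition="identity"`` for
    1 - SS_res/SS_tot about the 1:1 line. Returns NaN for r2 when either
    vector has zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("pred and true must be equal-length vectors of size >= 2")
    err = np.abs(pred - true)
    mae = float(err.mean())
    mdae = float(np.median(err))
    if pred.std() == 0 or true.std() == 0:
        return float("nan"), mae, mdae
    if r2_definition == "pearson":
        r2 = float(np.corrcoef(pred, true)[0, 1] ** 2)
    elif r2_definition == "identity":
        ss_res = float(((pred - true) ** 2).sum())
        ss_tot = float(((true - true.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
    else:
        raise ValueError(f"unknown r2_definition {r2_definition!r}")
    return r2, mae, mdae


def evaluate(pred, true) -> ClockEvaluation:
    r2, mae, mdae = evaluate_predictions(pred, true, "pearson")
    r2_id, _, _ = evaluate_predictions(pred, true, "identity")
    return ClockEvaluation(r2=r2, mae_years=mae, mdae_years=mdae, r2_identity=r2_id)


def relative_error_trend(pred, true) -> tuple[float, float, float]:
    """OLS of relative error (|pred - true| / true) on true age.

    Returns (slope per year, two-sided slope p-value, regression r2). A
    negative slope means the clock gets relatively more accurate with age.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least 3 fish")
    if np.any(true <= 0):
        raise ValueError("true ages must be positive")
    rel = np.abs(pred - true) / true
    fit = stats.linregress(true, rel)
    return float(fit.slope), float(fit.pvalue), float(fit.rvalue**2)
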