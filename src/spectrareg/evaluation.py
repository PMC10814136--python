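"""Model performance metrics: RMSE, R², RPD, and the comparison table.

Conventions: R² is the coefficient-of-determination form
``1 - Σ(ŷ-y)² / Σ(ȳ-y)²`` (not squared Pearson r); RPD divides the
sample standard deviation of the reference values (n-1 denominator) by
the prediction RMSE.  RPD below 1.4 marks an unreliable model, 1.4-2.0 a
reliable one, and above 2.0 high reliability.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "rmse",
    "r_squared",
    "rpd",
    "reliability_class",
    "evaluate_split",
    "evaluate_all",
]


def _pair(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0 or y.size != y_hat.size:
        raise ParameterError("y and y_hat must be non-empty and of equal length")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root mean square error."""
    y, y_hat = _pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y, y_hat = _pair(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ParameterError("R² undefined for a constant reference vector")
    return 1.0 - float(np.sum((y_hat - y) ** 2)) / ss_tot


def rpd(y, y_hat) -> float:
    """Residual prediction deviation: SD(y) / RMSE(y, y_hat), SD with n-1."""
    y, y_hat = _pair(y, y_hat)
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise ParameterError("RPD undefined for a constant reference vector")
    err = rmse(y, y_hat)
    if err == 0:
        warnings.warn("zero RMSE; RPD reported as +inf", stacklevel=2)
        return float("inf")
    return sd / err


def reliability_class(value: float) -> str:
    """Map an RPD value to {unreliable, reliable, high}.

    Boundary values 1.4 and 2.0 are assigned to the middle class.
    """
    if value <= 0:
        raise ParameterError("RPD must be positive")
    if value < 1.4:
        return "unreliable"
    if value <= 2.0:
        return "reliable"
    return "high"


def evaluate_split(trained, x, y, split) -> dict:
    """Metrics for one model/target on the three split parts.

    Returns a dict with R²/RMSE on calibration, validation and
    prediction, plus the prediction-set RPD and its reliability class.
    """
    out = {}
    for part, idx in (("C", split.cal_idx), ("V", split.val_idx), ("P", split.pred_idx)):
        pred = trained.predict(x[idx])
        out[f"R2_{part}"] = r_squared(y[idx], pred)
        out[f"RMSE{part}"] = rmse(y[idx], pred)
    pred_p = trained.predict(x[split.pred_idx])
    out["RPDP"] = rpd(y[split.pred_idx], pred_p)
    out["reliability"] = reliability_class(out["RPDP"])
    return out


def evaluate_all(models: dict, x, targets, split):
    """Build the model-comparison table.

    ``models`` maps ``(model_name, target_name)`` to a trained model;
    ``targets`` is a :class:`spectrareg.pipeline.TargetTable`.  Returns
    ``(report DataFrame, scatter DataFrame)``; the scatter frame carries
    (measured, predicted, part) pairs for every model/target for
    measured-vs-predicted diagnostics.
    """
    rows = []
    scatter_rows = []
    for (name, target), trained in models.items():
        y = targets.column(target)
        metrics = evaluate_split(trained, x, y, split)
        rows.append({"target": target, "model": name, **metrics})
        for part, idx in (("cal", split.cal_idx), ("val", split.val_idx),
                          ("pred", split.pred_idx)):
            pred = trained.predict(x[idx])
            for yi, pi in zip(y[idx], pred):
                scatter_rows.append({"target": target, "model": name, "part": part,
                                     "measured": yi, "predicted": pi})
    report = pd.DataFrame(rows)
    scatter = pd.DataFrame(scatter_rows)
    return report, scatter
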