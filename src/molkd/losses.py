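"""Regression losses, the cosine distillation loss, uncertainty weighting,
and the R²/RMSE/deviation metrics.

The distillation loss is L_KD = 1 − mean_i cos(e_T,i, e_S,i) over matched
teacher/student embedding rows. Student training combines it with a
regression term through homoscedastic uncertainty weighting,

    L_total = L_reg / (2σ₁²) + L_KD / (2σ₂²) + log σ₁ + log σ₂,

whose learnable σ's settle at the stationary point σ_i = √L_i. The headline
benefit metric is the relative R² deviation,
(1 − R²_without-KD / R²_with-KD) × 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UncertaintyWeights",
    "LossValue",
    "regression_loss",
    "kd_cosine_loss",
    "uncertainty_total_loss",
    "uncertainty_gradients",
    "fit_uncertainty_weights",
    "r_squared",
    "relative_r2_deviation",
    "rmse",
    "rmse_improvement",
]


@dataclass
class UncertaintyWeights:
    """Learnable log σ₁ (regression task) and log σ₂ (distillation task).

    Parametrizing by log σ keeps both σ's positive without constraints;
    initialization at 0 means σ = 1 (equal task weights).
    """

    log_sigma1: float = 0.0
    log_sigma2: float = 0.0

    @property
    def sigma1(self) -> float:
        return math.exp(self.log_sigma1)

    @property
    def sigma2(self) -> float:
        return math.exp(self.log_sigma2)


@dataclass(frozen=True)
class LossValue:
    total: float
    components: dict

    def __post_init__(self):
        recombined = sum(self.components.values())
        if abs(recombined - self.total) > 1e-10 * max(1.0, abs(self.total)):
            raise ValueError("components do not recombine to the total")


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=np.float64).ravel()
    yp = np.asarray(y_pred, dtype=np.float64).ravel()
    if yt.shape != yp.shape or yt.size < 1:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    if not (np.all(np.isfinite(yt)) and np.all(np.isfinite(yp))):
        raise ValueError("non-finite input")
    return yt, yp


def regression_loss(
    y_true, y_pred, kind: str = "mae", delta: float = 1.0
) -> float:
    """MAE / MSE / Huber / Smooth-L1 over a prediction vector.

    Huber: ½r² below δ, δ(|r| − δ/2) above. Smooth-L1 is Huber scaled by
    1/δ: r²/(2δ) below δ, |r| − δ/2 above.
    """
    yt, yp = _check_pair(y_true, y_pred)
    r = yt - yp
    if kind == "mae":
        return float(np.mean(np.abs(r)))
    if kind == "mse":
        return float(np.mean(r**2))
    a = np.abs(r)
    if kind == "huber":
        per = np.where(a <= delta, 0.5 * r**2, delta * (a - 0.5 * delta))
        return float(per.mean())
    if kind == "smooth_l1":
        per = np.where(a <= delta, 0.5 * r**2 / delta, a - 0.5 * delta)
        return float(per.mean())
    raise ValueError(f"unknown loss kind {kind!r}")


def _rows(e) -> tuple[np.ndarray, list[str] | None]:
    if hasattr(e, "values"):
        return np.atleast_2d(e.values), list(e.molecule_ids)
    return np.atleast_2d(np.asarray(e, dtype=np.float64)), None


def kd_cosine_loss(e_teacher, e_student) -> float:
    """Distillation loss 1 − mean rowwise cosine; range [0, 2]."""
    return float(1.0 - np.mean(_rowwise_cosine(e_teacher, e_student)))


def _rowwise_cosine(e_teacher, e_student) -> np.ndarray:
    et, ids_t = _rows(e_teacher)
    es, ids_s = _rows(e_student)
    if et.shape != es.shape:
        raise ValueError(
            f"embedding shapes differ: {et.shape} vs {es.shape}"
        )
    nt = np.linalg.norm(et, axis=1)
    ns = np.linalg.norm(es, axis=1)
    for norms, ids, who in ((nt, ids_t, "teacher"), (ns, ids_s, "student")):
        if np.any(norms == 0):
            bad = int(np.argmax(norms == 0))
            label = ids[bad] if ids else str(bad)
            raise ValueError(f"zero-norm {who} embedding row for molecule {label}")
    return np.einsum("ij,ij->i", et, es) / (nt * ns)


def uncertainty_total_loss(
    l_reg: float, l_kd: float, weights: UncertaintyWeights
) -> LossValue:
    """Homoscedastic uncertainty-weighted combination of the two tasks."""
    if not (np.isfinite(l_reg) and np.isfinite(l_kd)) or l_reg < 0 or l_kd < 0:
        raise ValueError("loss terms must be finite and nonnegative")
    s1, s2 = weights.sigma1, weights.sigma2
    comp = {
        "regression": l_reg / (2.0 * s1**2),
        "distillation": l_kd / (2.0 * s2**2),
        "regularizer": weights.log_sigma1 + weights.log_sigma2,
    }
    return LossValue(total=sum(comp.values()), components=comp)


def uncertainty_gradients(
    l_reg: float, l_kd: float, weights: UncertaintyWeights
) -> tuple[float, float]:
    """∂L_total/∂log σ_i = 1 − l_i/σ_i²; zero exactly at σ_i = √l_i."""
    return (
        1.0 - l_reg / weights.sigma1**2,
        1.0 - l_kd / weights.sigma2**2,
    )


def fit_uncertainty_weights(
    l_reg: float,
    l_kd: float,
    weights: UncertaintyWeights | None = None,
    lr: float = 0.05,
    steps: int = 5000,
) -> UncertaintyWeights:
    """Gradient descent on (log σ₁, log σ₂) for fixed loss values.

    Converges to the analytic stationary point σ_i = √l_i.
    """
    w = weights or UncertaintyWeights()
    for _ in range(steps):
        g1, g2 = uncertainty_gradients(l_reg, l_kd, w)
        w.log_sigma1 -= lr * g1
        w.log_sigma2 -= lr * g2
    return w


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot; ≤ 1, unbounded below."""
    yt, yp = _check_pair(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("r_squared requires at least 2 samples")
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true is constant; R² undefined")
    return 1.0 - float(np.sum((yt - yp) ** 2)) / ss_tot


def relative_r2_deviation(r2_with_kd: float, r2_without_kd: float) -> float:
    """KD-benefit metric (1 − R²_woKD / R²_wKD) × 100, in percent.

    Returns NaN (the undefined flag) when R²_wKD ≤ 0, where the ratio loses
    meaning; reports exclude such rows from summaries.
    """
    if not np.isfinite(r2_with_kd) or r2_with_kd <= 0.0:
        return math.nan
    return (1.0 - r2_without_kd / r2_with_kd) * 100.0


def rmse(y_true, y_pred) -> float:
    yt, yp = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((yt - yp) ** 2)))


def rmse_improvement(rmse_kd: float, rmse_nokd: float) -> float:
    """(1 − RMSE_KD / RMSE_noKD) × 100; NaN when the baseline RMSE is ≤ 0."""
    if not np.isfinite(rmse_nokd) or rmse_nokd <= 0.0:
        return math.nan
    return (1.0 - rmse_kd / rmse_nokd) * 100.0
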