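"""Prediction of kinetic constants and hydrolysis curves at new conditions.

A fitted response surface for the initial rate ``a`` yields, at a coded
condition x0, a point prediction with the confidence interval

    yhat(x0) +/- t_{alpha/2, df} * sqrt(sigma2 * x0'(X'X)^-1 x0).

A full hydrolysis-curve prediction then evaluates the logarithmic model with
the predicted ``a`` and a fixed representative ``b``.  Because the model is
monotone increasing in ``a`` at every t > 0, the curve band obtained by
pushing the interval endpoints of ``a`` through the model is exact: only the
uncertainty in ``a`` is propagated, ``b`` is treated as a known constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputDataError
from .kinetics import log_model
from .titration import AssayConfig, alpha_nh_to_dh

__all__ = [
    "PredictionResult",
    "PredictedCurve",
    "predict_a",
    "predict_curve",
    "percent_error",
    "validation_correlation",
]


@dataclass(frozen=True)
class PredictionResult:
    """Predicted response at one coded condition, with its confidence interval."""

    x0: tuple
    value: float
    se: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95
    df: int | None = None

    def __post_init__(self):
        if self.se < 0:
            raise InputDataError("standard error must be >= 0")
        if not (self.ci_low <= self.value <= self.ci_high):
            raise InputDataError("interval must bracket the point prediction")

    def __str__(self) -> str:
        return (
            f"{self.value:.4g} +/- {self.se:.3g} "
            f"[{self.ci_low:.4g}, {self.ci_high:.4g}] at {int(self.confidence * 100)}%"
        )


@dataclass(frozen=True)
class PredictedCurve:
    """Predicted hydrolysis curve with pointwise band, in mM and DH percent."""

    times: np.ndarray
    p_mid: np.ndarray
    p_low: np.ndarray
    p_high: np.ndarray
    dh_mid: np.ndarray
    dh_low: np.ndarray
    dh_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "p_mid_mM": self.p_mid,
                "p_low_mM": self.p_low,
                "p_high_mM": self.p_high,
                "dh_mid_percent": self.dh_mid,
                "dh_low_percent": self.dh_low,
                "dh_high_percent": self.dh_high,
            }
        )

    def dh_at(self, t: float) -> float:
        """Mid-band DH (%) at time t (must be one of the evaluated times)."""
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise InputDataError(f"time {t} not on the evaluated grid")
        return float(self.dh_mid[idx[0]])


def predict_a(results, x0, confidence: float = 0.95, convention: str = "standard") -> PredictionResult:
    """Predict the kinetic constant ``a`` at a coded condition.

    Thin functional front end to
    :meth:`hydrokin.design.ResponseSurfaceResults.predict`.
    """
    return results.predict(x0, confidence=confidence, convention=convention)


def predict_curve(
    a_result: PredictionResult,
    b_fixed: float,
    times,
    config: AssayConfig | None = None,
) -> PredictedCurve:
    """Assemble a predicted hydrolysis curve with its confidence band.

    The mid curve uses the predicted ``a``; the band edges re-evaluate the
    model at the interval endpoints of ``a`` (exact for a monotone map).  A
    negative lower endpoint is clamped to zero with a warning.  DH series use
    the assay constants in ``config`` (package defaults when omitted).
    """
    if b_fixed <= 0:
        raise InputDataError("b_fixed must be > 0")
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0:
        raise InputDataError("the time grid must start at 0")
    config = config or AssayConfig()

    a_low = a_result.ci_low
    if a_low < 0:
        warnings.warn(
            f"lower confidence limit of a is negative ({a_low:.3g} mM/min); clamped to 0",
            UserWarning,
            stacklevel=2,
        )
        a_low = 0.0
    p_mid = log_model(a_result.value, b_fixed, times)
    p_low = log_model(a_low, b_fixed, times)
    p_high = log_model(a_result.ci_high, b_fixed, times)
    return PredictedCurve(
        times=times,
        p_mid=p_mid,
        p_low=p_low,
        p_high=p_high,
        dh_mid=alpha_nh_to_dh(p_mid, config, percent=True),
        dh_low=alpha_nh_to_dh(p_low, config, percent=True),
        dh_high=alpha_nh_to_dh(p_high, config, percent=True),
    )


def percent_error(predicted: float, experimental: float) -> float:
    """Relative error 100*|predicted - experimental|/experimental, percent."""
    if experimental == 0:
        raise InputDataError("percent error undefined for a zero experimental value")
    return 100.0 * abs(predicted - experimental) / abs(experimental)


def validation_correlation(predicted, experimental) -> float:
    """Squared Pearson correlation between predicted and experimental vectors.

    Note R^2 defined this way is sign-blind: a perfectly anti-correlated
    pair also scores 1.0.  It measures linear association, not agreement.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    experimental = np.asarray(experimental, dtype=float).ravel()
    if predicted.size != experimental.size:
        raise InputDataError("vectors must have equal length")
    if predicted.size < 2:
        raise InputDataError("need at least two points")
    if np.std(predicted) == 0 or np.std(experimental) == 0:
        raise InputDataError("correlation undefined for a zero-variance vector")
    r = np.corrcoef(predicted, experimental)[0, 1]
    return float(r * r)
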