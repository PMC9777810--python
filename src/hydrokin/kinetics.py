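"""First modeling level: the logarithmic hydrolysis-kinetics model.

A protease hydrolysis curve is described by the two-constant logarithmic
model

    P(t) = (1/b) * ln(a*b*t + 1),

the closed form of the rate law dP/dt = a * exp(-b*P) with P(0) = 0.  The
constant ``a`` (mM/min) is the initial hydrolysis rate — the slope dP/dt at
t = 0 — and ``b`` (1/mM) is the extension constant governing how fast the
rate attenuates as product accumulates.  The constants are estimated by
nonlinear least squares; standard errors come from the linearized dispersion
matrix at the optimum, se_j = sqrt(sigma2 * C_jj) with C = (J'J)^-1 and
sigma2 = SSE/(n-2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import BoundaryWarning, DegenerateDataError, FitError, InputDataError
from .titration import HydrolysisCurve

__all__ = ["log_model", "LogKineticModel", "KineticFit", "fit_log_model", "initial_rate"]

_B_LOWER = 1e-12  # lower bound for both constants in the bounded NLS


def log_model(a, b, t):
    """Evaluate P = (1/b)*ln(a*b*t + 1).

    ``log1p`` keeps the evaluation accurate in the near-linear regime
    a*b*t << 1, where P -> a*t.  ``b`` must be strictly positive; use the
    linear limit a*t explicitly if an unattenuated model is wanted.
    """
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(a < 0):
        raise InputDataError("initial rate a must be >= 0")
    if not np.all(np.asarray(b) > 0):
        raise InputDataError("extension constant b must be > 0 (use P = a*t for b = 0)")
    if np.any(t < 0):
        raise InputDataError("time must be >= 0")
    out = np.log1p(a * b * t) / b
    return float(out) if out.ndim == 0 else out


def _model_jacobian(a: float, b: float, t: np.ndarray) -> np.ndarray:
    """Jacobian of log_model predictions with respect to (a, b)."""
    abt1 = a * b * t + 1.0
    p = np.log1p(a * b * t) / b
    d_a = t / abt1
    d_b = (-p + a * t / abt1) / b
    return np.column_stack([d_a, d_b])


@dataclass
class KineticFit:
    """Results of fitting the logarithmic model to one hydrolysis curve.

    Attributes
    ----------
    a, b : float
        Initial rate (mM/min) and extension constant (1/mM).
    se_a, se_b : float
        Linearized standard errors, se_j = sqrt(sigma2 * C_jj).
    r_squared : float
        Coefficient of determination about the mean of the observations.
    n_points : int
        Number of fitted points.
    residual_variance : float
        sigma2 = SSE/(n-2), mM^2.
    cov : np.ndarray
        2x2 covariance matrix sigma2 * (J'J)^-1 of (a, b).
    b_on_bound : bool
        True when b ended on its lower bound and the fit degenerated to the
        linear limit P = a*t.
    """

    a: float
    b: float
    se_a: float
    se_b: float
    r_squared: float
    n_points: int
    residual_variance: float
    cov: np.ndarray = field(repr=False, default=None)
    b_on_bound: bool = False

    @property
    def initial_rate(self) -> float:
        """dP/dt at t = 0, which is exactly the constant a."""
        return self.a

    def predict(self, t):
        """Model curve at the fitted constants."""
        if self.b_on_bound:
            t = np.asarray(t, dtype=float)
            return self.a * t
        return log_model(self.a, self.b, t)

    def summary(self) -> str:
        lines = [
            "Logarithmic kinetic model  P = (1/b) ln(a b t + 1)",
            f"  n points          : {self.n_points}",
            f"  a  (mM/min)       : {self.a:.4g} +/- {self.se_a:.3g}",
            f"  b  (1/mM)         : {self.b:.4g} +/- {self.se_b:.3g}",
            f"  R^2               : {self.r_squared:.5f}",
            f"  residual variance : {self.residual_variance:.4g} mM^2",
        ]
        if self.b_on_bound:
            lines.append("  note: b hit its lower bound; linear-limit fit P = a t reported")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "residual_variance": self.residual_variance,
        }


class LogKineticModel:
    """Nonlinear least-squares model for one hydrolysis curve.

    Parameters
    ----------
    curve : HydrolysisCurve
        Product concentration against time; at least 4 points, at least one
        of them positive.

    Examples
    --------
    >>> t = np.linspace(0, 60, 61)
    >>> curve = HydrolysisCurve(t, log_model(9.46, 0.0359, t))
    >>> fit = LogKineticModel(curve).fit()
    >>> round(fit.a, 2), round(fit.b, 4)
    (9.46, 0.0359)
    """

    def __init__(self, curve: HydrolysisCurve):
        if not isinstance(curve, HydrolysisCurve):
            curve = HydrolysisCurve(np.asarray(curve[0], float), np.asarray(curve[1], float))
        if len(curve) < 4:
            raise InputDataError(f"need >= 4 points to fit, got {len(curve)}")
        if not np.any(curve.product > 0):
            raise DegenerateDataError("all product values are zero; nothing to fit")
        self.curve = curve

    # -- starting values -------------------------------------------------
    def _initial_guess(self) -> tuple[float, float]:
        """a0 from the slope over the first 10% of points; b0 = 1/max(P).

        a is the initial slope of the curve and 1/b sets its saturation
        scale, so these are natural, scale-free starting points.
        """
        t, p = self.curve.times, self.curve.product
        m = max(2, int(np.ceil(0.1 * t.size)))
        tt, pp = t[:m], p[:m]
        denom = np.sum((tt - tt.mean()) ** 2)
        if denom > 0:
            a0 = float(np.sum((tt - tt.mean()) * (pp - pp.mean())) / denom)
        else:  # pragma: no cover - guarded by strictly increasing times
            a0 = 0.0
        if not np.isfinite(a0) or a0 <= 0:
            # fall back to the secant slope over the whole record
            a0 = float(p[-1] / t[-1]) if t[-1] > 0 else 1.0
        a0 = max(a0, _B_LOWER)
        b0 = 1.0 / float(np.max(p))
        return a0, b0

    def fit(self, ftol: float = 1e-10) -> KineticFit:
        """Fit (a, b) by bounded nonlinear least squares with multi-start.

        Both constants are bounded below at 1e-12.  On solver failure the
        fit restarts from three log-spaced b0 values; total failure raises
        :class:`FitError` carrying the solver diagnostics.
        """
        t, p = self.curve.times, self.curve.product
        a0, b0 = self._initial_guess()

        def residuals(theta):
            a, b = theta
            return np.log1p(a * b * t) / b - p

        def jac(theta):
            return _model_jacobian(theta[0], theta[1], t)

        attempts, best = [], None
        for b_start in (b0, b0 / 10.0, b0 * 10.0):
            try:
                sol = least_squares(
                    residuals,
                    x0=[a0, b_start],
                    jac=jac,
                    bounds=([_B_LOWER, _B_LOWER], [np.inf, np.inf]),
                    ftol=ftol,
                    xtol=1e-12,
                    gtol=1e-12,
                )
            except Exception as exc:  # numerical blow-up in an attempt
                attempts.append({"b0": b_start, "error": str(exc)})
                continue
            attempts.append({"b0": b_start, "status": sol.status, "cost": float(sol.cost)})
            if sol.status > 0 and (best is None or sol.cost < best.cost):
                best = sol
            if best is not None and sol is best and sol.status > 0:
                break  # first start converged; no need for restarts
        if best is None:
            raise FitError("nonlinear least squares did not converge", {"attempts": attempts})

        a_hat, b_hat = float(best.x[0]), float(best.x[1])
        resid = residuals(best.x)
        sse = float(np.dot(resid, resid))
        n = t.size
        sigma2 = sse / (n - 2)
        sst = float(np.sum((p - p.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 1.0

        b_on_bound = b_hat <= _B_LOWER * (1 + 1e-6)
        if b_on_bound:
            warnings.warn(
                "b reached its lower bound; reporting the linear-limit fit P = a t",
                BoundaryWarning,
                stacklevel=2,
            )
            # OLS slope through the origin, its exact standard error
            stt = float(np.dot(t, t))
            a_hat = float(np.dot(t, p) / stt)
            resid = a_hat * t - p
            sse = float(np.dot(resid, resid))
            sigma2 = sse / (n - 1)
            r2 = 1.0 - sse / sst if sst > 0 else 1.0
            cov = np.array([[sigma2 / stt, 0.0], [0.0, np.inf]])
            se_a, se_b = float(np.sqrt(sigma2 / stt)), np.inf
        else:
            jtj = _model_jacobian(a_hat, b_hat, t)
            jtj = jtj.T @ jtj
            try:
                c = np.linalg.inv(jtj)
            except np.linalg.LinAlgError as exc:
                raise FitError("singular dispersion matrix at the optimum", {"attempts": attempts}) from exc
            cov = sigma2 * c
            se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

        return KineticFit(
            a=a_hat,
            b=b_hat,
            se_a=se_a,
            se_b=se_b,
            r_squared=r2,
            n_points=n,
            residual_variance=sigma2,
            cov=cov,
            b_on_bound=b_on_bound,
        )


def fit_log_model(curve: HydrolysisCurve) -> KineticFit:
    """Convenience wrapper: ``LogKineticModel(curve).fit()``."""
    return LogKineticModel(curve).fit()


def initial_rate(fit: KineticFit) -> float:
    """Initial hydrolysis rate dP/dt at t = 0 for a fitted model (equals a)."""
    return fit.initial_rate
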