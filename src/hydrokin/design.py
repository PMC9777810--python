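"""Second modeling level: central composite design and response-surface regression.

The operating conditions — temperature T (x1) and protease dose E (x2) — are
coded as x = (natural - center)/step and laid out on a central composite
circumscribed (CCC) design: the four factorial corners (+/-1, +/-1), four
axial points at +/-sqrt(2) on each axis, and replicated center points.  Each
kinetic constant is then regressed on the full quadratic polynomial

    y = b0 + b1*x1 + b2*x2 + b11*x1^2 + b22*x2^2 + b12*x1*x2

by ordinary least squares, non-significant terms are removed by backward
elimination on their t-test p-values, and the regression is summarized with
an ANOVA block.  Coefficient inference uses the standard residual degrees of
freedom n - k (k = number of terms including the intercept); for the ANOVA
block an alternative ``"paper"`` convention with df_reg = k and
df_err = n - k - 1 is available, as printed in some food-engineering RSM
reports.

OLS fitting and coefficient inference are delegated to
:mod:`statsmodels`; the design construction, term bookkeeping, reduction
and ANOVA conventions are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ExtrapolationWarning, InputDataError
from .prediction import PredictionResult

__all__ = [
    "SQRT2",
    "TERMS",
    "VariableCoding",
    "CCCDesign",
    "build_ccc",
    "design_matrix",
    "ResponseSurface",
    "ResponseSurfaceResults",
    "fit_polynomial",
    "reduce_model",
    "anova",
    "fixed_b",
]

SQRT2 = math.sqrt(2.0)

#: Canonical term order of the full quadratic model in two coded factors.
TERMS = ("1", "x1", "x2", "x1^2", "x2^2", "x1*x2")

_TERM_FUNCS = {
    "1": lambda x: np.ones(x.shape[0]),
    "x1": lambda x: x[:, 0],
    "x2": lambda x: x[:, 1],
    "x1^2": lambda x: x[:, 0] ** 2,
    "x2^2": lambda x: x[:, 1] ** 2,
    "x1*x2": lambda x: x[:, 0] * x[:, 1],
}


def _check_terms(terms: Sequence[str]) -> tuple[str, ...]:
    terms = tuple(terms)
    unknown = [t for t in terms if t not in _TERM_FUNCS]
    if unknown:
        raise InputDataError(f"unknown polynomial terms: {unknown}; valid terms are {TERMS}")
    if "1" not in terms:
        raise InputDataError("the term set must include the intercept '1'")
    if len(set(terms)) != len(terms):
        raise InputDataError("duplicate terms in term set")
    return terms


def design_matrix(x: np.ndarray, terms: Sequence[str] = TERMS) -> np.ndarray:
    """Expand coded points (n, 2) into the model matrix for ``terms``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != 2:
        raise InputDataError(f"coded points must have two columns (x1, x2), got {x.shape[1]}")
    terms = _check_terms(terms)
    return np.column_stack([_TERM_FUNCS[t](x) for t in terms])


@dataclass(frozen=True)
class VariableCoding:
    """Coded <-> natural transform for one operating variable.

    ``natural = center + coded * step``; the axial distance records how far
    the star points of the design sit in coded units.
    """

    name: str
    center: float
    step: float
    axial: float = SQRT2

    def __post_init__(self):
        if self.step <= 0:
            raise InputDataError("coding step must be > 0")
        if self.axial < 1:
            raise InputDataError("axial distance must be >= 1")

    def decode(self, coded):
        """Coded units to natural units."""
        return self.center + np.asarray(coded, dtype=float) * self.step

    def encode(self, natural):
        """Natural units to coded units (exact inverse of :meth:`decode`)."""
        return (np.asarray(natural, dtype=float) - self.center) / self.step

    def levels(self) -> np.ndarray:
        """Natural values at the five canonical coded levels."""
        return self.decode([-self.axial, -1.0, 0.0, 1.0, self.axial])


@dataclass(frozen=True)
class CCCDesign:
    """Coded two-factor central composite circumscribed design."""

    coded: np.ndarray
    n_center: int
    axial: float = SQRT2

    def __post_init__(self):
        coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        object.__setattr__(self, "coded", coded)
        if coded.shape != (8 + self.n_center, 2):
            raise InputDataError(
                f"a two-factor CCC with {self.n_center} center points has "
                f"{8 + self.n_center} rows, got {coded.shape}"
            )

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coded, columns=["x1", "x2"])


def build_ccc(n_center: int = 2, axial: float = SQRT2) -> CCCDesign:
    """Build the coded two-factor CCC: factorial corners, axial points, centers.

    With ``axial=sqrt(2)`` the axial points fall on the circle through the
    factorial corners (circumscribed design).  Row order: the four corners,
    the four axial points, then the center replicates.
    """
    if n_center < 1:
        raise InputDataError("need at least one center point")
    rows = [
        (-1.0, -1.0),
        (-1.0, 1.0),
        (1.0, -1.0),
        (1.0, 1.0),
        (-axial, 0.0),
        (axial, 0.0),
        (0.0, -axial),
        (0.0, axial),
    ]
    rows += [(0.0, 0.0)] * n_center
    return CCCDesign(coded=np.array(rows), n_center=n_center, axial=axial)


def _coerce_points(design) -> tuple[np.ndarray, float]:
    """Accept a CCCDesign or a bare (n, 2) array of coded points."""
    if isinstance(design, CCCDesign):
        return design.coded, design.axial
    x = np.atleast_2d(np.asarray(design, dtype=float))
    return x, SQRT2


class ResponseSurface:
    """OLS polynomial model of a response over coded design points.

    Parameters
    ----------
    design : CCCDesign or array-like of shape (n, 2)
        Coded (x1, x2) points.
    response : array-like of length n
        Observed response (a kinetic constant per design run).
    terms : sequence of str
        Subset of :data:`TERMS`; must include the intercept.
    """

    def __init__(self, design, response, terms: Sequence[str] = TERMS):
        self.points, self.axial = _coerce_points(design)
        self.response = np.asarray(response, dtype=float).ravel()
        if self.response.size != self.points.shape[0]:
            raise InputDataError(
                f"{self.response.size} responses for {self.points.shape[0]} design rows"
            )
        self.terms = _check_terms(terms)
        self.exog = design_matrix(self.points, self.terms)
        rank = np.linalg.matrix_rank(self.exog)
        if rank < len(self.terms):
            collinear = self._collinear_terms()
            raise InputDataError(
                f"singular model matrix; collinear terms on this design: {collinear}"
            )

    def _collinear_terms(self) -> list[str]:
        """Greedy scan naming the terms whose columns add no rank."""
        kept, collinear = [], []
        for term in self.terms:
            trial = kept + [term]
            mat = np.column_stack([_TERM_FUNCS[t](self.points) for t in trial])
            if np.linalg.matrix_rank(mat) == len(trial):
                kept.append(term)
            else:
                collinear.append(term)
        return collinear

    def fit(self) -> "ResponseSurfaceResults":
        ols = sm.OLS(self.response, self.exog).fit()
        return ResponseSurfaceResults(model=self, _ols=ols)


@dataclass
class ResponseSurfaceResults:
    """Fitted polynomial surface with coefficient inference.

    Coefficient standard errors, t-values and two-sided p-values use
    df = n - k (k terms including the intercept).
    """

    model: ResponseSurface
    _ols: object = field(repr=False)

    # -- basic accessors -------------------------------------------------
    @property
    def terms(self) -> tuple[str, ...]:
        return self.model.terms

    @property
    def nobs(self) -> int:
        return int(self._ols.nobs)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._ols.params, index=list(self.terms))

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._ols.bse, index=list(self.terms))

    @property
    def tvalues(self) -> pd.Series:
        return pd.Series(self._ols.tvalues, index=list(self.terms))

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self._ols.pvalues, index=list(self.terms))

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._ols.rsquared_adj)

    @property
    def scale(self) -> float:
        """Residual variance SSE/(n - k)."""
        return float(self._ols.scale)

    @property
    def ssr(self) -> float:
        """Residual (error) sum of squares."""
        return float(self._ols.ssr)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._ols.fittedvalues)

    @property
    def dispersion(self) -> np.ndarray:
        """(X'X)^-1 over the retained terms."""
        x = self.model.exog
        return np.linalg.inv(x.T @ x)

    # -- model reduction -------------------------------------------------
    def reduce(self, alpha: float = 0.05, method: str = "backward") -> "ResponseSurfaceResults":
        """Eliminate non-significant terms by t-test p-value.

        ``method="backward"`` (default) repeatedly drops the non-intercept
        term with the largest p-value above ``alpha`` and refits, until
        every remaining non-intercept term has p <= alpha.
        ``method="single_pass"`` drops every non-significant non-intercept
        term of the current fit at once and refits once.  The two rules can
        disagree: a term marginal in the full model may become significant
        after another term's removal, in which case backward elimination
        keeps it and the single pass does not.  The intercept is always
        retained; the worst case is an intercept-only model.  Both rules are
        idempotent on an already-reduced model.
        """
        if method not in ("backward", "single_pass"):
            raise InputDataError(f"unknown reduction method {method!r}")

        def _refit(terms: list[str]) -> "ResponseSurfaceResults":
            surface = ResponseSurface(self.model.points, self.model.response, terms)
            surface.axial = self.model.axial
            return surface.fit()

        if method == "single_pass":
            keep = ["1"] + [
                t for t in self.terms if t != "1" and self.pvalues[t] <= alpha
            ]
            return self if len(keep) == len(self.terms) else _refit(keep)
        current = self
        while True:
            pvals = current.pvalues.drop("1", errors="ignore")
            if pvals.empty or pvals.max() <= alpha:
                return current
            worst = pvals.idxmax()
            current = _refit([t for t in current.terms if t != worst])

    # -- ANOVA -----------------------------------------------------------
    def anova(self, convention: str = "standard") -> pd.DataFrame:
        """Regression ANOVA about the mean.

        ``convention="standard"``: df_reg = k - 1, df_err = n - k.
        ``convention="paper"``: df_reg = k, df_err = n - k - 1, matching the
        degrees-of-freedom bookkeeping printed in some RSM reports.  The sums
        of squares are identical under both conventions; only the df (hence
        mean squares, F and p) differ.
        """
        y = self.model.response
        yhat = self.fittedvalues
        ss_reg = float(np.sum((yhat - y.mean()) ** 2))
        ss_err = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        n, k = y.size, len(self.terms)
        if convention == "standard":
            df_reg, df_err = k - 1, n - k
        elif convention == "paper":
            df_reg, df_err = k, n - k - 1
        else:
            raise InputDataError(f"unknown ANOVA convention {convention!r}; use 'standard' or 'paper'")
        df_tot = n - 1
        ms_reg = ss_reg / df_reg
        ms_err = ss_err / df_err
        f_val = ms_reg / ms_err
        p_val = float(stats.f.sf(f_val, df_reg, df_err))
        return pd.DataFrame(
            {
                "df": [df_reg, df_err, df_tot],
                "sum_sq": [ss_reg, ss_err, ss_tot],
                "mean_sq": [ms_reg, ms_err, np.nan],
                "F": [f_val, np.nan, np.nan],
                "p": [p_val, np.nan, np.nan],
            },
            index=["regression", "error", "total"],
        )

    # -- prediction ------------------------------------------------------
    def value_at(self, x0) -> float:
        """Point prediction of the surface at coded condition ``x0``."""
        row = design_matrix(np.atleast_2d(np.asarray(x0, float)), self.terms)[0]
        return float(row @ self.params.to_numpy())

    def predict(
        self,
        x0,
        confidence: float = 0.95,
        convention: str = "standard",
    ) -> PredictionResult:
        """Predict the response at ``x0`` with a confidence interval.

        The interval is  yhat(x0) +/- t_{alpha/2,df} * sqrt(sigma2 * x0'(X'X)^-1 x0).
        ``convention="standard"`` uses sigma2 = SSE/(n-k) and df = n - k;
        ``convention="paper"`` uses sigma2 = SSE/(n-k-1) and df = n - k - 1.
        Conditions outside the axial radius in any coordinate trigger an
        extrapolation warning (not an error).
        """
        x0 = np.asarray(x0, dtype=float).ravel()
        if x0.size != 2:
            raise InputDataError("x0 must be a coded (x1, x2) pair")
        if np.any(np.abs(x0) > self.model.axial + 1e-9):
            warnings.warn(
                f"condition {tuple(x0)} lies outside the design region "
                f"(axial distance {self.model.axial:.4g}); extrapolating",
                ExtrapolationWarning,
                stacklevel=2,
            )
        n, k = self.nobs, len(self.terms)
        if convention == "standard":
            df = n - k
            sigma2 = self.ssr / df
        elif convention == "paper":
            df = n - k - 1
            sigma2 = self.ssr / df
        else:
            raise InputDataError(f"unknown convention {convention!r}; use 'standard' or 'paper'")
        if not 0 < confidence < 1:
            raise InputDataError("confidence must lie in (0, 1)")
        row = design_matrix(x0[None, :], self.terms)[0]
        value = float(row @ self.params.to_numpy())
        leverage = float(row @ self.dispersion @ row)
        se = math.sqrt(sigma2 * leverage)
        t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, df))
        half = t_crit * se
        return PredictionResult(
            x0=tuple(x0),
            value=value,
            se=se,
            ci_low=value - half,
            ci_high=value + half,
            confidence=confidence,
            df=df,
        )

    # -- reporting -------------------------------------------------------
    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def summary(self, convention: str = "standard") -> str:
        rows = [
            "Response-surface regression (coded factors x1, x2)",
            f"  terms : {' + '.join(self.terms)}",
            f"  n = {self.nobs},  R^2 = {self.rsquared:.4f},  adj R^2 = {self.rsquared_adj:.4f}",
            "",
            "  term      coefficient          se           t            p",
        ]
        for term in self.terms:
            rows.append(
                f"  {term:<8} {self.params[term]: .5g}      {self.bse[term]:.4g}"
                f"      {self.tvalues[term]: .4g}      {self.pvalues[term]:.3e}"
            )
        an = self.anova(convention=convention)
        rows += ["", f"  ANOVA ({convention} convention)"]
        rows.append("  source       df      sum_sq        mean_sq       F         p")
        for name, r in an.iterrows():
            msq = "" if np.isnan(r["mean_sq"]) else f"{r['mean_sq']:.5g}"
            fv = "" if np.isnan(r["F"]) else f"{r['F']:.4g}"
            pv = "" if np.isnan(r["p"]) else f"{r['p']:.3e}"
            rows.append(
                f"  {name:<11} {int(r['df']):>3}   {r['sum_sq']:.6g}      {msq:<10}    {fv:<8}  {pv}"
            )
        return "\n".join(rows)

    def to_dict(self) -> dict:
        """JSON-serializable description (round-trips through ``from_dict``)."""
        return {
            "terms": list(self.terms),
            "points": self.model.points.tolist(),
            "response": self.model.response.tolist(),
            "axial": self.model.axial,
            "coefficients": self.params.to_dict(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ResponseSurfaceResults":
        surface = ResponseSurface(
            np.asarray(payload["points"], float),
            np.asarray(payload["response"], float),
            tuple(payload["terms"]),
        )
        surface.axial = float(payload.get("axial", SQRT2))
        return surface.fit()


def fit_polynomial(design, response, terms: Sequence[str] = TERMS) -> ResponseSurfaceResults:
    """OLS fit of ``response`` on the coded design over ``terms``."""
    return ResponseSurface(design, response, terms).fit()


def reduce_model(
    design,
    response,
    alpha: float = 0.05,
    terms: Sequence[str] = TERMS,
    method: str = "backward",
) -> ResponseSurfaceResults:
    """Fit the full polynomial then eliminate non-significant terms."""
    return ResponseSurface(design, response, terms).fit().reduce(alpha=alpha, method=method)


def anova(results: ResponseSurfaceResults, convention: str = "standard") -> pd.DataFrame:
    """ANOVA table for a fitted surface; see :meth:`ResponseSurfaceResults.anova`."""
    return results.anova(convention=convention)


def fixed_b(models_or_values) -> float:
    """Representative fixed value of the extension constant b.

    Given a fitted (preferably reduced) b-surface, returns its prediction at
    the design center — the model intercept, since every non-intercept term
    vanishes at the origin.  Given a raw vector of b values, returns their
    mean (which coincides with the center prediction for models without pure
    quadratic terms on an orthogonal design).
    """
    if isinstance(models_or_values, ResponseSurfaceResults):
        return models_or_values.value_at((0.0, 0.0))
    values = np.asarray(models_or_values, dtype=float).ravel()
    if values.size == 0:
        raise InputDataError("empty b vector")
    return float(values.mean())
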