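"""End-to-end study orchestration: per-curve fits -> surface models -> predictions.

A *study* is the full two-level workflow: every design run's hydrolysis
curve is fitted with the logarithmic model, the resulting constants ``a``
and ``b`` are each regressed on the coded design and reduced, ``b`` is
collapsed to its center value, and (optionally) hydrolysis curves and DH are
predicted at new conditions.  The study is described by a YAML file listing
the per-run curve files keyed by their coded conditions.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ResponseSurfaceResults, fit_polynomial, fixed_b, reduce_model
from .exceptions import FitError, InputDataError
from .io import read_curve, read_trace
from .kinetics import KineticFit, fit_log_model
from .prediction import PredictedCurve, predict_a, predict_curve
from .titration import AssayConfig, trace_to_curve

__all__ = ["StudyBundle", "run_study", "write_report"]

logger = logging.getLogger("hydrokin")


@dataclass
class StudyBundle:
    """All artifacts of one executed study."""

    points: np.ndarray
    fits: list[KineticFit | None]
    failed_runs: list[int]
    results_a: ResponseSurfaceResults
    results_b: ResponseSurfaceResults
    b_fixed: float
    predictions: list[dict] = field(default_factory=list)
    convention: str = "standard"
    alpha: float = 0.05
    config_hash: str = ""
    seed: int | None = None

    @property
    def ok(self) -> bool:
        return not self.failed_runs

    def fit_table(self) -> pd.DataFrame:
        rows = []
        for (x1, x2), fit in zip(self.points, self.fits):
            if fit is None:
                rows.append({"x1": x1, "x2": x2})
            else:
                rows.append({"x1": x1, "x2": x2, **fit.to_dict()})
        return pd.DataFrame(rows)


def _load_run(path: Path, kind: str, config: AssayConfig):
    if kind == "trace":
        return trace_to_curve(read_trace(path), config)
    if kind == "curve":
        return read_curve(path)
    raise InputDataError(f"unknown input kind {kind!r}; use 'trace' or 'curve'")


def run_study(config_path, assay: AssayConfig | None = None) -> StudyBundle:
    """Execute the two-level workflow described by a study YAML file.

    The file must list ``curves`` as mappings with keys ``x1``, ``x2`` and
    ``path``; optional keys are ``assay`` (constants mapping), ``input``
    (``trace`` or ``curve``, default ``trace``), ``alpha``, ``convention``,
    ``seed``, ``t_end``, ``confidence`` and ``predict`` (list of ``x1, x2``
    mappings).  A run whose fit fails is flagged and skipped; the study
    continues on the remaining runs and the bundle reports ``ok = False``.
    """
    config_path = Path(config_path)
    text = config_path.read_text(encoding="utf-8")
    spec = yaml.safe_load(text) or {}
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    seed = spec.get("seed")
    logger.info("study config=%s sha256=%s seed=%s hydrokin=%s numpy=%s",
                config_path.name, digest, seed, __version__, np.__version__)

    if assay is None:
        assay = AssayConfig.from_mapping(spec.get("assay", {})) if spec.get("assay") else AssayConfig()
    entries = spec.get("curves") or []
    if not entries:
        raise InputDataError(f"{config_path}: 'curves' list is empty")
    kind = spec.get("input", "trace")
    alpha = float(spec.get("alpha", 0.05))
    convention = spec.get("convention", "standard")

    points, fits, failed = [], [], []
    for i, entry in enumerate(entries):
        try:
            x1, x2, path = float(entry["x1"]), float(entry["x2"]), Path(entry["path"])
        except (KeyError, TypeError) as exc:
            raise InputDataError(f"{config_path}: curve entry {i} lacks x1/x2/path") from exc
        if not path.is_absolute():
            path = config_path.parent / path
        if not path.exists():
            raise InputDataError(f"missing curve file: {path}")
        points.append((x1, x2))
        try:
            curve = _load_run(path, kind, assay)
            fits.append(fit_log_model(curve))
        except FitError as exc:
            logger.warning("run %d (%s): fit failed: %s", i + 1, path.name, exc)
            fits.append(None)
            failed.append(i)
    points = np.asarray(points, dtype=float)

    good = [i for i in range(len(fits)) if fits[i] is not None]
    if len(good) < 6:
        raise InputDataError("fewer than 6 successful fits; cannot fit the full quadratic surface")
    x_good = points[good]
    a_vals = np.array([fits[i].a for i in good])
    b_vals = np.array([fits[i].b for i in good])
    results_a = reduce_model(x_good, a_vals, alpha=alpha)
    results_b = reduce_model(x_good, b_vals, alpha=alpha)
    b_fix = fixed_b(results_b)

    predictions = []
    t_end = float(spec.get("t_end", 60.0))
    confidence = float(spec.get("confidence", 0.95))
    for cond in spec.get("predict") or []:
        x0 = (float(cond["x1"]), float(cond["x2"]))
        pred = predict_a(results_a, x0, confidence=confidence, convention=convention)
        times = np.linspace(0.0, t_end, 121)
        curve = predict_curve(pred, b_fix, times, assay)
        predictions.append({"x0": x0, "a": pred, "curve": curve, "dh_60": curve.dh_mid[-1]})

    return StudyBundle(
        points=points,
        fits=fits,
        failed_runs=failed,
        results_a=results_a,
        results_b=results_b,
        b_fixed=b_fix,
        predictions=predictions,
        convention=convention,
        alpha=alpha,
        config_hash=digest,
        seed=seed,
    )


def _fmt(x: float, sig: int = 3) -> str:
    return f"{x:.{sig}g}"


def write_report(bundle: StudyBundle, path) -> None:
    """Render a deterministic plain-text study report.

    Fixed float formatting (3 significant figures for constants, scientific
    notation for p-values) so that rerunning on unchanged inputs produces a
    byte-identical file.
    """
    lines = [
        "hydrokin study report",
        f"config sha256 : {bundle.config_hash}",
        f"seed          : {bundle.seed}",
        f"alpha         : {bundle.alpha}",
        f"convention    : {bundle.convention}",
        "",
        "Per-run logarithmic fits  P = (1/b) ln(a b t + 1)",
        "  run    x1       x2       a(mM/min)  b(1/mM)   R^2",
    ]
    for i, ((x1, x2), fit) in enumerate(zip(bundle.points, bundle.fits), start=1):
        if fit is None:
            lines.append(f"  {i:>3}  {x1: .3f}  {x2: .3f}   FIT FAILED")
        else:
            lines.append(
                f"  {i:>3}  {x1: .3f}  {x2: .3f}   {_fmt(fit.a):<9}  {_fmt(fit.b):<8}  {fit.r_squared:.4f}"
            )
    for label, res in (("a", bundle.results_a), ("b", bundle.results_b)):
        lines += ["", f"Reduced surface for kinetic constant {label}", ""]
        lines.append("  " + res.summary(convention=bundle.convention).replace("\n", "\n  "))
    lines += ["", f"Fixed b (center value): {_fmt(bundle.b_fixed)}"]
    if bundle.predictions:
        lines += ["", "Predictions", "  x1      x2      a_pred    ci_low    ci_high   DH60(%)"]
        for p in bundle.predictions:
            a = p["a"]
            lines.append(
                f"  {p['x0'][0]: .3f} {p['x0'][1]: .3f}  {_fmt(a.value):<8}  {_fmt(a.ci_low):<8} "
                f" {_fmt(a.ci_high):<8}  {_fmt(p['dh_60'])}"
            )
    if bundle.failed_runs:
        lines += ["", f"WARNING: {len(bundle.failed_runs)} run(s) failed to fit: "
                  f"{[i + 1 for i in bundle.failed_runs]}"]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
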