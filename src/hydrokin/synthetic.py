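"""Synthetic pH-stat hydrolysis experiments for testing the full pipeline.

The generator integrates the rate law

    dP/dt = a * exp(-b*P) * exp(-k_d*t),        P(0) = 0,

by fixed-step fourth-order Runge-Kutta.  With k_d = 0 this reproduces the
logarithmic model's closed form exactly (to integrator accuracy); a positive
first-order inactivation rate k_d emulates a thermolabile protease whose
curves plateau early — the regime where the two-constant logarithmic model
is a deliberate misspecification.  The product curve is then converted back
to a cumulative titrant trace, V(t) = P(t)*alpha*V_T/N, and measurement
noise is applied on the titrant volume (the quantity the instrument actually
records): additive Gaussian noise, a running maximum to restore cumulative
monotonicity, then optional quantization to the dispensing resolution.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` stream per run, so every fixture is
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import CCCDesign, build_ccc, design_matrix
from .exceptions import InputDataError
from .titration import AssayConfig, HydrolysisCurve

__all__ = [
    "SimulationScenario",
    "surface_value",
    "simulate_product",
    "simulate_titration",
    "simulate_design_study",
    "noise_for_target_r2",
    "SimulatedStudy",
]

#: Default true a-surface (mM/min, coded units): the reduced Alcalase-like
#: model of the bundled milk study — intercept, linear T and E effects and a
#: T:E interaction.
DEFAULT_SURFACE: Mapping[str, float] = {"1": 9.69, "x1": 4.56, "x2": 4.88, "x1*x2": 2.82}


@dataclass(frozen=True)
class SimulationScenario:
    """Full specification of one simulated pH-stat study.

    Parameters
    ----------
    surface
        True a(x1, x2) polynomial, term -> coefficient in coded units.
    b_true
        True extension constant, 1/mM (shared by all runs, mirroring its
        substrate-driven nature).
    inactivation_rate
        First-order enzyme decay constant k_d (1/min); 0 disables
        inactivation.  ln(2)/10 corresponds to a 10-minute half-life, the
        behaviour of a thermolabile metalloprotease near 60 C.
    noise_sd
        Gaussian noise on the cumulative titrant volume, mL.
    titrant_resolution
        Dispensing quantum, mL; 0 means a continuous burette.
    sample_interval
        Sampling interval of the autotitrator, seconds (default one reading
        per second).
    duration
        Reaction time, minutes.
    seed
        Integer seed for the run's generator stream.
    """

    surface: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SURFACE))
    b_true: float = 0.0410
    inactivation_rate: float = 0.0
    noise_sd: float = 0.0
    titrant_resolution: float = 0.0
    sample_interval: float = 1.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.b_true <= 0:
            raise InputDataError("b_true must be > 0")
        if self.inactivation_rate < 0 or self.noise_sd < 0 or self.titrant_resolution < 0:
            raise InputDataError("rates, noise and resolution must be >= 0")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise InputDataError("sample_interval and duration must be > 0")

    def replace(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)


def surface_value(surface: Mapping[str, float], condition) -> float:
    """Evaluate a term->coefficient polynomial at one coded (x1, x2) point."""
    x = np.atleast_2d(np.asarray(condition, dtype=float))
    terms = list(surface)
    row = design_matrix(x, terms if "1" in terms else ["1"] + terms)
    if "1" not in terms:
        row = row[:, 1:]
    return float(row[0] @ np.array([surface[t] for t in terms]))


def _rk4_path(a: float, b: float, kd: float, times_min: np.ndarray, max_step: float = 0.01) -> np.ndarray:
    """Integrate dP/dt = a e^{-bP} e^{-kd t} through ``times_min`` (RK4, step <= max_step)."""

    def rate(t, p):
        return a * math.exp(-b * p) * math.exp(-kd * t)

    out = np.empty_like(times_min)
    out[0] = 0.0
    p = 0.0
    for i in range(1, times_min.size):
        t0, t1 = times_min[i - 1], times_min[i]
        n_sub = max(1, int(math.ceil((t1 - t0) / max_step)))
        h = (t1 - t0) / n_sub
        t = t0
        for _ in range(n_sub):
            k1 = rate(t, p)
            k2 = rate(t + h / 2, p + h * k1 / 2)
            k3 = rate(t + h / 2, p + h * k2 / 2)
            k4 = rate(t + h, p + h * k3)
            p += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            t += h
        out[i] = p
    return out


def simulate_product(scenario: SimulationScenario, condition=(0.0, 0.0)) -> HydrolysisCurve:
    """Noise-free product curve at one coded condition.

    The true initial rate is the scenario surface evaluated at the
    condition; the curve is the RK4 solution of the (optionally inactivating)
    rate law on the scenario's sampling grid.  With ``inactivation_rate=0``
    the result coincides with the logarithmic model's closed form.
    """
    a = surface_value(scenario.surface, condition)
    if a < 0:
        raise InputDataError(
            f"the surface gives a negative initial rate ({a:.3g}) at {tuple(condition)}"
        )
    n = int(round(scenario.duration * 60.0 / scenario.sample_interval))
    times = np.arange(n + 1) * (scenario.sample_interval / 60.0)  # minutes
    if a == 0.0:
        return HydrolysisCurve(times=times, product=np.zeros_like(times))
    product = _rk4_path(a, scenario.b_true, scenario.inactivation_rate, times)
    return HydrolysisCurve(times=times, product=np.maximum(product, 0.0))


def simulate_titration(
    curve: HydrolysisCurve,
    config: AssayConfig,
    scenario: SimulationScenario | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Turn a product curve into a noisy cumulative titration trace.

    Inverts the titration relation (V = P*alpha*V_T/N, mL), adds seeded
    Gaussian volume noise, restores monotonicity by a running maximum
    (anchored at V(0) = 0: the burette is zeroed at protease addition), and
    quantizes to the dispensing resolution.  Returns a frame with columns
    ``time`` (min) and ``volume`` (mL).
    """
    scenario = scenario or SimulationScenario()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    volume = curve.product * config.dissociation * config.reaction_volume_l / config.normality
    if scenario.noise_sd > 0:
        volume = volume + rng.normal(0.0, scenario.noise_sd, size=volume.shape)
    volume[0] = 0.0
    volume = np.maximum.accumulate(np.maximum(volume, 0.0))
    if scenario.titrant_resolution > 0:
        q = scenario.titrant_resolution
        volume = np.round(volume / q) * q
    return pd.DataFrame({"time": curve.times, "volume": volume})


@dataclass(frozen=True)
class SimulatedStudy:
    """Traces plus ground truth for one simulated design study."""

    traces: list
    truth: pd.DataFrame
    scenario: SimulationScenario
    design: CCCDesign


def simulate_design_study(
    scenario: SimulationScenario,
    design: CCCDesign | None = None,
    config: AssayConfig | None = None,
) -> SimulatedStudy:
    """One simulated pH-stat experiment per design row, with a truth table.

    The truth table records the surface's true ``a`` at each row and the
    shared ``b``, so that end-to-end parameter-recovery of the whole
    fit -> reduce -> predict pipeline can be scored.
    """
    design = design or build_ccc(n_center=2)
    config = config or AssayConfig()
    rng = np.random.default_rng(scenario.seed)
    traces, a_true = [], []
    for row in design.coded:
        curve = simulate_product(scenario, row)
        traces.append(simulate_titration(curve, config, scenario, rng=rng))
        a_true.append(surface_value(scenario.surface, row))
    truth = pd.DataFrame(
        {
            "x1": design.coded[:, 0],
            "x2": design.coded[:, 1],
            "a_true": a_true,
            "b_true": scenario.b_true,
        }
    )
    return SimulatedStudy(traces=traces, truth=truth, scenario=scenario, design=design)


def noise_for_target_r2(
    scenario: SimulationScenario,
    config: AssayConfig | None = None,
    condition=(0.0, 0.0),
    target_r2: float = 0.99,
) -> float:
    """Titrant-volume noise sd (mL) giving a chosen per-curve fit R^2.

    For homoscedastic product noise, R^2 of the curve fit is approximately
    1 - sigma_P^2/Var(P); inverting at the reference condition and mapping
    product noise back to volume noise through the titration relation gives
    the sd.  Used to pitch simulations at a stated fit quality instead of an
    arbitrary noise level.
    """
    if not 0 < target_r2 < 1:
        raise InputDataError("target_r2 must lie in (0, 1)")
    config = config or AssayConfig()
    curve = simulate_product(scenario, condition)
    var_p = float(np.var(curve.product))
    sigma_p = math.sqrt((1.0 - target_r2) * var_p)
    return sigma_p * config.dissociation * config.reaction_volume_l / config.normality
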