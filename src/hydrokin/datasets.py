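"""Bundled milk-protein hydrolysis study data.

A two-factor central composite circumscribed study of milk-protein
hydrolysis with three commercial bacterial proteases (Alcalase, Neutrase,
Protamex).  Temperature T (48-62 C, coded x1) and protease dose E
(19-231 mAU, coded x2) were varied over ten runs; each run's pH-stat curve
was summarized by the logarithmic-model constants (a, b), and four extra
runs per protease served as validation conditions.  The tables here are the
published per-run constants and validation summaries; the raw titration
traces are not public, which is exactly what the synthetic module
compensates for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import SQRT2, CCCDesign, VariableCoding
from .titration import AssayConfig

__all__ = [
    "default_assay",
    "variable_codings",
    "study_design",
    "load_kinetic_constants",
    "load_validation",
    "reduced_model_terms",
    "PROTEASES",
]

PROTEASES = ("alcalase", "neutrase", "protamex")

# Coded (x1=T, x2=E) design in the study's run order.
_DESIGN_ROWS = [
    (-SQRT2, 0.0),
    (-1.0, 1.0),
    (-1.0, -1.0),
    (0.0, SQRT2),
    (0.0, 0.0),
    (0.0, -SQRT2),
    (1.0, 1.0),
    (1.0, -1.0),
    (SQRT2, 0.0),
    (0.0, 0.0),
]

# Fitted logarithmic-model constants per run: (a [mM/min], b [1/mM], R^2).
_CONSTANTS = {
    "alcalase": [
        (4.06, 0.0494, 0.9940),
        (7.56, 0.0432, 0.9955),
        (2.89, 0.0498, 0.9955),
        (15.2, 0.0356, 0.9980),
        (9.46, 0.0359, 0.9928),
        (2.15, 0.0508, 0.9987),
        (21.7, 0.0361, 0.9990),
        (5.76, 0.0353, 0.9974),
        (17.8, 0.0343, 0.9981),
        (10.4, 0.0401, 0.9962),
    ],
    "neutrase": [
        (25.6, 0.135, 0.9967),
        (30.2, 0.104, 0.9923),
        (8.76, 0.105, 0.9996),
        (42.7, 0.080, 0.9985),
        (26.3, 0.082, 0.9993),
        (4.96, 0.082, 0.9993),
        (86.5, 0.078, 0.9933),
        (22.0, 0.085, 0.9934),
        (105.8, 0.090, 0.9866),
        (37.7, 0.084, 0.9989),
    ],
    "protamex": [
        (9.15, 0.0631, 0.9966),
        (16.5, 0.0509, 0.9983),
        (4.36, 0.0542, 0.9980),
        (26.6, 0.0409, 0.9991),
        (16.1, 0.0407, 0.9990),
        (2.93, 0.0498, 0.9981),
        (40.7, 0.0386, 0.9979),
        (9.44, 0.0392, 0.9993),
        (30.2, 0.0411, 0.9967),
        (16.5, 0.0399, 0.9990),
    ],
}

# Validation runs: coded condition, published predicted/experimental a
# (mM/min) and predicted/experimental DH after 60 min (%).
_VALIDATION = {
    "alcalase": [
        # (x1, x2, a_pred, a_exp, dh_pred, dh_exp)
        (-0.5, 0.0, 7.41, 9.10, 21.8, 25.7),
        (0.5, 0.0, 12.0, 10.2, 25.2, 24.8),
        (0.0, -1.0, 4.81, 3.92, 18.8, 19.6),
        (0.0, 1.0, 14.6, 13.8, 26.6, 27.2),
    ],
    "protamex": [
        (-0.5, 0.0, 13.6, 17.0, 25.5, 29.6),
        (0.5, 0.0, 21.0, 16.9, 28.5, 27.5),
        (0.0, -1.0, 7.65, 7.44, 21.6, 23.4),
        (0.0, 1.0, 26.8, 25.9, 30.3, 30.1),
    ],
}

# Retained term sets of the published reduced second-level models.
_REDUCED_TERMS = {
    "alcalase": {"a": ("1", "x1", "x2", "x1*x2"), "b": ("1", "x1", "x2")},
    "neutrase": {"a": ("1", "x1", "x2", "x1^2"), "b": ("1", "x1", "x1^2")},
    "protamex": {"a": ("1", "x1", "x2", "x1*x2"), "b": ("1", "x1", "x1^2")},
}


def default_assay() -> AssayConfig:
    """Assay constants of the bundled study.

    0.5 N NaOH titrant, average dissociation 0.2, 40 mL reaction volume
    (40 g of milk at unit density), 10.7 meq/g total alpha-amino content,
    1.24 g protein (3.1% w/w protein in 40 g).
    """
    return AssayConfig(
        normality=0.5,
        dissociation=0.2,
        reaction_volume_l=0.040,
        h_total=10.7,
        protein_mass_g=1.24,
    )


def variable_codings() -> dict[str, VariableCoding]:
    """Coded <-> natural transforms: T centered at 55 C (step 5), E at 125 mAU (step 75)."""
    return {
        "T": VariableCoding(name="T", center=55.0, step=5.0, axial=SQRT2),
        "E": VariableCoding(name="E", center=125.0, step=75.0, axial=SQRT2),
    }


def study_design() -> CCCDesign:
    """The ten-run coded CCC design in the study's run order."""
    return CCCDesign(coded=np.array(_DESIGN_ROWS), n_center=2, axial=SQRT2)


def load_kinetic_constants(protease: str | None = None) -> pd.DataFrame:
    """Per-run fitted kinetic constants.

    Columns: ``protease, exp, x1, x2, a, b, r_squared``; runs are numbered
    1-10 in study order.  Pass a protease name to filter.
    """
    frames = []
    for name in PROTEASES:
        rows = _CONSTANTS[name]
        frames.append(
            pd.DataFrame(
                {
                    "protease": name,
                    "exp": np.arange(1, 11),
                    "x1": [r[0] for r in _DESIGN_ROWS],
                    "x2": [r[1] for r in _DESIGN_ROWS],
                    "a": [r[0] for r in rows],
                    "b": [r[1] for r in rows],
                    "r_squared": [r[2] for r in rows],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if protease is not None:
        key = protease.lower()
        if key not in PROTEASES:
            raise KeyError(f"unknown protease {protease!r}; choose from {PROTEASES}")
        table = table[table["protease"] == key].reset_index(drop=True)
    return table


def load_validation(protease: str | None = None) -> pd.DataFrame:
    """Validation-run summaries for Alcalase and Protamex.

    Columns: coded condition, published predicted and experimental initial
    rate ``a`` (mM/min), and predicted and experimental DH after 60 min (%).
    Neutrase was excluded from validation (severe thermal inactivation).
    """
    frames = []
    for name, rows in _VALIDATION.items():
        frames.append(
            pd.DataFrame(
                rows, columns=["x1", "x2", "a_pred", "a_exp", "dh_pred", "dh_exp"]
            ).assign(protease=name, exp=np.arange(11, 15))
        )
    table = pd.concat(frames, ignore_index=True)
    if protease is not None:
        key = protease.lower()
        if key not in _VALIDATION:
            raise KeyError(f"no validation data for {protease!r}; available: {tuple(_VALIDATION)}")
        table = table[table["protease"] == key].reset_index(drop=True)
    return table[["protease", "exp", "x1", "x2", "a_pred", "a_exp", "dh_pred", "dh_exp"]]


def reduced_model_terms(protease: str, constant: str) -> tuple[str, ...]:
    """Retained term set of the published reduced model for one constant ('a' or 'b')."""
    key = protease.lower()
    if key not in _REDUCED_TERMS:
        raise KeyError(f"unknown protease {protease!r}; choose from {PROTEASES}")
    if constant not in ("a", "b"):
        raise KeyError("constant must be 'a' or 'b'")
    return _REDUCED_TERMS[key][constant]
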