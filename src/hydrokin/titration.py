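"""pH-stat titration records to product-concentration curves and degree of hydrolysis.

The pH-stat technique keeps the reaction pH constant by titrating the protons
released on peptide-bond cleavage with NaOH.  The cumulative base volume V
(mL) is therefore proportional to the concentration of released alpha-amino
groups::

    P [mM] = V * N / (alpha * V_T)

where N is the titrant normality (eq/L), alpha the average degree of
dissociation of the alpha-amino groups at the working pH, and V_T the
reaction volume (L).  The degree of hydrolysis follows by scaling against the
total alpha-amino content of the protein load::

    DH = P * V_T / (h_T * M_P)

with h_T the alpha-amino content per gram of protein (meq/g) and M_P the
protein mass in the reactor (g).  Both relations treat V_T as constant: the
added titrant volume is assumed not to dilute the mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, InputDataError, MonotonicityWarning

__all__ = [
    "TitrationRecord",
    "AssayConfig",
    "HydrolysisCurve",
    "volume_to_alpha_nh",
    "alpha_nh_to_dh",
    "trace_to_curve",
]


@dataclass(frozen=True)
class TitrationRecord:
    """One pH-stat reading: elapsed time (min) and cumulative NaOH volume (mL)."""

    time: float
    volume: float

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time < 0:
            raise InputDataError(f"time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.volume) or self.volume < 0:
            raise InputDataError(f"volume must be finite and >= 0, got {self.volume}")


@dataclass(frozen=True)
class AssayConfig:
    """Constants of the pH-stat assay shared by the titration conversions.

    Parameters
    ----------
    normality : float
        Titrant (NaOH) normality N, eq/L.
    dissociation : float
        Average degree of dissociation alpha of the released alpha-amino
        groups at the working pH, in (0, 1].
    reaction_volume_l : float
        Total reaction volume V_T in liters, assumed constant.
    h_total : float
        Total alpha-amino content of the protein h_T, meq per gram.
    protein_mass_g : float
        Protein mass in the reactor M_P, grams.
    """

    normality: float = 0.5
    dissociation: float = 0.2
    reaction_volume_l: float = 0.040
    h_total: float = 10.7
    protein_mass_g: float = 1.24

    def __post_init__(self):
        for name in ("normality", "dissociation", "reaction_volume_l", "h_total", "protein_mass_g"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ConfigurationError(f"{name} must be finite and > 0, got {value}")
        if self.dissociation > 1:
            raise ConfigurationError(f"dissociation must lie in (0, 1], got {self.dissociation}")

    @property
    def total_alpha_nh_meq(self) -> float:
        """Total titratable alpha-amino groups h_T * M_P, meq."""
        return self.h_total * self.protein_mass_g

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "AssayConfig":
        """Build from a flat mapping; accepts ``reaction_volume_ml`` as an alternative."""
        data = dict(mapping)
        if "reaction_volume_ml" in data:
            if "reaction_volume_l" in data:
                raise ConfigurationError("give reaction_volume_l or reaction_volume_ml, not both")
            data["reaction_volume_l"] = float(data.pop("reaction_volume_ml")) / 1000.0
        known = {"normality", "dissociation", "reaction_volume_l", "h_total", "protein_mass_g"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown assay keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_yaml(cls, path) -> "AssayConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: expected a mapping of assay constants")
        return cls.from_mapping(data)

    def replace(self, **kwargs) -> "AssayConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class HydrolysisCurve:
    """Released alpha-amino concentration P (mM) against reaction time (min)."""

    times: np.ndarray
    product: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        product = np.asarray(self.product, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "product", product)
        if times.ndim != 1 or product.ndim != 1:
            raise InputDataError("times and product must be one-dimensional")
        if times.shape != product.shape:
            raise InputDataError(
                f"length mismatch: {times.size} times vs {product.size} product values"
            )
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(product)):
            raise InputDataError("times and product must be finite")
        if times.size and times[0] < 0:
            raise InputDataError("times must be >= 0")
        if np.any(np.diff(times) <= 0):
            raise InputDataError("times must be strictly increasing")
        if np.any(product < 0):
            raise InputDataError("product concentrations must be >= 0")
        if times.size and times[0] == 0 and product[0] != 0:
            raise InputDataError("product must be 0 at time 0")

    def __len__(self) -> int:
        return self.times.size

    def dh(self, config: AssayConfig, percent: bool = True) -> np.ndarray:
        """Degree-of-hydrolysis series corresponding to this curve."""
        return alpha_nh_to_dh(self.product, config, percent=percent)

    def to_frame(self, config: AssayConfig | None = None) -> pd.DataFrame:
        frame = pd.DataFrame({"time": self.times, "alpha_nh_mM": self.product})
        if config is not None:
            frame["dh_percent"] = self.dh(config, percent=True)
        return frame


def volume_to_alpha_nh(volume_ml, config: AssayConfig):
    """Convert cumulative NaOH volume (mL) to released alpha-amino concentration (mM).

    P = V*N/(alpha*V_T); with V in mL, N in eq/L and V_T in L the result is
    mmol per liter of reaction mixture.  Linear in V.
    """
    volume_ml = np.asarray(volume_ml, dtype=float)
    if np.any(~np.isfinite(volume_ml)):
        raise InputDataError("titrant volume must be finite")
    if np.any(volume_ml < 0):
        raise InputDataError("titrant volume must be >= 0")
    result = volume_ml * config.normality / (config.dissociation * config.reaction_volume_l)
    return float(result) if result.ndim == 0 else result


def alpha_nh_to_dh(concentration_mm, config: AssayConfig, percent: bool = False):
    """Convert released alpha-amino concentration (mM) to degree of hydrolysis.

    DH = P*V_T/(h_T*M_P); dimensionless fraction, or percent when requested.
    """
    concentration_mm = np.asarray(concentration_mm, dtype=float)
    if np.any(concentration_mm < 0):
        raise InputDataError("concentration must be >= 0")
    dh = concentration_mm * config.reaction_volume_l / config.total_alpha_nh_meq
    if percent:
        dh = dh * 100.0
    return float(dh) if dh.ndim == 0 else dh


def _records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        missing = {"time", "volume"} - set(records.columns)
        if missing:
            raise InputDataError(f"trace frame lacks columns: {sorted(missing)}")
        return records["time"].to_numpy(float), records["volume"].to_numpy(float)
    times, volumes = [], []
    for rec in records:
        if isinstance(rec, TitrationRecord):
            times.append(rec.time)
            volumes.append(rec.volume)
        else:
            t, v = rec
            times.append(float(t))
            volumes.append(float(v))
    return np.asarray(times, float), np.asarray(volumes, float)


def trace_to_curve(
    records: Iterable[TitrationRecord] | pd.DataFrame | Sequence[tuple],
    config: AssayConfig,
    downsample: int | None = None,
    time_unit: str = "min",
    fix_monotonicity: bool = False,
) -> HydrolysisCurve:
    """Convert a cumulative titration trace to a :class:`HydrolysisCurve`.

    Parameters
    ----------
    records
        Sequence of :class:`TitrationRecord` (or ``(time, volume)`` pairs), or
        a DataFrame with columns ``time`` and ``volume``.
    config
        Assay constants used for the volume-to-concentration conversion.
    downsample
        Optional target point count; points are taken uniformly in index with
        the first and last record always retained.
    time_unit
        ``"min"`` (default) or ``"s"``; seconds are converted to minutes,
        the time unit used throughout the package.
    fix_monotonicity
        A cumulative volume that decreases is an input error by default.
        When True, it is corrected by a running maximum and a
        :class:`MonotonicityWarning` is emitted instead.
    """
    times, volumes = _records_to_arrays(records)
    if times.size == 0:
        raise InputDataError("empty titration trace")
    if not np.all(np.isfinite(times)):
        raise InputDataError("times must be finite (unsortable trace)")
    order = np.argsort(times, kind="stable")
    times, volumes = times[order], volumes[order]
    if np.any(np.diff(times) == 0):
        raise InputDataError("duplicate time points in titration trace")
    if time_unit == "s":
        times = times / 60.0
    elif time_unit != "min":
        raise InputDataError(f"unknown time unit {time_unit!r}; use 'min' or 's'")
    if np.any(np.diff(volumes) < 0):
        if not fix_monotonicity:
            raise InputDataError(
                "cumulative titrant volume decreases; pass fix_monotonicity=True to correct"
            )
        warnings.warn(
            "cumulative titrant volume decreased; corrected with a running maximum",
            MonotonicityWarning,
            stacklevel=2,
        )
        volumes = np.maximum.accumulate(volumes)
    if downsample is not None:
        if downsample < 2:
            raise InputDataError("downsample target must be >= 2 to keep both endpoints")
        if downsample < times.size:
            idx = np.unique(np.round(np.linspace(0, times.size - 1, downsample)).astype(int))
            times, volumes = times[idx], volumes[idx]
    product = volume_to_alpha_nh(volumes, config)
    return HydrolysisCurve(times=times, product=np.atleast_1d(product))
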