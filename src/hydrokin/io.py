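"""CSV/JSON/YAML input-output for curves, traces, models and study reports.

All files are plain comma-separated UTF-8 text with a header row and '.' as
the decimal mark, regardless of locale.  Numeric fields round-trip at full
double precision (17 significant digits); rendered reports use the display
precision of the study tables (3-4 significant figures).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import ResponseSurfaceResults
from .exceptions import InputDataError
from .titration import AssayConfig, HydrolysisCurve

__all__ = [
    "read_trace",
    "read_curve",
    "write_curve",
    "read_assay_config",
    "save_model",
    "load_model",
]


def _read_numeric_csv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    """Strict two-column numeric CSV reader with per-line error reporting."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise InputDataError(f"{path}: empty file")
        names = [h.strip() for h in header.rstrip("\n").split(",")]
        missing = set(columns) - set(names)
        if missing:
            raise InputDataError(f"{path}: header lacks columns {sorted(missing)}")
        idx = {c: names.index(c) for c in columns}
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(names):
                raise InputDataError(
                    f"{path}:{lineno}: expected {len(names)} fields, got {len(parts)}"
                )
            try:
                rows.append([float(parts[idx[c]]) for c in columns])
            except ValueError as exc:
                raise InputDataError(
                    f"{path}:{lineno}: non-numeric field ({exc}); note the decimal "
                    "mark must be '.', not ','"
                ) from None
    if not rows:
        raise InputDataError(f"{path}: no data rows after the header")
    return pd.DataFrame(rows, columns=list(columns))


def read_trace(path) -> pd.DataFrame:
    """Read a titration trace CSV with columns ``time,volume``."""
    return _read_numeric_csv(path, ("time", "volume"))


def read_curve(path) -> HydrolysisCurve:
    """Read a hydrolysis curve CSV with columns ``time,alpha_nh_mM``."""
    frame = _read_numeric_csv(path, ("time", "alpha_nh_mM"))
    return HydrolysisCurve(
        times=frame["time"].to_numpy(), product=frame["alpha_nh_mM"].to_numpy()
    )


def write_curve(curve: HydrolysisCurve, path, config: AssayConfig | None = None) -> None:
    """Write ``time,alpha_nh_mM[,dh_percent]`` at full double precision."""
    frame = curve.to_frame(config)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_assay_config(path) -> AssayConfig:
    """Read assay constants from YAML or flat ``key=value`` lines."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if "=" in text and ":" not in text:
        data = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputDataError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            data[key.strip()] = float(value.strip())
        return AssayConfig.from_mapping(data)
    loaded = yaml.safe_load(text) or {}
    return AssayConfig.from_mapping(loaded)


def save_model(results: ResponseSurfaceResults, path) -> None:
    """Serialize a fitted response surface to JSON (data + terms, refit on load)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> ResponseSurfaceResults:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    return ResponseSurfaceResults.from_dict(payload)
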