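"""Tabular and metadata output for analysis results.

Every analysis writes a tidy CSV (one row per time point, branch point or
division) plus a JSON sidecar with run metadata: model id, parameter values
and provenance, tolerances and software version.  Numbers are serialised at
12 significant digits, so identical inputs produce byte-identical files
(the whole pipeline is deterministic; there are no seeds).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import ParameterSet

__all__ = ["write_table", "write_metadata"]

_FLOAT_FMT = "%.12g"


def write_table(df: pd.DataFrame, path: Path | str) -> Path:
    """Write a tidy CSV with 12-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    return obj


def write_metadata(path: Path | str, *, model_id: str,
                   params: ParameterSet, analysis: str,
                   provenance: dict[str, str] | None = None,
                   rtol: float | None = None, atol: float | None = None,
                   **extras) -> Path:
    """Write the JSON sidecar describing one run.

    Units are fixed package-wide: time in minutes, concentrations in
    dimensionless activity units.  The note field records that reruns are
    seed-free deterministic.
    """
    meta = {
        "software": {"name": "mitoclock", "version": __version__},
        "model_id": model_id,
        "analysis": analysis,
        "units": {"time": "min", "concentration": "dimensionless a.u."},
        "parameters": _jsonable(params.as_dict()),
        "tolerances": {"rtol": rtol, "atol": atol},
        "determinism": "seed-free; identical inputs give identical outputs",
    }
    if provenance:
        meta["parameter_provenance"] = provenance
    meta.update(_jsonable(extras))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path
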