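"""CSV / JSON readers and writers for datasets, fit results and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import ExperimentalDataset, FitResult, RestartTrace
from .params import KineticParameters

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "write_fit_result",
    "read_fit_result",
    "write_json",
]


def read_timecourse_csv(path: str | Path) -> ExperimentalDataset:
    """Read a (scenario, dose_uM, time_min, miller_units[, weight]) CSV.

    Performs row-level validation; errors name the offending row (1-based,
    excluding the header) and field.  A missing weight column defaults to 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = ["scenario", "dose_uM", "time_min", "miller_units"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0

    for col in ("dose_uM", "time_min", "miller_units", "weight"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValueError(f"{path}: row {row}: non-numeric value in {col!r}")
        df[col] = coerced
    for col, lo in (("time_min", 0.0), ("dose_uM", 0.0), ("weight", 0.0)):
        bad = df.index[df[col] < lo]
        if len(bad):
            row = int(bad[0]) + 1
            raise ValueError(f"{path}: row {row}: {col} must be >= {lo}")
    bad = df.index[df["time_min"] > 500]
    if len(bad):
        raise ValueError(f"{path}: row {int(bad[0]) + 1}: time_min must be <= 500")
    return ExperimentalDataset(df)


def write_timecourse_csv(data: ExperimentalDataset, path: str | Path) -> None:
    data.records.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_fit_result(result: FitResult, path: str | Path) -> None:
    """Serialize a FitResult (parameters, SSE, bounds, trace, seed) as JSON."""
    write_json(result.to_dict(), path)


def read_fit_result(path: str | Path) -> FitResult:
    d = json.loads(Path(path).read_text())
    return FitResult(
        params=KineticParameters.from_dict(d["params"]),
        sse=d["sse"],
        free=tuple(d["free"]),
        bounds={k: tuple(v) for k, v in d["bounds"].items()},
        restarts=[RestartTrace(**r) for r in d["restarts"]],
        seed=d["seed"],
        variant=d["variant"],
    )
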