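"""File formats: trace CSV, fit-result JSON, metadata CSV, TIFF stacks.

Trace CSVs carry the columns ``time_s``, ``intensity_spot``,
``intensity_ref`` and ``is_prebleach``; metadata CSVs tag trace files
with their condition (``rh_percent``, ``temperature_c``, ``sample_id``,
``spot_id``, ``direction``, ``phase``).  Ground truth for generated
datasets goes into a JSON sidecar next to the data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap_core import FitResult, FrapTrace

__all__ = [
    "write_trace_csv", "read_trace_csv",
    "write_fit_json", "read_fit_json",
    "read_metadata_csv", "write_tiff_stack", "read_tiff_stack",
    "write_ground_truth_json",
]

METADATA_COLUMNS = ["trace_file", "rh_percent", "temperature_c",
                    "sample_id", "spot_id", "direction", "phase"]


def write_trace_csv(trace: FrapTrace, path: str | Path) -> None:
    pd.DataFrame({
        "time_s": trace.time,
        "intensity_spot": trace.spot_intensity,
        "intensity_ref": trace.reference_intensity,
        "is_prebleach": trace.prebleach_mask.astype(int),
    }).to_csv(path, index=False)


def read_trace_csv(path: str | Path, normalized: bool = False) -> FrapTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "intensity_spot", "intensity_ref", "is_prebleach"} - set(df)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return FrapTrace(
        time=df["time_s"].to_numpy(),
        spot_intensity=df["intensity_spot"].to_numpy(),
        reference_intensity=df["intensity_ref"].to_numpy(),
        prebleach_mask=df["is_prebleach"].to_numpy().astype(bool),
        normalized=normalized,
    )


def write_fit_json(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2))


def read_fit_json(path: str | Path) -> FitResult:
    data = json.loads(Path(path).read_text())
    data["covariance"] = np.asarray(data["covariance"], dtype=float)
    return FitResult(**data)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def write_tiff_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_tiff_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable({k: getattr(obj, k) for k in obj.__dataclass_fields__})
    return obj


def write_ground_truth_json(truth: dict, path: str | Path) -> None:
    """Sidecar with the generator's ground truth (arrays listed out)."""
    truth = {k: v for k, v in truth.items() if k != "stack"}
    Path(path).write_text(json.dumps(_jsonable(truth), indent=2))
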