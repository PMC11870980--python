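"""On-disk formats: BIDS-style events TSV and timecourse-matrix TSV
with a JSON sidecar.

Everything is plain text: tab-separated, "." decimal, UTF-8, header
row.  Matrices store rows = voxels/depth bins and columns = time
samples; their sampling interval and units travel in a sidecar JSON
next to the TSV.  Round trips are lossless to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = ["read_events", "write_events", "read_matrix", "write_matrix"]

EVENT_COLUMNS = ("onset", "duration", "trial_type")


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ParseError(f"event table lacks columns: {', '.join(missing)}")
    events.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV; errors carry 1-based line numbers."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as err:  # pragma: no cover - pandas message wrapped
        raise ParseError(f"{path}: cannot parse events TSV: {err}")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {', '.join(missing)}")
    for col in ("onset", "duration"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        if len(bad):
            raise ParseError(
                f"{path}: malformed number in column {col!r} at line {bad[0] + 2}")
        if coerced.isna().any():
            line = int(table.index[coerced.isna()][0]) + 2
            raise ParseError(f"{path}: missing {col!r} value at line {line}")
        table[col] = coerced
    stim_onsets = table.loc[table["trial_type"] == "stim", "onset"].to_numpy()
    if np.any(np.diff(stim_onsets) <= 0):
        k = int(np.nonzero(np.diff(stim_onsets) <= 0)[0][0])
        raise ParseError(
            f"{path}: stimulus onsets not strictly increasing near line {k + 2}")
    return table


def write_matrix(matrix: np.ndarray, path: str | Path, tr: float,
                 units: str = "arbitrary", seed: int | None = None) -> Path:
    """Write a (rows x time) matrix TSV plus its JSON sidecar."""
    path = Path(path)
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    frame = pd.DataFrame(matrix,
                         columns=[f"t{j}" for j in range(matrix.shape[1])])
    frame.insert(0, "row", np.arange(matrix.shape[0]))
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {"tr": tr, "n_rows": int(matrix.shape[0]),
               "n_samples": int(matrix.shape[1]), "units": units}
    if seed is not None:
        sidecar["seed"] = int(seed)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ParseError(f"{path}: missing JSON sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as err:  # pragma: no cover
        raise ParseError(f"{path}: cannot parse matrix TSV: {err}")
    if "row" in frame.columns:
        frame = frame.drop(columns="row")
    try:
        matrix = frame.to_numpy(dtype=float)
    except ValueError as err:
        raise ParseError(f"{path}: non-numeric matrix entry: {err}")
    return matrix, meta
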