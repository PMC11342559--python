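"""Result analytics and file plumbing.

Covers the comparison metrics used to confront simulated and measured
joint kinematics (per-coordinate RMSE on a common time grid), laxity
envelope tables, zero-phase Butterworth smoothing for imported
joint-simulator recordings, and CSV readers/writers with a small
``# key: value`` metadata header block.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .equilibrium_solver import LAXITY_PROTOCOL, KinematicsTrace, LaxityResult

__all__ = [
    "rmse",
    "trace_rmse",
    "laxity_envelope",
    "butterworth_smooth",
    "write_trace_csv",
    "read_trace_csv",
    "read_experimental_csv",
]

GS_COLUMNS = ("flexion_deg", "varus_deg", "external_deg",
              "medial_mm", "anterior_mm", "superior_mm")


def _as_frame(trace) -> pd.DataFrame:
    if isinstance(trace, KinematicsTrace):
        return trace.to_frame()
    return pd.DataFrame(trace)


def rmse(trace_a, trace_b, coordinate: str, n_grid: int = 200) -> float:
    """Root-mean-square difference of one coordinate between two traces.

    Both traces (``KinematicsTrace`` or DataFrames with a ``time_s``
    column) are linearly resampled onto a uniform time grid spanning
    their overlapping time range before the pointwise comparison, so
    recordings with different sampling do not need to be aligned first.
    """
    a, b = _as_frame(trace_a), _as_frame(trace_b)
    for df in (a, b):
        if "time_s" not in df or coordinate not in df:
            raise ValueError(f"trace lacks time_s/{coordinate} columns")
    t0 = max(a.time_s.min(), b.time_s.min())
    t1 = min(a.time_s.max(), b.time_s.max())
    if not t1 > t0:
        raise ValueError("traces have no overlapping time range")
    grid = np.linspace(t0, t1, n_grid)
    ya = np.interp(grid, a.time_s, a[coordinate])
    yb = np.interp(grid, b.time_s, b[coordinate])
    return float(np.sqrt(np.mean((ya - yb) ** 2)))


def trace_rmse(trace_a, trace_b, coordinates=GS_COLUMNS[1:]) -> pd.Series:
    """RMSE for several coordinates at once (mm for translations, deg
    for rotations)."""
    return pd.Series({c: rmse(trace_a, trace_b, c) for c in coordinates})


def laxity_envelope(result: LaxityResult) -> pd.DataFrame:
    """Envelope table of a laxity test: per flexion angle the driven
    coordinate at -load (lower), passive, +load (upper), and the range.

    Legs are labeled by signed applied load; a non-converged leg makes
    the corresponding position and the range NaN (missing), never zero.
    """
    coord = result.driven_coordinate
    spec = LAXITY_PROTOCOL[result.test]
    rows = []
    for rec in result.records:
        def val(key):
            st = rec[key]
            if st is None or not st.converged:
                return np.nan
            return getattr(st.gs, coord)
        upper, lower, passive = val("plus"), val("minus"), val("passive")
        rows.append({
            "angle_deg": rec["angle_deg"],
            "test": result.test,
            "coordinate": coord,
            "load_plus": rec.get("load_plus", spec["load"]),
            "load_minus": rec.get("load_minus", -spec["load"]),
            "load_unit": spec["unit"],
            "lower": lower,
            "passive": passive,
            "upper": upper,
            "range": np.abs(upper - lower),
            "converged_all": bool(rec["passive"].converged
                                  and rec["plus"].converged
                                  and rec["minus"].converged),
        })
    return pd.DataFrame(rows)


def butterworth_smooth(series, fs: float, cutoff_hz: float = 6.0,
                       order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth smoothing of a uniformly sampled
    signal (filtfilt, so DC gain is exactly 1 and no phase lag is
    introduced).  Intended for imported experimental recordings, e.g.
    100 Hz joint-simulator data; simulated traces are noise-free and are
    not filtered."""
    y = np.asarray(series, dtype=float)
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie below the "
                         f"Nyquist frequency {fs / 2} Hz")
    b, a = signal.butter(order, cutoff_hz, fs=fs)
    padlen = min(3 * max(len(a), len(b)), len(y) - 1)
    return signal.filtfilt(b, a, y, padlen=padlen)


def write_trace_csv(df, path, metadata: dict | None = None) -> None:
    """CSV with a ``# key: value`` header block followed by the table."""
    df = _as_frame(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_trace_csv(path):
    """Inverse of :func:`write_trace_csv`: returns (DataFrame, metadata)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def read_experimental_csv(path, smooth: bool = False, fs: float = 100.0,
                          cutoff_hz: float = 6.0) -> pd.DataFrame:
    """Read a joint-simulator kinematics export (time + six coordinate
    columns), optionally applying the standard zero-phase Butterworth
    smoothing used for 100 Hz recordings."""
    df, _ = read_trace_csv(path)
    missing = [c for c in ("time_s",) + GS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"experimental trace missing columns: {missing}")
    if smooth:
        out = df.copy()
        for c in GS_COLUMNS:
            out[c] = butterworth_smooth(df[c].to_numpy(), fs=fs,
                                        cutoff_hz=cutoff_hz)
        return out
    return df
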