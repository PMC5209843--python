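"""CSV input/output.

The tip-position table is the contract between the imaging and rhythm
stages: one row per frame with columns ``frame_index, time_h`` and, per
chamber *i*, ``c<i>_left_y`` and ``c<i>_right_y`` (empty field = missing
frame).  Dialect is fixed for bit-stable outputs: UTF-8, "." decimal point,
"," separator, mandatory header.  The vertical coordinate is
upward-positive (image height minus pixel row).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .series import TimeSeries

_TRACE_COL = re.compile(r"^(?P<chamber>c\d+)_(?P<leaf>left|right)_y$")


def write_positions_csv(path, traces, times_h: np.ndarray,
                        include_unusable: bool = True) -> None:
    """Write tip positions of a plate (list of SeedlingTrace) to CSV."""
    data: dict[str, object] = {
        "frame_index": np.arange(len(times_h), dtype=int),
        "time_h": np.asarray(times_h, dtype=float),
    }
    for tr in traces:
        if not include_unusable and not tr.usable:
            continue
        data[f"c{tr.chamber_index}_left_y"] = tr.left.y
        data[f"c{tr.chamber_index}_right_y"] = tr.right.y
    pd.DataFrame(data).to_csv(path, index=False)


def write_series_csv(path, series: TimeSeries, column: str = "y") -> None:
    """Write one time series (e.g. a simulated trace) to CSV."""
    pd.DataFrame({"time_h": series.t, column: series.y}).to_csv(path, index=False)


def read_positions_csv(path) -> dict[str, TimeSeries]:
    """Read any CSV with a ``time_h`` column plus one column per trace.

    Returns a mapping of column name -> TimeSeries.  Columns named in the
    imaging convention (``c<i>_left_y``) keep that label; any other numeric
    column is accepted as a free-form trace.
    """
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise ValueError(f"{path}: a 'time_h' column is required")
    t = df["time_h"].to_numpy(dtype=float)
    out: dict[str, TimeSeries] = {}
    for col in df.columns:
        if col in ("time_h", "frame_index"):
            continue
        y = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        out[col] = TimeSeries(t, y, label=col)
    return out


def trace_pairs(traces: dict[str, TimeSeries]) -> dict[str, dict[str, TimeSeries]]:
    """Group imaging-convention columns into per-chamber left/right pairs.

    Free-form columns (no ``c<i>_left_y`` pattern) become singleton entries
    under their own name with leaf key "left".
    """
    pairs: dict[str, dict[str, TimeSeries]] = {}
    for name, ts in traces.items():
        m = _TRACE_COL.match(name)
        if m:
            pairs.setdefault(m["chamber"], {})[m["leaf"]] = ts
        else:
            pairs.setdefault(name, {})["left"] = ts
    return pairs


def write_periods_csv(path, rows: list[dict]) -> None:
    """Write per-trace period results.

    Expected keys: trace_label, chamber, leaf, period_h, phase_h,
    amplitude_px, rel_err, n_terms, status.
    """
    cols = ["trace_label", "chamber", "leaf", "period_h", "phase_h",
            "amplitude_px", "rel_err", "n_terms", "status"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_periods_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_groups_csv(path) -> dict[str, str]:
    """Map chamber/trace label -> group label (columns: chamber, group)."""
    df = pd.read_csv(path)
    if not {"chamber", "group"} <= set(df.columns):
        raise ValueError(f"{path}: columns 'chamber' and 'group' are required")
    return dict(zip(df["chamber"].astype(str), df["group"].astype(str)))


def write_group_stats_csv(path, result) -> None:
    """Write a GroupResult as a two-row summary CSV."""
    df = pd.DataFrame({
        "group": result.labels,
        "n": result.n,
        "mean_period_h": result.mean,
        "sd_h": result.sd,
        "t": [result.t_statistic] * 2,
        "df": [result.df] * 2,
        "p_value": [result.p_value] * 2,
    })
    df.to_csv(path, index=False)


def ensure_parent(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path
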