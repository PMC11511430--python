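"""Reading, trimming and Z-score normalisation of region time-series matrices.

A dataset is a T x R matrix of BOLD responses sampled every ``tr_seconds``:
one column per named region (e.g. V1 ... V5/MT), one row per frame. The
first frames of a scan are typically discarded (magnetisation has not
reached steady state) and each region's series is Z-scored before
modelling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesMatrix",
    "read_timeseries",
    "write_timeseries",
    "drop_initial_frames",
    "zscore",
]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """T x R matrix of region responses with labels and sampling interval.

    Parameters
    ----------
    values
        Array of shape (T, R); signal units, or Z-scores if ``normalized``.
    region_labels
        R unique region names, one per column.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    normalized
        True once each column has been Z-scored (mean 0, sample sd 1).
    """

    values: np.ndarray
    region_labels: tuple[str, ...]
    tr_seconds: float = 3.0
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (time x region) array")
        t, r = values.shape
        if t < 2 or r < 1:
            raise ValueError(f"need T >= 2 and R >= 1, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains missing or non-finite values")
        if len(self.region_labels) != r:
            raise ValueError(
                f"{len(self.region_labels)} labels for {r} columns"
            )
        if len(set(self.region_labels)) != r:
            raise ValueError(f"duplicate region labels: {list(self.region_labels)}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.normalized:
            mean = values.mean(axis=0)
            sd = values.std(axis=0, ddof=1)
            if np.any(np.abs(mean) > 1e-8) or np.any(np.abs(sd - 1.0) > 1e-8):
                raise ValueError("normalized flag set but columns are not Z-scores")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def column(self, region: str) -> np.ndarray:
        return self.values[:, self.region_labels.index(region)]


def _detect_delimiter(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_timeseries(
    path: str,
    delimiter: str | None = None,
    tr_seconds: float = 3.0,
    ignore_time_column: bool = False,
) -> TimeSeriesMatrix:
    """Read a delimited matrix with a header row of region names.

    The delimiter is auto-detected between comma and tab when not given.
    With ``ignore_time_column`` the first column is dropped (a time axis).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    with open(path) as fh:
        raw_header = [c.strip() for c in fh.readline().rstrip("\n").split(delimiter)]
    if len(set(raw_header)) != len(raw_header):  # pandas would mangle these
        raise ValueError(f"{path}: duplicate region labels in header: {raw_header}")
    df = pd.read_csv(path, sep=delimiter, header=0)
    if ignore_time_column:
        df = df.iloc[:, 1:]
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values or ragged rows")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric data cell ({exc})") from exc
    labels = [str(c) for c in df.columns]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate region labels in header: {labels}")
    return TimeSeriesMatrix(values, tuple(labels), tr_seconds=tr_seconds)


def write_timeseries(ts: TimeSeriesMatrix, path: str) -> None:
    """Write comma-delimited with full float precision (round-trip safe)."""
    pd.DataFrame(ts.values, columns=list(ts.region_labels)).to_csv(path, index=False)


def drop_initial_frames(ts: TimeSeriesMatrix, n_drop: int) -> TimeSeriesMatrix:
    """Remove the first ``n_drop`` frames (scanner equilibration period)."""
    if n_drop < 0:
        raise ValueError("n_drop must be non-negative")
    if n_drop >= ts.n_frames:
        raise ValueError(
            f"cannot drop {n_drop} of {ts.n_frames} frames: nothing would remain"
        )
    if n_drop == 0:
        return ts
    # trimming invalidates exact column moments, so the flag is reset
    return replace(ts, values=ts.values[n_drop:].copy(), normalized=False)


def zscore(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Z-score each region's series: (x - mean) / sample sd (divisor T-1)."""
    mean = ts.values.mean(axis=0)
    sd = ts.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.region_labels[i] for i in bad]
        raise ValueError(f"constant region(s) cannot be Z-scored: {names}")
    return replace(ts, values=(ts.values - mean) / sd, normalized=True)
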