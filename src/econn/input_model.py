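"""System-input series u(t) for each region.

For periodic (block / phase-encoded) task designs the stimulus drive is
modelled by the fundamental frequency of each region's own response: the
single non-DC DFT bin with the largest magnitude, reconstructed in the
time domain with its amplitude and phase. For resting state the input is
identically zero; a measured or simulated input can also be supplied as a
matrix file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_norm import TimeSeriesMatrix, read_timeseries

__all__ = ["InputMatrix", "extract_fundamental", "zero_input", "read_input"]

#: recognised provenance tags for an input matrix
SOURCES = ("fft_fundamental", "file", "zero", "simulated")


@dataclass(frozen=True)
class InputMatrix:
    """T x R per-region input series paired with a :class:`TimeSeriesMatrix`.

    ``fundamental_cycles[r]`` records the winning DFT bin (cycles per
    record) when ``source == "fft_fundamental"``; otherwise it is None.
    """

    values: np.ndarray
    source: str
    fundamental_cycles: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("input values must be 2-D (time x region)")
        if self.source not in SOURCES:
            raise ValueError(f"unknown input source {self.source!r}")
        if self.source == "zero" and np.any(values != 0.0):
            raise ValueError("zero-source input must be identically 0")
        if self.fundamental_cycles is not None:
            object.__setattr__(
                self, "fundamental_cycles", tuple(int(c) for c in self.fundamental_cycles)
            )
            if len(self.fundamental_cycles) != values.shape[1]:
                raise ValueError("one fundamental cycle count per region required")

    @property
    def is_zero(self) -> bool:
        return self.source == "zero"


def extract_fundamental(ts: TimeSeriesMatrix) -> InputMatrix:
    """Per-region fundamental-frequency sinusoid of the response.

    Each column is mean-removed, transformed with the real FFT, and the
    bin of maximum magnitude among 1 ... floor(T/2) is kept (ties broken
    toward the lower frequency); the returned series is the inverse
    transform of that single bin, so amplitude and phase of the dominant
    periodic component are preserved. The DC level is discarded — the
    model intercept absorbs it.
    """
    t = ts.n_frames
    if t < 4:
        raise ValueError("need at least 4 frames to estimate a fundamental")
    out = np.empty_like(ts.values)
    cycles = []
    for j, label in enumerate(ts.region_labels):
        col = ts.values[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"region {label!r} is constant: no non-DC component")
        spec = np.fft.rfft(col - col.mean())
        # bins 1 .. floor(T/2); argmax returns the first (lowest-frequency) max
        k = 1 + int(np.argmax(np.abs(spec[1:])))
        keep = np.zeros_like(spec)
        keep[k] = spec[k]
        out[:, j] = np.fft.irfft(keep, n=t)
        cycles.append(k)
    return InputMatrix(out, source="fft_fundamental", fundamental_cycles=tuple(cycles))


def zero_input(ts: TimeSeriesMatrix) -> InputMatrix:
    """All-zero input matching ``ts`` — the resting-state convention."""
    return InputMatrix(np.zeros_like(ts.values), source="zero")


def read_input(path: str, ts: TimeSeriesMatrix, delimiter: str | None = None) -> InputMatrix:
    """Load a user-supplied input matrix; shape and region order must match."""
    loaded = read_timeseries(path, delimiter=delimiter, tr_seconds=ts.tr_seconds)
    if loaded.values.shape != ts.values.shape:
        raise ValueError(
            f"input shape {loaded.values.shape} does not match data {ts.values.shape}"
        )
    if loaded.region_labels != ts.region_labels:
        raise ValueError("input file region labels differ from the data file")
    return InputMatrix(loaded.values, source="file")
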