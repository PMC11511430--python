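"""Polynomial (NARX) predictor matrix for one seed region.

For a seed region the dependent variable is Y_seed(t), t = P+1 ... T, and
the predictors are four blocks of lagged terms over all R regions and
lags 1 ... P:

==========  ===========================  ==================
block       content                      columns
==========  ===========================  ==================
AR          Y_r(t-l)                     R * P
Input       u_r(t-l)                     R * P
ArNon       Y_r(t-l)^2                   R * P
iNonlin     u_r(t-l)^2                   R * P
==========  ===========================  ==================

Within each block columns are ordered lag by lag with the region cycling
fastest: Y1(t-1), Y2(t-1), ..., YR(t-1), Y1(t-2), ..., YR(t-P). Nonlinear
cross terms such as Y2(t-1)*Y3(t-2) are deliberately excluded: a product
of two regions has no single-source causal reading. The intercept is not
a column; fits handle it separately.

When the input is identically zero (resting state) the Input and iNonlin
blocks are omitted by default — zero columns carry no information and
break standardisation — leaving 2*R*P columns; a flag retains them as
zero columns for layout compatibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .input_model import InputMatrix
from .io_norm import TimeSeriesMatrix

__all__ = ["BLOCKS", "ColumnDescriptor", "DesignMatrix", "build_design", "parameter_count"]

BLOCKS = ("AR", "Input", "ArNon", "iNonlin")

#: what each block contains (squared-response vs squared-input terms)
BLOCK_CONTENT = {
    "AR": "Y",
    "Input": "u",
    "ArNon": "Y^2",
    "iNonlin": "u^2",
}


@dataclass(frozen=True, order=True)
class ColumnDescriptor:
    """One predictor column: block, source region (1-based index), lag."""

    block: str
    region: int
    lag: int
    region_label: str = ""

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}")

    @property
    def content(self) -> str:
        return BLOCK_CONTENT[self.block]

    @property
    def is_input(self) -> bool:
        return self.block in ("Input", "iNonlin")

    @property
    def is_quadratic(self) -> bool:
        return self.block in ("ArNon", "iNonlin")

    def name(self) -> str:
        base = "u" if self.is_input else "Y"
        sq = "^2" if self.is_quadratic else ""
        return f"{base}{self.region}{sq}(t-{self.lag})"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.block}:{self.region_label or self.region}:{self.lag}"


@dataclass(frozen=True)
class DesignMatrix:
    """(T-P) x C predictor matrix X with response y for one seed region."""

    X: np.ndarray
    y: np.ndarray
    columns: tuple[ColumnDescriptor, ...]
    seed_region: str
    ar_order: int
    region_labels: tuple[str, ...]
    with_inputs: bool

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("one descriptor per column required")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def column_index(self, desc: ColumnDescriptor) -> int:
        return self.columns.index(desc)

    def to_frame(self) -> pd.DataFrame:
        """Audit export: header cells are ``block:region_label:lag``."""
        return pd.DataFrame(self.X, columns=[str(c) for c in self.columns])


def parameter_count(n_regions: int, ar_order: int, with_inputs: bool = True) -> int:
    """Number of model parameters including the intercept.

    Four blocks of R*P terms with inputs present (4*R*P + 1), two without
    (2*R*P + 1). For 8 regions at AR order 3 with inputs this is 97.
    """
    if n_regions < 1 or ar_order < 1:
        raise ValueError("need n_regions >= 1 and ar_order >= 1")
    blocks = 4 if with_inputs else 2
    return blocks * n_regions * ar_order + 1


def build_design(
    ts: TimeSeriesMatrix,
    u: InputMatrix,
    seed_region: str,
    ar_order: int,
    keep_zero_input_blocks: bool = False,
) -> DesignMatrix:
    """Assemble the lagged polynomial predictor matrix for ``seed_region``.

    Rows correspond to t = P+1 ... T so every predictor uses strictly
    past values; the first P frames appear only as lags.
    """
    if ar_order < 1:
        raise ValueError("ar_order must be >= 1")
    if seed_region not in ts.region_labels:
        raise ValueError(f"unknown seed region {seed_region!r}")
    t, r = ts.values.shape
    p = ar_order
    if t <= p:
        raise ValueError(f"need more than ar_order={p} frames, got {t}")
    if u.values.shape != ts.values.shape:
        raise ValueError("input matrix shape must match the time series")

    with_inputs = not (u.is_zero and not keep_zero_input_blocks)
    block_names = BLOCKS if with_inputs else ("AR", "ArNon")
    lagged = {
        "AR": ts.values,
        "Input": u.values,
        "ArNon": ts.values**2,
        "iNonlin": u.values**2,
    }

    n = t - p
    cols: list[ColumnDescriptor] = []
    mats: list[np.ndarray] = []
    for block in block_names:
        src = lagged[block]
        for lag in range(1, p + 1):
            # rows are t = p .. t-1 (0-based), so lag l reads rows p-l .. t-1-l
            mats.append(src[p - lag : t - lag, :])
            cols.extend(
                ColumnDescriptor(block, j + 1, lag, ts.region_labels[j])
                for j in range(r)
            )
    x = np.concatenate(mats, axis=1)
    y = ts.column(seed_region)[p:].copy()

    if n <= x.shape[1]:
        warnings.warn(
            f"design has {n} rows but {x.shape[1]} columns (p >= n); "
            "LASSO selection remains well defined",
            stacklevel=2,
        )
    return DesignMatrix(
        X=x,
        y=y,
        columns=tuple(cols),
        seed_region=seed_region,
        ar_order=p,
        region_labels=ts.region_labels,
        with_inputs=with_inputs,
    )
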