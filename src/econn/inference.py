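"""Granger-causality tests on the selected terms and network assembly.

Each selected term is tested by comparing nested OLS fits: the
unrestricted model regresses the seed response on every selected column
plus the intercept; the restricted model removes the tested term. With
RRSS and URSS the restricted/unrestricted residual sums of squares,

    F = ((RRSS - URSS) / q) / (URSS / (N - k)),   q = 1 per term,

where N is the number of design rows and k the number of unrestricted
parameters including the intercept. The equivalent t statistic is
t = sign(coefficient) * sqrt(F), with t^2 = F exactly. A significant
term reads as a directed edge: its source region (response or input,
linear or squared, at its lag) influences the seed region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ColumnDescriptor, DesignMatrix
from .selection import SelectionResult

__all__ = ["EdgeTest", "test_term", "test_all", "build_network", "INTERCEPT"]

#: sentinel for testing the intercept (never an edge)
INTERCEPT = "intercept"


@dataclass(frozen=True)
class EdgeTest:
    """Nested-model test of one selected term (or the intercept)."""

    term: ColumnDescriptor | str
    coefficient: float
    rrss: float
    urss: float
    q: int
    df_denominator: int
    F: float
    t: float
    p_value: float
    significant: bool
    alpha: float
    seed_region: str

    @property
    def is_intercept(self) -> bool:
        return self.term == INTERCEPT

    @property
    def edge(self) -> tuple[str, str, int, str] | None:
        """(source, target, lag, term_type) or None for the intercept."""
        if self.is_intercept:
            return None
        src = ("u" if self.term.is_input else "") + (self.term.region_label or str(self.term.region))
        kind = ("quadratic" if self.term.is_quadratic else "linear")
        kind += "_input" if self.term.is_input else "_response"
        return (src, self.seed_region, self.term.lag, kind)


def _rss(X: np.ndarray, y: np.ndarray, intercept: bool) -> float:
    cols = [np.ones(len(y))] if intercept else []
    if X.size:
        cols.append(X)
    if not cols:
        return float(y @ y)
    a = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    r = y - a @ beta
    return float(r @ r)


def test_term(
    dm: DesignMatrix,
    support: tuple[ColumnDescriptor, ...],
    term: ColumnDescriptor | str,
    alpha: float = 0.05,
) -> EdgeTest:
    """F/t test of one term of the selected model against its removal."""
    support = tuple(support)
    if term != INTERCEPT and term not in support:
        raise ValueError(f"term {term} is not in the selected support")
    idx = [dm.column_index(c) for c in support]
    X = dm.X[:, idx]
    y = dm.y
    n = dm.n_rows
    k = len(support) + 1  # unrestricted parameters incl. intercept
    dfd = n - k
    if dfd <= 0:
        raise ValueError(f"no residual degrees of freedom: N={n}, k={k}")

    urss = _rss(X, y, intercept=True)
    a = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(a, y, rcond=None)
    if term == INTERCEPT:
        coef = float(beta[0])
        rrss = _rss(X, y, intercept=False)
    else:
        pos = support.index(term)
        coef = float(beta[pos + 1])
        rest = X[:, [j for j in range(len(support)) if j != pos]]
        rrss = _rss(rest, y, intercept=True)
    rrss = max(rrss, urss)  # guard tiny negative differences from lstsq round-off

    if urss <= 1e-12 * max(1.0, float(y @ y)):  # numerically perfect fit
        warnings.warn(
            f"perfect fit for seed {dm.seed_region}: F reported as infinity",
            stacklevel=2,
        )
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (rrss - urss) / (urss / dfd)
        p = float(stats.f.sf(f_stat, 1, dfd))
    t_stat = math.copysign(math.sqrt(f_stat), coef) if f_stat != math.inf else math.copysign(math.inf, coef)
    return EdgeTest(
        term=term,
        coefficient=coef,
        rrss=rrss,
        urss=urss,
        q=1,
        df_denominator=dfd,
        F=f_stat,
        t=t_stat,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        seed_region=dm.seed_region,
    )


def test_all(dm: DesignMatrix, sr: SelectionResult, alpha: float = 0.05,
             bonferroni: bool = False) -> list[EdgeTest]:
    """Test the intercept and every selected term of one seed model.

    Results keep the design's block order. ``bonferroni`` divides alpha
    by the number of tests; by default no multiplicity correction is
    applied.
    """
    terms: list[ColumnDescriptor | str] = [INTERCEPT, *sr.support]
    level = alpha / len(terms) if bonferroni else alpha
    return [test_term(dm, sr.support, term, alpha=level) for term in terms]


def build_network(tests_per_seed: dict[str, list[EdgeTest]], alpha: float = 0.05) -> pd.DataFrame:
    """Directed edge list over all analysed seed regions.

    One row per non-intercept term: source, target, lag, term type,
    coefficient, F, t, df, p, significance, and a self-loop tag for AR
    terms of the seed on itself.
    """
    # the region index -> label mapping must agree across seed analyses
    labels: dict[int, str] = {}
    for seed, tests in tests_per_seed.items():
        for et in tests:
            if et.is_intercept:
                continue
            if et.seed_region != seed:
                raise ValueError(f"tests under seed {seed!r} belong to {et.seed_region!r}")
            known = labels.setdefault(et.term.region, et.term.region_label)
            if known != et.term.region_label:
                raise ValueError(
                    f"inconsistent region sets across seeds: region {et.term.region} "
                    f"is {known!r} vs {et.term.region_label!r}"
                )

    rows = []
    for seed, tests in tests_per_seed.items():
        for et in tests:
            if et.is_intercept:
                continue
            src, tgt, lag, kind = et.edge
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "lag": lag,
                    "term_type": kind,
                    "coefficient": et.coefficient,
                    "F": et.F,
                    "t": et.t,
                    "df": et.df_denominator,
                    "p": et.p_value,
                    "significant": bool(et.p_value < alpha),
                    "self_loop": bool(not et.term.is_input and et.term.region_label == seed),
                }
            )
    columns = ["source", "target", "lag", "term_type", "coefficient", "F", "t",
               "df", "p", "significant", "self_loop"]
    return pd.DataFrame(rows, columns=columns)
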