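"""Nested-model F/t term tests and network assembly."""

import numpy as np
import pytest
from scipy import stats

from econn import build_design, build_network, fit_lasso_path
from econn.inference import test_all as granger_test_all
from econn.inference import test_term as granger_test_term
from econn.design import ColumnDescriptor
from econn.inference import INTERCEPT


def _plain_design(X, y):
    from econn.design import DesignMatrix

    cols = tuple(ColumnDescriptor("AR", j + 1, 1, f"x{j+1}") for j in range(X.shape[1]))
    return DesignMatrix(X=X, y=y, columns=cols, seed_region="y", ar_order=1,
                        region_labels=tuple(c.region_label for c in cols),
                        with_inputs=False)


def _classical_t(X, y):
    """Textbook OLS t statistics via (X'X)^{-1} and coefficient SEs."""
    a = np.column_stack([np.ones(len(y)), X])
    xtx_inv = np.linalg.inv(a.T @ a)
    beta = xtx_inv @ a.T @ y
    resid = y - a @ beta
    s2 = resid @ resid / (len(y) - a.shape[1])
    se = np.sqrt(s2 * np.diag(xtx_inv))
    return beta, beta / se


class TestTestTerm:
    def test_f_equals_squared_classical_t(self, rng):
        """F from nested RSS comparison == t^2 from the closed-form OLS
        oracle, for every term of a 3-predictor toy model."""
        n = 30
        X = rng.standard_normal((n, 3))
        y = 1.0 + X @ np.array([0.5, -1.2, 0.0]) + 0.3 * rng.standard_normal(n)
        dm = _plain_design(X, y)
        support = dm.columns
        beta, t_oracle = _classical_t(X, y)
        for pos, term in enumerate([INTERCEPT, *support]):
            et = granger_test_term(dm, support, term)
            assert et.F == pytest.approx(t_oracle[pos] ** 2, abs=1e-8)
            assert et.t == pytest.approx(t_oracle[pos], abs=1e-8)
            assert et.coefficient == pytest.approx(beta[pos], abs=1e-10)
            assert et.t**2 == pytest.approx(et.F, abs=1e-10)
            assert et.rrss >= et.urss >= 0

    def test_duplicated_column_gives_f_zero(self, rng):
        n = 25
        x = rng.standard_normal(n)
        X = np.column_stack([x, x])  # exact duplicate
        y = x + 0.1 * rng.standard_normal(n)
        dm = _plain_design(X, y)
        et = granger_test_term(dm, dm.columns, dm.columns[0])
        assert et.F == pytest.approx(0.0, abs=1e-8)
        assert et.p_value == pytest.approx(1.0, abs=1e-6)

    def test_df_convention_117_minus_6(self, rng):
        """5 selected terms + intercept at N=117 -> denominator df 111."""
        X = rng.standard_normal((120, 8))
        from econn import InputMatrix, TimeSeriesMatrix

        ts = TimeSeriesMatrix(X, tuple(f"V{i+1}" for i in range(8)))
        u = InputMatrix(rng.standard_normal((120, 8)), source="file")
        dm = build_design(ts, u, "V1", 3)
        support = tuple(dm.columns[j] for j in (0, 10, 30, 55, 90))
        et = granger_test_term(dm, support, support[0])
        assert dm.n_rows == 117
        assert et.df_denominator == 111

    def test_f_vs_two_sided_t_pvalue(self, rng):
        n = 40
        X = rng.standard_normal((n, 2))
        y = X[:, 0] * 0.4 + rng.standard_normal(n)
        dm = _plain_design(X, y)
        et = granger_test_term(dm, dm.columns, dm.columns[0])
        p_t = 2 * stats.t.sf(abs(et.t), et.df_denominator)
        assert et.p_value == pytest.approx(p_t, abs=1e-10)

    def test_perfect_fit_reports_infinite_f(self):
        x = np.linspace(0, 1, 20)
        y = 2.0 + 3.0 * x  # exactly linear, no noise
        dm = _plain_design(x[:, None], y)
        with pytest.warns(UserWarning, match="perfect fit"):
            et = granger_test_term(dm, dm.columns, dm.columns[0])
        assert et.F == np.inf
        assert et.p_value == 0.0

    def test_term_not_in_support_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        dm = _plain_design(X, rng.standard_normal(20))
        with pytest.raises(ValueError, match="support"):
            granger_test_term(dm, (dm.columns[0],), dm.columns[1])

    def test_zero_coefficient_term_gives_f_zero(self, rng):
        # y built to be exactly orthogonal to the tested column's unique part
        n = 50
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y0 = x1 + 0.5 * rng.standard_normal(n)
        # subtract x2's fitted contribution so its refit coefficient is ~0
        # while a genuine residual remains
        a = np.column_stack([np.ones(n), x1, x2])
        c2 = np.linalg.lstsq(a, y0, rcond=None)[0][2]
        y = y0 - c2 * x2
        dm = _plain_design(np.column_stack([x1, x2]), y)
        et = granger_test_term(dm, dm.columns, dm.columns[1])
        assert abs(et.coefficient) < 1e-10
        assert et.F < 1e-8


class TestTestAll:
    def test_counts_and_order(self, three_region_sim):
        _, ts, u, _ = three_region_sim
        dm = build_design(ts, u, "V1", 2)
        sr = fit_lasso_path(dm, n_folds=5, seed=6)
        tests = granger_test_all(dm, sr)
        assert len(tests) == len(sr.support) + 1
        assert tests[0].is_intercept
        assert [t.term for t in tests[1:]] == list(sr.support)

    def test_bonferroni_flag_tightens_level(self, three_region_sim):
        _, ts, u, _ = three_region_sim
        dm = build_design(ts, u, "V1", 2)
        sr = fit_lasso_path(dm, n_folds=5, seed=6)
        plain = granger_test_all(dm, sr, alpha=0.05)
        corr = granger_test_all(dm, sr, alpha=0.05, bonferroni=True)
        assert all(c.alpha == pytest.approx(0.05 / len(plain)) for c in corr)
        assert sum(c.significant for c in corr) <= sum(p.significant for p in plain)


class TestBuildNetwork:
    def _tests_for(self, ts, u, region, seed):
        dm = build_design(ts, u, region, 2)
        sr = fit_lasso_path(dm, n_folds=5, seed=seed)
        return granger_test_all(dm, sr)

    def test_edge_list_round_trip(self, three_region_sim, tmp_path):
        import pandas as pd

        _, ts, u, _ = three_region_sim
        tests = {r: self._tests_for(ts, u, r, 9) for r in ts.region_labels}
        edges = build_network(tests)
        path = tmp_path / "edges.csv"
        edges.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, edges, check_dtype=False)

    def test_intercept_never_an_edge(self, three_region_sim):
        _, ts, u, _ = three_region_sim
        tests = {"V1": self._tests_for(ts, u, "V1", 2)}
        edges = build_network(tests)
        assert len(edges) == sum(not t.is_intercept for t in tests["V1"])

    def test_self_loops_tagged(self, three_region_sim):
        _, ts, u, _ = three_region_sim
        tests = {"V1": self._tests_for(ts, u, "V1", 2)}
        edges = build_network(tests)
        for _, row in edges.iterrows():
            expected = row["source"] == "V1" and not row["source"].startswith("u")
            assert row["self_loop"] == expected

    def test_diagonal_network_has_no_cross_edges(self):
        """Each region depends only on its own lag (zero noise): no
        significant cross-region response edge may appear."""
        from econn.simulator import InputSpec, NetworkModel, simulate

        model = NetworkModel(
            n_regions=3,
            max_lag=1,
            ar_coeffs={(r, r, 1): 0.5 for r in (1, 2, 3)},
            input_coeffs={(r, r, 1): 0.8 for r in (1, 2, 3)},
            noise_sd=0.4,
            input_specs=(
                InputSpec("sinusoid", 5, 1.0, 0.0),
                InputSpec("sinusoid", 9, 1.0, 1.0),
                InputSpec("sinusoid", 14, 1.0, 2.0),
            ),
            n_frames=120,
            burn_in=50,
            seed=3,
        )
        ts, u, _ = simulate(model)
        tests = {}
        for region in ts.region_labels:
            dm = build_design(ts, u, region, 1)
            # true support (own AR lag, own input) plus one null cross term
            r = ts.region_labels.index(region) + 1
            other = r % 3 + 1
            support = (
                ColumnDescriptor("AR", r, 1, region),
                ColumnDescriptor("Input", r, 1, region),
                ColumnDescriptor("AR", other, 1, ts.region_labels[other - 1]),
            )
            tests[region] = [granger_test_term(dm, support, t) for t in support]
        edges = build_network(tests)
        cross = edges[(edges["term_type"] == "linear_response") & (~edges["self_loop"])]
        assert cross.empty or not cross["significant"].any()

    def test_inconsistent_region_labels_rejected(self, three_region_sim):
        _, ts, u, _ = three_region_sim
        tests = {"V1": self._tests_for(ts, u, "V1", 2)}
        bad = [t for t in tests["V1"] if not t.is_intercept][0]
        from dataclasses import replace

        clash = replace(bad, term=replace(bad.term, region_label="OTHER"),
                        seed_region="V2")
        with pytest.raises(ValueError):
            build_network({"V1": tests["V1"], "V2": [clash]})
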