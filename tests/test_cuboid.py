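"""Cuboid selection: combinatorics, criteria semantics, calibration."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabcc import (CaseCohortStudy, assign_to_cuboid, enumerate_lines,
                     near_cubic_dims, run_line_regressions, select_by_criterion,
                     two_round_selection)


def z_table(rows):
    """Build a line-regression table from (variable, z1, z2, z3) tuples."""
    recs = []
    for line_id_base, (v, *zs) in enumerate(rows):
        for dim, z in enumerate(zs):
            recs.append(dict(variable=v, dim=dim, line_id=line_id_base * 3 + dim,
                             z=z, rank=np.nan, is_noise=False, converged=True))
    return pd.DataFrame(recs)


class TestAssignment:
    def test_exact_fit_has_no_noise(self):
        a = assign_to_cuboid([f"v{i}" for i in range(8)], (2, 2, 2), 0,
                             pd.RangeIndex(5))
        assert a.noise_ids == []
        assert sorted(a.cell_of.values()) == sorted(
            (i, j, k) for i in range(2) for j in range(2) for k in range(2))

    def test_padding_count_for_full_scale_layout(self):
        ids = [f"v{i}" for i in range(1153)]
        a = assign_to_cuboid(ids, (11, 11, 10), 0, pd.RangeIndex(3))
        assert len(a.noise_ids) == 1210 - 1153 == 57
        assert len(a.cell_of) == 1210

    def test_too_small_cuboid_names_minimal_dims(self):
        with pytest.raises(ValueError, match="near-cubic"):
            assign_to_cuboid([f"v{i}" for i in range(9)], (2, 2, 2), 0,
                             pd.RangeIndex(3))

    def test_same_seed_reproducible(self):
        ids = [f"v{i}" for i in range(20)]
        a = assign_to_cuboid(ids, (3, 3, 3), 5, pd.RangeIndex(10))
        b = assign_to_cuboid(ids, (3, 3, 3), 5, pd.RangeIndex(10))
        assert a.cell_of == b.cell_of
        pd.testing.assert_frame_equal(a.noise_values, b.noise_values)

    def test_noise_standard_normal(self):
        a = assign_to_cuboid(["v0"], (4, 4, 4), 0, pd.RangeIndex(4000))
        vals = a.noise_values.to_numpy()
        assert abs(vals.mean()) < 0.05
        assert abs(vals.std() - 1) < 0.05


class TestLines:
    @pytest.mark.parametrize("dims", [(2, 2, 2), (3, 4, 5), (11, 11, 10), (1, 2, 3)])
    def test_counts_and_membership(self, dims):
        d1, d2, d3 = dims
        n = d1 * d2 * d3
        a = assign_to_cuboid([f"v{i}" for i in range(n)], dims, 0, pd.RangeIndex(2))
        lines = enumerate_lines(a)
        assert len(lines) == d2 * d3 + d1 * d3 + d1 * d2
        cnt = Counter(v for line in lines for v in line)
        assert set(cnt.values()) == {3}

    def test_full_scale_line_count(self):
        a = assign_to_cuboid([f"v{i}" for i in range(1153)], (11, 11, 10), 0,
                             pd.RangeIndex(2))
        assert len(enumerate_lines(a)) == 341

    def test_near_cubic_dims(self):
        assert near_cubic_dims(122) == (5, 5, 5)
        assert near_cubic_dims(8) == (2, 2, 2)
        assert near_cubic_dims(1) == (1, 1, 1)
        for k in (7, 29, 100, 500):
            d = near_cubic_dims(k)
            assert np.prod(d) >= k


class TestCriteria:
    def test_all_three_rule_for_z_threshold(self):
        tab = z_table([("a", 3.0, 2.6, 2.7), ("b", 3.0, 3.0, 2.4)])
        assert select_by_criterion(tab, "z_gt_2.5") == {"a"}

    def test_negative_z_counts_two_sided(self):
        tab = z_table([("a", -3.0, -2.6, 2.7)])
        assert select_by_criterion(tab, "z_gt_2.5") == {"a"}

    def test_rank_criteria(self):
        recs = []
        for dim in range(3):
            zs = {"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}
            # rank a=1 in all, b=2 in all; c=3 in all
            order = sorted(zs, key=lambda v: -zs[v])
            for rank, v in enumerate(order, start=1):
                recs.append(dict(variable=v, dim=dim, line_id=dim, z=zs[v],
                                 rank=rank, is_noise=False, converged=True))
        tab = pd.DataFrame(recs)
        assert select_by_criterion(tab, "top2") == {"a", "b"}
        assert select_by_criterion(tab, "top3") == {"a", "b", "c"}

    def test_ranked_1_2_3_selected_under_top3_not_top2(self):
        recs = []
        for dim, rank in enumerate([1, 2, 3]):
            recs.append(dict(variable="v", dim=dim, line_id=dim, z=2.0,
                             rank=rank, is_noise=False, converged=True))
        tab = pd.DataFrame(recs)
        assert select_by_criterion(tab, "top3") == {"v"}
        assert select_by_criterion(tab, "top2") == set()

    def test_top2_selections_subset_of_top3(self):
        rng = np.random.default_rng(0)
        n = 60
        ids = [f"v{i}" for i in range(n)]
        a = assign_to_cuboid(ids, (4, 4, 4), 0, pd.RangeIndex(300))
        df = pd.DataFrame({
            "event_time": rng.exponential(1, 300) + 0.01,
            "event": rng.random(300) < 0.5,
            "in_subcohort": True,
            "y": rng.normal(size=300),
        }, index=pd.RangeIndex(300))
        st = CaseCohortStudy(df, 1.0)
        V = pd.DataFrame(rng.normal(size=(300, n)), index=df.index, columns=ids)
        tab = run_line_regressions(st, V, a, backend="linear", outcome="y")
        assert select_by_criterion(tab, "top2") <= select_by_criterion(tab, "top3")


class TestLineRegressions:
    def _null_setup(self, rng, n=356, m=64, dims=(4, 4, 4)):
        df = pd.DataFrame({
            "event_time": rng.exponential(1, n) + 0.01,
            "event": rng.random(n) < 0.5,
            "in_subcohort": True,
            "y": rng.normal(size=n),
        }, index=pd.RangeIndex(n))
        ids = [f"v{i}" for i in range(m)]
        V = pd.DataFrame(rng.normal(size=(n, m)), index=df.index, columns=ids)
        a = assign_to_cuboid(ids, dims, int(rng.integers(2**31)), df.index)
        return CaseCohortStudy(df, 1.0), V, a

    def test_three_distinct_line_fits_per_variable(self):
        rng = np.random.default_rng(1)
        st, V, a = self._null_setup(rng)
        tab = run_line_regressions(st, V, a, backend="linear", outcome="y")
        per_var = tab.groupby("variable")
        assert (per_var["line_id"].nunique() == 3).all()
        assert (per_var["dim"].nunique() == 3).all()

    def test_null_z_scores_standard_normal(self):
        rng = np.random.default_rng(2)
        zs = []
        for _ in range(8):
            st, V, a = self._null_setup(rng)
            tab = run_line_regressions(st, V, a, backend="linear", outcome="y")
            zs.append(tab["z"].to_numpy())
        zs = np.concatenate(zs)
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_strong_signal_attains_rank_one(self):
        rng = np.random.default_rng(3)
        hits, reps = 0, 30
        for _ in range(reps):
            n = 300
            V = pd.DataFrame(rng.normal(size=(n, 27)),
                             columns=[f"v{i}" for i in range(27)])
            y = 1.0 * V["v0"] + rng.normal(size=n)
            df = pd.DataFrame({"event_time": np.ones(n), "event": True,
                               "in_subcohort": True, "y": y}, index=V.index)
            st = CaseCohortStudy(df, 1.0)
            a = assign_to_cuboid(list(V.columns), (3, 3, 3),
                                 int(rng.integers(2**31)), V.index)
            tab = run_line_regressions(st, V, a, backend="linear", outcome="y")
            hits += (tab.loc[tab["variable"] == "v0", "rank"] == 1).all()
        assert hits / reps >= 0.95

    def test_variable_order_invariance_given_fixed_assignment(self):
        rng = np.random.default_rng(4)
        st, V, a = self._null_setup(rng)
        t1 = run_line_regressions(st, V, a, backend="linear", outcome="y")
        V2 = V[list(V.columns[::-1])]
        t2 = run_line_regressions(st, V2, a, backend="linear", outcome="y")
        m1 = t1.set_index(["variable", "dim"])["z"].sort_index()
        m2 = t2.set_index(["variable", "dim"])["z"].sort_index()
        pd.testing.assert_series_equal(m1, m2)

    def test_logistic_backend_runs(self):
        rng = np.random.default_rng(5)
        st, V, a = self._null_setup(rng, n=400)
        tab = run_line_regressions(st, V, a, backend="logistic", outcome="event")
        assert tab["converged"].all()
        assert abs(tab["z"].std() - 1) < 0.25


class TestTwoRound:
    def test_global_null_round2_tiny(self):
        rng = np.random.default_rng(6)
        n, m = 356, 125
        df = pd.DataFrame({"event_time": rng.exponential(1, n) + 0.01,
                           "event": rng.random(n) < 0.5, "in_subcohort": True,
                           "y": rng.normal(size=n)}, index=pd.RangeIndex(n))
        st = CaseCohortStudy(df, 1.0)
        V = pd.DataFrame(rng.normal(size=(n, m)), index=df.index,
                         columns=[f"v{i}" for i in range(m)])
        res = two_round_selection(st, V, (5, 5, 5), backend="linear",
                                  outcome="y", seed=0)
        # nesting of cumulative criterion sets always holds
        assert set(res.nested_sets["c1"]) <= set(res.nested_sets["c1_2"])
        assert set(res.nested_sets["c1_2"]) <= set(res.nested_sets["c1_3"])
        assert len(res.round2["z_gt_2.5"]) <= 3

    def test_embedded_signals_recovered(self, small_study, qc_metab):
        res = two_round_selection(small_study.study, qc_metab.values,
                                  backend="case-cohort-cox", seed=1)
        causal = set(small_study.truth.query("is_causal").index)
        sens = len(causal & res.round2_union) / len(causal)
        assert sens >= 0.6
        if res.final_coefficients is not None:
            found = causal & set(res.final_coefficients.index)
            assert (res.final_coefficients.loc[sorted(found), "coef"] > 0).all()

    def test_empty_union_terminates_cleanly(self):
        rng = np.random.default_rng(7)
        n = 200
        df = pd.DataFrame({"event_time": rng.exponential(1, n) + 0.01,
                           "event": rng.random(n) < 0.5, "in_subcohort": True,
                           "y": rng.normal(size=n)}, index=pd.RangeIndex(n))
        st = CaseCohortStudy(df, 1.0)
        V = pd.DataFrame(rng.normal(size=(n, 8)) * 1e-8 + 1e-6,
                         columns=[f"v{i}" for i in range(8)], index=df.index)
        # constant-ish variables yield no selections or a failure-free result
        res = two_round_selection(st, V, (2, 2, 2), backend="linear",
                                  outcome="y", seed=0)
        assert isinstance(res.round2_union, set)
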