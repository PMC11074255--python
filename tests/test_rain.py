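"""Umbrella rank test: statistic, exact nulls, window p-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tiderhythm as tr
from tiderhythm.rain import (
    CIRCADIAN_WINDOW,
    CIRCATIDAL_WINDOW,
    _exact_fold_pvalues,
    _fold_plan,
    _fold_statistics,
    _umbrella_pairs,
    _null_sf,
    _tie_pattern,
    n_distinct_arrangements,
    umbrella_exact_pvalue,
    umbrella_max_statistic,
    umbrella_statistic,
)

from conftest import brute_force_pvalue, brute_force_umbrella


class TestUmbrellaStatistic:
    def test_perfect_umbrella_attains_maximum(self):
        # groups (fold m=4 of 8 points): strictly rising to peak 2 then falling
        series = [1, 4, 9, 0, 2, 5, 10, 1.5]  # g0={1,2}, g1={4,5}, g2={9,10}, g3={0,1.5}
        a = umbrella_statistic(series, 4, 2)
        assert a == umbrella_max_statistic(8, 4, 2)

    def test_constant_series_sits_at_null_expectation(self):
        series = np.ones(12)
        for m, h in [(3, 0), (4, 2), (6, 5)]:
            a = umbrella_statistic(series, m, h)
            plan = _fold_plan(12, m, "linear")
            assert a == pytest.approx(plan["peaks"][h]["mean"])

    @pytest.mark.parametrize("m,h", [(4, 0), (4, 2), (3, 1)])
    def test_matches_pairwise_count_oracle(self, m, h):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 5, size=8).astype(float)  # ties likely
            expected = brute_force_umbrella(x, m, _umbrella_pairs(m, h))
            assert umbrella_statistic(x, m, h) == pytest.approx(expected)

    def test_exhaustive_enumeration_small_case(self):
        # n = 8 points, 4 phases of 2: statistic distribution over all
        # distinct arrangements matches the exact enumeration machinery
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        p, a_obs = _exact_fold_pvalues(x, 4, "linear")
        for h in range(4):
            oracle = brute_force_pvalue(x, 4, _umbrella_pairs(4, h))
            assert p[h] == pytest.approx(oracle, abs=1e-12)

    def test_invalid_peak_phase_rejected(self):
        with pytest.raises(ValueError):
            umbrella_statistic(np.arange(8), 4, 4)


class TestExactNulls:
    """The DP null, the multiset enumeration and brute force must agree."""

    @pytest.mark.parametrize("n,m", [(7, 3), (8, 4), (9, 4)])
    @pytest.mark.parametrize("kind", ["linear", "cyclic", "detect"])
    def test_dp_equals_enumeration_continuous(self, n, m, kind):
        x = np.random.default_rng(n * m).normal(size=n)
        p_enum, a_obs = _exact_fold_pvalues(x, m, kind)
        for k in range(len(p_enum)):
            sf2 = _null_sf(n, m, k, kind)
            assert sf2[int(round(2 * a_obs[k]))] == pytest.approx(p_enum[k], abs=1e-12)

    def test_enumeration_handles_ties_exactly(self):
        x = np.array([2.0, 0.0, 1.0, 2.0, 0.0, 1.0, 2.0, 1.0])
        p, a_obs = _exact_fold_pvalues(x, 4, "linear")
        pattern = _tie_pattern(x)
        for h in range(4):
            oracle = brute_force_pvalue(x, 4, _umbrella_pairs(4, h))
            assert p[h] == pytest.approx(oracle, abs=1e-12)
            # tie-aware DP agrees with both
            sf2 = _null_sf(8, 4, h, "linear", pattern)
            assert sf2[int(round(2 * a_obs[h]))] == pytest.approx(oracle, abs=1e-12)

    @given(st.lists(st.integers(0, 6), min_size=6, max_size=8))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_pvalue_matches_permutation_oracle(self, vals):
        x = np.array(vals, dtype=float)
        m = 3
        p = umbrella_exact_pvalue(x, m, 1)
        oracle = brute_force_pvalue(x, m, _umbrella_pairs(m, 1))
        assert p == pytest.approx(oracle, abs=1e-9)

    def test_normal_moments_match_enumeration(self):
        """Tie-corrected mean/variance equal the enumerated distribution's."""
        rng = np.random.default_rng(9)
        for vals in (rng.normal(size=7), rng.integers(0, 3, size=7).astype(float)):
            for m in (3, 4):
                plan = _fold_plan(7, m, "linear")
                perms = np.array(list(itertools.permutations(vals)))
                A, mean, var = _fold_statistics(perms, m, "linear")
                _, mean_th, var_th = _fold_statistics(vals[None, :], m, "linear")
                for k in range(len(plan["peaks"])):
                    assert A[:, k].mean() == pytest.approx(mean[k], abs=1e-9)
                    assert A[:, k].var() == pytest.approx(var_th[0, k], abs=1e-9)

    def test_arrangement_count(self):
        assert n_distinct_arrangements([1, 2, 3]) == 6
        assert n_distinct_arrangements([1, 1, 2]) == 3
        assert n_distinct_arrangements(np.ones(5)) == 1


class TestPeriodWindows:
    def test_circatidal_candidates(self):
        assert CIRCATIDAL_WINDOW.candidate_periods(3.1, 17) == \
            pytest.approx([9.3, 12.4, 15.5])

    def test_circadian_candidates(self):
        assert CIRCADIAN_WINDOW.candidate_periods(3.1, 17) == \
            pytest.approx([21.7, 24.8, 27.9])

    def test_window_without_multiple_of_dt_errors(self):
        w = tr.PeriodWindow("w", 5.0, 0.4)
        with pytest.raises(ValueError, match="no multiple"):
            w.candidate_folds(2.0, 17)

    def test_empty_phase_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            CIRCADIAN_WINDOW.candidate_folds(3.1, 6)


class TestRhythmPvalue:
    def test_constant_series_p_is_one(self):
        r = tr.rhythm_pvalue(np.ones(17), CIRCATIDAL_WINDOW, 3.1)
        assert r.p_value == 1.0

    def test_noiseless_circatidal_cosine_matches_fold_minimum(self):
        """A clean 12.4-h cosine's window p is the best alternative's exact
        enumeration p times the number of (period, phase, shape) alternatives."""
        t = np.arange(17) * 3.1
        x = 10 + 3 * np.cos(2 * np.pi * t / 12.4)
        r = tr.rhythm_pvalue(x, CIRCATIDAL_WINDOW, 3.1)
        assert r.best_period_hours == pytest.approx(12.4)
        n_alt = sum(2 * m for m in CIRCATIDAL_WINDOW.candidate_folds(3.1, 17))
        pattern = _tie_pattern(x)
        best = np.inf
        for m in CIRCATIDAL_WINDOW.candidate_folds(3.1, 17):
            plan = _fold_plan(17, m, "detect")
            A, _, _ = _fold_statistics(x[None, :], m, "detect")
            for k in range(len(plan["peaks"])):
                sf2 = _null_sf(17, m, k, "detect", pattern)
                best = min(best, sf2[int(round(2 * A[0, k]))])
        assert r.p_value == pytest.approx(min(1.0, best * n_alt), rel=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        x = rng.lognormal(2, 0.5, size=17)
        base = tr.rhythm_pvalue(x, CIRCATIDAL_WINDOW, 3.1)
        for f in (lambda v: 3 * v + 7, np.log, lambda v: v**3):
            r = tr.rhythm_pvalue(f(x), CIRCATIDAL_WINDOW, 3.1)
            assert r.p_value == base.p_value
            assert r.best_period_hours == base.best_period_hours
            assert r.statistic == base.statistic

    def test_exact_false_uses_normal_approximation(self):
        t = np.arange(17) * 3.1
        x = 10 + 3 * np.cos(2 * np.pi * t / 12.4)
        r_exact = tr.rhythm_pvalue(x, CIRCATIDAL_WINDOW, 3.1)
        r_norm = tr.rhythm_pvalue(x, CIRCATIDAL_WINDOW, 3.1, exact=False)
        assert r_norm.p_value > r_exact.p_value  # normal tail is conservative


class TestDetectRhythms:
    def test_all_constant_matrix_has_no_hits(self):
        import pandas as pd
        t = np.arange(17) * 3.1
        m = tr.ExpressionMatrix(pd.DataFrame(np.full((5, 17), 3.0),
                                             index=[f"g{i}" for i in range(5)],
                                             columns=t))
        res, sets = tr.detect_rhythms(m)
        assert sets["circatidal"] == set() and sets["circadian"] == set()
        assert (res.p_value == 1.0).all()

    def test_planted_circatidal_genes_recovered(self, default_sim):
        matrix, truth = default_sim
        res, sets = tr.detect_rhythms(matrix)
        tid = set(truth.loc[truth.rhythm_class == "circatidal", "unit_id"])
        recovered = len(sets["circatidal"] & tid) / len(tid)
        assert recovered >= 0.9

    def test_threshold_is_strict(self, default_sim):
        matrix, _ = default_sim
        res, sets = tr.detect_rhythms(matrix, alpha=0.01)
        tid = res[res.window == "circatidal"]
        at_alpha = set(tid.loc[tid.p_value < 0.01, "gene_id"])
        assert sets["circatidal"] == at_alpha
        # a gene with p exactly at alpha would be excluded
        assert not (tid.p_value == 0.01).any() or \
            set(tid.loc[tid.p_value == 0.01, "gene_id"]).isdisjoint(at_alpha)

    def test_best_period_in_candidates(self, default_sim):
        matrix, _ = default_sim
        res, _ = tr.detect_rhythms(matrix)
        tid = res[res.window == "circatidal"]
        assert set(np.round(tid.best_period_hours, 6)) <= {9.3, 12.4, 15.5}


class TestTransitions:
    @staticmethod
    def _results(sig):
        rows = []
        for gene, (p_tid, p_cir) in sig.items():
            rows.append({"gene_id": gene, "window": "circatidal", "p_value": p_tid})
            rows.append({"gene_id": gene, "window": "circadian", "p_value": p_cir})
        return pd.DataFrame(rows)

    def test_single_switching_gene_found(self):
        a = self._results({"g1": (0.5, 0.001), "g2": (0.5, 0.5),
                           "g3": (0.001, 0.001), "g4": (0.001, 0.5)})
        b = self._results({"g1": (0.001, 0.5), "g2": (0.5, 0.5),
                           "g3": (0.001, 0.5), "g4": (0.001, 0.5)})
        # g1: circadian-only in A -> circatidal-only in B
        assert tr.rhythm_class_transitions(a, b) == {"g1"}

    def test_no_switching_genes_is_empty(self):
        a = self._results({"g1": (0.001, 0.5), "g2": (0.5, 0.5)})
        b = self._results({"g1": (0.001, 0.5), "g2": (0.5, 0.5)})
        assert tr.rhythm_class_transitions(a, b) == set()

    def test_mismatched_universe_errors(self):
        a = self._results({"g1": (0.5, 0.5)})
        b = self._results({"g2": (0.5, 0.5)})
        with pytest.raises(ValueError, match="universe"):
            tr.rhythm_class_transitions(a, b)


def test_overlap_counts():
    sets = {"a": {"g1", "g2", "g3"}, "b": {"g2", "g3", "g4"}, "c": {"g5"}}
    df = tr.overlap_counts(sets)
    row = df[(df.set_a == "a") & (df.set_b == "b")].iloc[0]
    assert row.n_overlap == 2 and row.n_a == 3 and row.n_b == 3
    assert df[(df.set_a == "a") & (df.set_b == "c")].iloc[0].n_overlap == 0
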