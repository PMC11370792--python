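"""Set partitions, uniqueness index, overlap inference, matching, ORA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from ftldtx import genesets


class TestPartition:
    def test_disjoint_sets(self):
        part = genesets.partition_unique_shared({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert part[("A",)] == part[("B",)] == part[("C",)] == 1
        assert all(v == 0 for k, v in part.items() if len(k) > 1)

    def test_identical_sets(self):
        s = {"x", "y", "z"}
        part = genesets.partition_unique_shared({"A": set(s), "B": set(s), "C": set(s)})
        assert part[("A", "B", "C")] == 3
        assert all(v == 0 for k, v in part.items() if len(k) < 3)

    def test_matches_membership_pattern_tally(self):
        rng = np.random.default_rng(60)
        genes = [f"g{i}" for i in range(50)]
        sets = {n: {g for g in genes if rng.random() < 0.4} for n in "ABC"}
        part = genesets.partition_unique_shared(sets)
        for k in range(1, 4):
            for combo in itertools.combinations(sorted(sets), k):
                members = [g for g in genes
                           if all(g in sets[n] for n in combo)
                           and all(g not in sets[n] for n in sets if n not in combo)]
                assert part[combo] == len(members)
        assert sum(part.values()) == len(set().union(*sets.values()))

    def test_order_invariant(self):
        sets = {"A": {"a", "b"}, "B": {"b", "c"}, "C": {"c"}}
        p1 = genesets.partition_unique_shared(sets)
        p2 = genesets.partition_unique_shared(dict(reversed(list(sets.items()))))
        assert p1 == p2

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            genesets.partition_unique_shared({"A": {"a"}})


class TestUniquenessIndex:
    def test_direct_formula(self):
        part = {("A",): 2, ("B",): 2, ("C",): 2,
                ("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1, ("A", "B", "C"): 3}
        assert genesets.uniqueness_index(part) == pytest.approx(1.0)

    def test_no_shared_genes_undefined(self):
        part = {("A",): 2, ("B",): 1, ("C",): 0,
                ("A", "B"): 0, ("B", "C"): 0, ("A", "C"): 0, ("A", "B", "C"): 0}
        assert genesets.uniqueness_index(part) is None

    def test_hand_counted_toy(self):
        sets = {"A": {"a", "b", "s"}, "B": {"c", "s"}, "C": {"d", "e", "s", "t"},
                }
        sets["B"].add("t")
        part = genesets.partition_unique_shared(sets)
        # unique: A{a,b}, B{c}, C{d,e} = 5; shared: s (ABC), t (BC) = 2
        assert genesets.uniqueness_index(part) == pytest.approx(5 / 2)


class TestThresholdSweep:
    @staticmethod
    def _table(rs, ps):
        return pd.DataFrame({"r": rs, "p_fdr": ps},
                            index=[f"g{i}" for i in range(len(rs))])

    def test_single_tau_grid(self):
        t = self._table([0.5, -0.4, 0.1], [0.01, 0.01, 0.01])
        sweep = genesets.threshold_sweep({"A": t, "B": t, "C": t}, taus=[0.3])
        assert sweep.tau_star == 0.3

    def test_all_undefined_gives_none(self):
        # disjoint selections at every threshold -> shared counts all zero
        a = self._table([0.5, 0.0, 0.0], [0.01, 1.0, 1.0])
        b = self._table([0.0, 0.5, 0.0], [1.0, 0.01, 1.0])
        c = self._table([0.0, 0.0, 0.5], [1.0, 1.0, 0.01])
        sweep = genesets.threshold_sweep({"A": a, "B": b, "C": c}, taus=[0.1, 0.2])
        assert sweep.tau_star is None

    def test_plateau_rule_picks_first_tau_at_90pct(self):
        # construct: at tau<=0.2 shared gene g9 keeps U low; above 0.25 it drops out
        rs_a = [0.6, 0.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.22]
        rs_b = [0.0, 0.0, 0.6, 0.6, 0.0, 0.0, 0.0, 0.0, 0.0, 0.22]
        rs_c = [0.0, 0.0, 0.0, 0.0, 0.6, 0.6, 0.0, 0.0, 0.0, 0.22]
        ps = [0.001] * 10
        tables = {"A": self._table(rs_a, ps), "B": self._table(rs_b, ps),
                  "C": self._table(rs_c, ps)}
        sweep = genesets.threshold_sweep(tables, taus=[0.1, 0.2, 0.25, 0.3])
        # U = 6/1 below 0.25; undefined (no shared) at 0.25+ -> max defined U is 6
        assert sweep.table.loc[0.1, "U"] == pytest.approx(6.0)
        assert sweep.tau_star == 0.1
        # counts never increase as tau rises
        assert (sweep.table[["A", "B", "C"]].diff().dropna() <= 0).all().all()


class TestFisherOverlap:
    def test_observed_zero_overlap_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        p = genesets.fisher_overlap({"g0"}, {"g1"}, bg)[1]
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small(self):
        # overlap 3 of |A|=4, |B|=5 in N=10: exact tail by enumerating 5-subsets
        universe = list(range(10))
        A = set(range(4))
        count = 0
        total = 0
        for B in itertools.combinations(universe, 5):
            total += 1
            if len(A & set(B)) >= 3:
                count += 1
        bg = {f"g{i}" for i in universe}
        a = {f"g{i}" for i in A}
        b = {f"g{i}" for i in range(3)} | {f"g{i}" for i in (7, 8)}  # overlap 3
        k, p = genesets.fisher_overlap(a, b, bg)
        assert k == 3
        assert p == pytest.approx(count / total)

    def test_universe_violation_rejected(self):
        with pytest.raises(ValueError):
            genesets.fisher_overlap({"x"}, {"y"}, {"y"})


class TestChisqProportions:
    def test_equal_proportions_zero(self):
        stat, _ = genesets.chisq_proportions(10, 100, 10, 100)
        assert stat == pytest.approx(0.0)

    def test_symmetric_in_group_order(self):
        s1, p1 = genesets.chisq_proportions(30, 120, 15, 140)
        s2, p2 = genesets.chisq_proportions(15, 140, 30, 120)
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_zero_iff_equal_proportions(self):
        stat, _ = genesets.chisq_proportions(20, 80, 30, 120)  # both 0.25
        assert stat == pytest.approx(0.0)
        stat2, _ = genesets.chisq_proportions(21, 80, 30, 120)
        assert stat2 > 0

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            genesets.chisq_proportions(0, 10, 0, 10)


class TestResampleNull:
    def test_full_pool_degenerate(self):
        null, _ = genesets.resample_overlap_null(list("abcd"), 4, {"a", "b"}, B=10, seed=1)
        assert (null == 2).all()

    def test_disjoint_query_all_zero(self):
        null, _ = genesets.resample_overlap_null(list("abcd"), 2, {"x"}, B=10, seed=2)
        assert (null == 0).all()

    def test_converges_to_exhaustive_enumeration(self):
        pool = list("abcdefgh")
        query = {"a", "b", "c"}
        exact = {}
        subsets = list(itertools.combinations(pool, 3))
        for s in subsets:
            k = len(query & set(s))
            exact[k] = exact.get(k, 0) + 1
        exact_tail = sum(v for k, v in exact.items() if k >= 2) / len(subsets)
        null, p = genesets.resample_overlap_null(pool, 3, query, B=20000, seed=3,
                                                 observed=2)
        assert p == pytest.approx(exact_tail, abs=0.01)

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            genesets.resample_overlap_null(list("ab"), 3, {"a"}, B=5, seed=0)


class TestMatchByLength:
    def test_exact_length_twins_chosen(self):
        q = pd.Series({"q1": 100.0, "q2": 2000.0})
        c = pd.Series({"c1": 100.0, "c2": 2000.0, "c3": 555.0})
        m = genesets.match_by_length(q, c)
        assert m["q1"] == "c1" and m["q2"] == "c2"

    def test_insufficient_candidates_rejected(self):
        with pytest.raises(ValueError):
            genesets.match_by_length(pd.Series({"q": 1.0, "r": 2.0}),
                                     pd.Series({"c": 1.0}))

    def test_near_optimal_vs_assignment_oracle(self):
        rng = np.random.default_rng(61)
        q = pd.Series(rng.uniform(100, 10000, 6), index=[f"q{i}" for i in range(6)])
        c = pd.Series(rng.uniform(100, 10000, 10), index=[f"c{i}" for i in range(10)])
        m = genesets.match_by_length(q, c)
        assert len(set(m)) == 6  # 1:1, no replacement
        cost = sum(abs(np.log(q[k]) - np.log(c[v])) for k, v in m.items())
        D = np.abs(np.log(q.to_numpy())[:, None] - np.log(c.to_numpy())[None, :])
        rows, cols = linear_sum_assignment(D)
        optimal = D[rows, cols].sum()
        assert cost <= 2.0 * optimal + 1e-9  # documented greedy optimality gap

    def test_deterministic(self):
        q = pd.Series({"q1": 10.0, "q2": 20.0})
        c = pd.Series({"c2": 12.0, "c1": 12.0, "c3": 25.0})
        m1 = genesets.match_by_length(q, c)
        m2 = genesets.match_by_length(q, c)
        assert m1.equals(m2)
        assert m1["q1"] == "c1"  # tie on length broken by candidate id order


class TestOra:
    def test_query_term_attains_minimal_p(self):
        bg = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(8)}
        colls = {"self": set(query),
                 "half": {f"g{i}" for i in range(4)} | {f"g{i}" for i in range(30, 34)},
                 "other": {f"g{i}" for i in range(20, 28)}}
        out = genesets.ora_collections(query, colls, bg)
        assert out["p"].idxmin() == "self"

    def test_single_term_holm_equals_raw(self):
        bg = {f"g{i}" for i in range(20)}
        out = genesets.ora_collections({"g0", "g1"}, {"t": {"g0", "g5"}}, bg)
        assert out.loc["t", "p_holm"] == pytest.approx(out.loc["t", "p"])

    def test_holm_matches_brute_force_step_down(self):
        bg = {f"g{i}" for i in range(60)}
        rng = np.random.default_rng(62)
        query = set(rng.choice(sorted(bg), 15, replace=False))
        colls = {f"t{j}": set(rng.choice(sorted(bg), 10, replace=False))
                 for j in range(5)}
        out = genesets.ora_collections(query, colls, bg)
        raw = out["p"].to_numpy()
        m = len(raw)
        order = np.argsort(raw)
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx] * (m - rank))
            expected[idx] = min(running, 1.0)
        np.testing.assert_allclose(out["p_holm"].to_numpy(), expected)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            genesets.ora_collections(set(), {"t": {"a"}}, {"a"})
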