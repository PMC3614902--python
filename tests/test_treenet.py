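"""K2P distances, NJ trees, parsimony networks, strict-clock dating."""

import math

import numpy as np
import pytest

from haplogeo.haplotypes import HaplotypeMatrix, StepDistanceMatrix, pairwise_steps
from haplogeo.treenet import (
    SaturationError,
    bipartitions,
    k2p,
    midpoint_root,
    nj_bootstrap,
    nj_tree,
    parsimony_limit,
    parsimony_probability,
    strict_clock_age,
    tcs_network,
)
from haplogeo.synthdata import HPG_I, HPG_II, MU, SEQ_LENGTH


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p("ACGTACGT", "ACGTACGT") == 0.0

    def test_pure_transition_closed_form(self):
        # 1 transition in 100 sites: P=0.01, Q=0
        s1 = "A" * 100
        s2 = "G" + "A" * 99
        expect = -0.5 * math.log(1 - 0.02)
        assert k2p(s1, s2) == pytest.approx(expect, abs=1e-12)
        assert k2p(s1, s2) == pytest.approx(0.010101, abs=1e-6)

    def test_pure_transversion_closed_form(self):
        s1 = "A" * 100
        s2 = "C" + "A" * 99
        expect = -0.5 * math.log(0.99) - 0.25 * math.log(0.98)
        assert k2p(s1, s2) == pytest.approx(expect, abs=1e-12)
        assert k2p(s1, s2) == pytest.approx(0.010076, abs=1e-6)

    def test_gap_columns_excluded_pairwise(self):
        assert k2p("ACGT-A", "ACGTTA") == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p("AAAA", "GGGG")


from _treeutil import random_additive_matrix as _random_additive


class TestNeighborJoining:
    def test_three_taxa_three_point_solution(self):
        labels = ["a", "b", "c"]
        m = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree((labels, m))
        # three-point equations: la=1, lb=2, lc=3
        assert tree.distance("a", "b") == pytest.approx(3.0, abs=1e-9)
        assert tree.distance("a", "c") == pytest.approx(4.0, abs=1e-9)
        assert tree.distance("b", "c") == pytest.approx(5.0, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree((["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_additive_matrix_recovered_exactly(self, rng):
        """NJ reproduces topology and path lengths of random additive trees."""
        for _ in range(15):
            labels, m, clades = _random_additive(rng, int(rng.integers(5, 9)))
            tree = nj_tree((labels, m))
            ref = sorted(labels)[0]
            full = set(labels)
            want = set()
            for c in clades:
                side = c if ref not in c else frozenset(full - c)
                want.add(side)
            assert bipartitions(tree) >= want
            for i, a in enumerate(labels):
                for b in labels[i + 1 :]:
                    assert tree.distance(a, b) == pytest.approx(
                        m[labels.index(a), labels.index(b)], abs=1e-8
                    )

    def test_fixture_tree_separates_the_two_haplogroups(self, steps):
        tree = nj_tree(steps)
        assert frozenset(HPG_II) in bipartitions(tree)

    def test_midpoint_rooting_balances_deepest_leaves(self):
        labels = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0.0, 2.0, 8.0, 9.0],
                [2.0, 0.0, 8.0, 9.0],
                [8.0, 8.0, 0.0, 3.0],
                [9.0, 9.0, 3.0, 0.0],
            ]
        )
        tree = midpoint_root(nj_tree((labels, m)))
        depths = tree.depths()
        leaf_depth = {t.name: d for t, d in depths.items() if t.name in labels}
        deepest = max(leaf_depth.values())
        # the two sides of the root reach equally deep
        left, right = tree.root.clades
        lmax = max(leaf_depth[t.name] for t in left.get_terminals())
        rmax = max(leaf_depth[t.name] for t in right.get_terminals())
        assert lmax == pytest.approx(rmax, abs=1e-9)
        assert deepest == pytest.approx(9.0 / 2, abs=1e-9)


class TestBootstrap:
    def test_clean_two_clade_signal_gets_full_support(self):
        taxa = ["a1", "a2", "a3", "b1", "b2", "b3"]
        # 20 characters all splitting a* | b*
        states = []
        for t in taxa:
            states.append(tuple("A" if t.startswith("a") else "T" for _ in range(20)))
        # make rows distinct with 3 private suffix characters per taxon
        uniq = []
        for i, row in enumerate(states):
            tail = ["C"] * len(taxa)
            tail[i] = "G"
            uniq.append(row + tuple(tail))
        hm = HaplotypeMatrix(taxa, uniq)
        _, support = nj_bootstrap(hm, n_reps=100, seed=0)
        split = frozenset({"b1", "b2", "b3"})
        assert support[split] == pytest.approx(1.0)

    def test_deterministic_given_seed(self, char_matrix):
        _, s1 = nj_bootstrap(char_matrix, n_reps=50, seed=123)
        _, s2 = nj_bootstrap(char_matrix, n_reps=50, seed=123)
        assert s1 == s2

    def test_invalid_replicate_count(self, char_matrix):
        with pytest.raises(ValueError):
            nj_bootstrap(char_matrix, n_reps=0)


class TestParsimonyLimit:
    def test_extreme_probability_keeps_single_step_only(self):
        assert parsimony_limit(2106, p=0.999999) == 1

    def test_monotone_in_sequence_length(self):
        limits = [parsimony_limit(L) for L in (50, 200, 800, 2106)]
        assert limits == sorted(limits)
        assert limits[-1] > limits[0]

    def test_probability_decreases_with_steps(self):
        probs = [parsimony_probability(j, 500) for j in range(1, 8)]
        assert probs == sorted(probs, reverse=True)

    def test_monte_carlo_oracle_small_length(self, rng):
        """DP posterior matches direct simulation of the mutation model."""
        L, j = 40, 2
        b = j / (j + 1)
        hits_num = hits_den = 0
        for _ in range(40000):
            M = int(rng.geometric(1 - b)) - 1
            jj = ss = 0
            for _ in range(M):
                u = rng.random()
                pf = max(L - jj - ss, 0) / L
                pd = jj / L
                if u < pf:
                    jj += 1
                elif u < pf + pd:
                    if rng.random() < 1 / 3:
                        jj -= 1
                        ss += 1
                else:
                    jj += 1
                    ss -= 1
            if jj == j:
                hits_den += 1
                if M == j:
                    hits_num += 1
        mc = hits_num / hits_den
        assert parsimony_probability(j, L) == pytest.approx(mc, abs=0.01)


class TestNetwork:
    def test_two_haplotypes_one_step_single_edge(self):
        hm = HaplotypeMatrix(["a", "b"], [("A",), ("T",)])
        g = tcs_network(hm, seq_length=500)
        assert set(g.edges()) == {("a", "b")}

    def test_fixture_network_matches_published_topology(self, char_matrix):
        g = tcs_network(char_matrix, seq_length=SEQ_LENGTH)
        observed_edges = {
            frozenset(e) for e in g.edges() if not any(n.startswith("x") for n in e)
        }
        assert observed_edges == {
            frozenset(p) for p in [("A", "B"), ("A", "E"), ("A", "F"),
                                   ("B", "G"), ("D", "E"), ("D", "H")]
        }
        # C attaches through exactly one inferred intermediate
        inferred = [n for n, data in g.nodes(data=True) if data["inferred"]]
        assert len(inferred) == 1
        assert set(g.neighbors("C")) == set(inferred)
        assert set(g.neighbors(inferred[0])) == {"A", "C"}

    def test_fixture_hubs_are_the_ancestral_haplotypes(self, char_matrix):
        g = tcs_network(char_matrix, seq_length=SEQ_LENGTH)
        assert g.degree("A") >= 3
        assert g.degree("D") >= 2

    def test_every_edge_is_one_step(self, char_matrix):
        g = tcs_network(char_matrix, seq_length=SEQ_LENGTH)
        assert all(data["steps"] == 1 for _, _, data in g.edges(data=True))

    def test_path_lengths_match_step_distances_within_limit(self, char_matrix, steps):
        import networkx as nx

        g = tcs_network(char_matrix, seq_length=SEQ_LENGTH)
        for a in "ABCDEFGH":
            for b in "ABCDEFGH":
                if a < b and steps[a, b] <= 2:
                    assert nx.shortest_path_length(g, a, b) == steps[a, b]

    def test_disconnected_warns(self):
        hm = HaplotypeMatrix(
            ["a", "b"], [tuple("AAAAAAAA"), tuple("TTTTTTTT")]
        )
        with pytest.warns(UserWarning):
            g = tcs_network(hm, seq_length=10, limit=2)
        assert not g.has_edge("a", "b")


class TestStrictClock:
    def test_two_sequences_closed_form(self):
        hm = HaplotypeMatrix(["a", "b"], [("A", "A", "A"), ("T", "T", "A")])
        res = strict_clock_age(["a"], ["b"], hm, mu=1e-9, L=1000, n_boot=100, seed=0)
        assert res.age_myr == pytest.approx(2 / (2 * 1e-9 * 1000) / 1e6)

    def test_scales_inversely_with_rate_and_length(self, char_matrix):
        r1 = strict_clock_age(list(HPG_I), list(HPG_II), char_matrix, MU, 2106,
                              n_boot=10, seed=0)
        r2 = strict_clock_age(list(HPG_I), list(HPG_II), char_matrix, 2 * MU, 2106,
                              n_boot=10, seed=0)
        r3 = strict_clock_age(list(HPG_I), list(HPG_II), char_matrix, MU, 4212,
                              n_boot=10, seed=0)
        assert r2.age_myr == pytest.approx(r1.age_myr / 2)
        assert r3.age_myr == pytest.approx(r1.age_myr / 2)

    def test_overlapping_groups_rejected(self, char_matrix):
        with pytest.raises(ValueError):
            strict_clock_age(["A", "B"], ["B", "D"], char_matrix, MU, 2106)

    def test_simulated_clock_data_interval_coverage(self, rng):
        """Characters simulated on a star clock tree: the bootstrap interval
        covers the true age in most replicates."""
        mu, L, T = 1e-9, 2000, 2e6  # expected 8 steps between groups
        cover = 0
        reps = 30
        taxa = ["a1", "a2", "a3", "b1", "b2", "b3"]
        for _ in range(reps):
            lam = mu * L * T
            # two clades splitting at T: half of each lineage's mutations sit
            # on the shared stem branch, half are private to the tip
            stems = {"a": int(rng.poisson(lam / 2)), "b": int(rng.poisson(lam / 2))}
            private = {t: int(rng.poisson(lam / 2)) for t in taxa}
            for t in taxa:  # distinct rows require >= 1 private mutation
                while private[t] == 0:
                    private[t] = int(rng.poisson(lam / 2))
            total = sum(stems.values()) + sum(private.values())
            rows = {}
            pos = {"stem_a": 0, "stem_b": stems["a"]}
            offset = stems["a"] + stems["b"]
            for t in taxa:
                row = ["0"] * total
                g = t[0]
                start = 0 if g == "a" else stems["a"]
                for k in range(stems[g]):
                    row[start + k] = "1"
                for k in range(private[t]):
                    row[offset + k] = "1"
                offset += private[t]
                rows[t] = tuple(row)
            _ = pos
            hm = HaplotypeMatrix(list(rows), list(rows.values()))
            res = strict_clock_age(
                ["a1", "a2", "a3"], ["b1", "b2", "b3"], hm, mu, L,
                n_boot=200, seed=rng,
            )
            lo, hi = res.interval_myr
            cover += lo <= T / 1e6 <= hi
        assert cover / reps >= 0.8
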