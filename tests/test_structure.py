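"""Geography parsing, AMOVA components, SAMOVA search and Mantel test."""

import itertools
import math

import numpy as np
import pytest

from haplogeo.diversity import PopulationRecord
from haplogeo.haplotypes import StepDistanceMatrix
from haplogeo.structure import (
    amova,
    contiguity_graph,
    geo_matrix,
    great_circle,
    mantel,
    pairwise_phist,
    parse_dms,
    samova,
)
from haplogeo.synthdata import planted_partition_dataset


def _pop(code, counts, lon=90.0, lat=30.0):
    return PopulationRecord(code, "", lon, lat, 0.0, sum(counts.values()), counts)


def _dist(labels, m):
    return StepDistanceMatrix(labels, np.asarray(m))


class TestCoordinates:
    @pytest.mark.parametrize(
        "text,expected",
        [("90°00′", 90.0), ("91°06′", 91.1), ("86°24′", 86.4)],
    )
    def test_parse_single(self, text, expected):
        assert parse_dms(text) == pytest.approx(expected)

    def test_parse_pair(self):
        lon, lat = parse_dms("91°06′/30°29′")
        assert lon == pytest.approx(91.1)
        assert lat == pytest.approx(30.0 + 29.0 / 60.0)

    def test_malformed_raises(self):
        with pytest.raises(ValueError):
            parse_dms("north by northwest")

    def test_identical_points_zero(self):
        assert great_circle((91.1, 30.48), (91.1, 30.48)) == 0.0

    def test_antipodal_half_circumference(self):
        assert great_circle((0.0, 0.0), (180.0, 0.0)) == pytest.approx(
            math.pi * 6371.0, rel=1e-12
        )

    def test_against_law_of_cosines_oracle(self):
        a, b = (91.1, 30.4833), (91.433, 29.7)
        lon1, lat1 = map(math.radians, a)
        lon2, lat2 = map(math.radians, b)
        expect = 6371.0 * math.acos(
            math.sin(lat1) * math.sin(lat2)
            + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
        )
        assert great_circle(a, b) == pytest.approx(expect, rel=1e-9)

    def test_latitude_validation(self):
        with pytest.raises(ValueError):
            great_circle((0, 95), (0, 0))


def _amova_oracle(pops, d):
    """Explicit individual-level sums-of-squares Phi_ST."""
    ind, popid = [], []
    for k, p in enumerate(pops):
        for h, c in sorted(p.counts.items()):
            ind += [h] * c
            popid += [k] * c
    N, P = len(ind), len(pops)
    D2 = np.array([[d[ind[i], ind[j]] ** 2 for j in range(N)] for i in range(N)], float)
    sst = D2.sum() / (2 * N)
    ssw = 0.0
    for k in range(P):
        idx = [i for i in range(N) if popid[i] == k]
        ssw += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    sw = (sst - ssw, ssw)
    sigma_w = ssw / (N - P)
    ns = np.array([p.n for p in pops])
    nc = (N - (ns**2).sum() / N) / (P - 1)
    sigma_a = ((sst - ssw) / (P - 1) - sigma_w) / nc
    return sw, sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


class TestAmova:
    def test_matches_individual_level_oracle(self, rng):
        labels = ["a", "b", "c", "d"]
        for _ in range(10):
            m = np.triu(rng.integers(1, 6, size=(4, 4)), 1)
            m = m + m.T
            d = _dist(labels, m)
            pops = []
            for k in range(3):
                counts = {}
                for _ in range(int(rng.integers(4, 9))):
                    h = labels[int(rng.integers(4))]
                    counts[h] = counts.get(h, 0) + 1
                pops.append(_pop(f"P{k}", counts))
            res = amova(pops, d, None, n_perm=0)
            _, sa, sw, phi = _amova_oracle(pops, d)
            assert res.phi["F_ST"] == pytest.approx(phi, abs=1e-12)
            assert res.variance_components["a"] == pytest.approx(sa, abs=1e-12)
            assert res.variance_components["c"] == pytest.approx(sw, abs=1e-12)

    def test_identical_compositions_give_null_phi(self):
        d = _dist(["a", "b"], [[0, 2], [2, 0]])
        pops = [_pop(f"P{k}", {"a": 4, "b": 4}) for k in range(3)]
        res = amova(pops, d, None, n_perm=200, seed=0)
        # exactly equal compositions give a small negative variance estimate
        assert res.phi["F_ST"] <= 0
        assert abs(res.phi["F_ST"]) < 0.25
        assert res.p_values["F_ST"] > 0.5

    def test_private_fixed_haplotypes_give_phi_one(self):
        m = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        d = _dist(["a", "b", "c"], m)
        pops = [_pop(f"P{k}", {h: 8}) for k, h in enumerate("abc")]
        res = amova(pops, d, None, n_perm=100, seed=0)
        assert res.phi["F_ST"] == pytest.approx(1.0)
        assert res.p_values["F_ST"] < 0.05

    def test_relabeling_invariance(self, rng):
        labels = ["a", "b", "c"]
        m = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]])
        d = _dist(labels, m)
        pops = [
            _pop("P0", {"a": 5, "b": 3}),
            _pop("P1", {"b": 4, "c": 4}),
            _pop("P2", {"a": 2, "c": 6}),
        ]
        res1 = amova(pops, d, None, n_perm=0)
        res2 = amova(pops[::-1], d, None, n_perm=0)
        assert res1.phi["F_ST"] == pytest.approx(res2.phi["F_ST"], abs=1e-12)

    def test_degenerate_variance_rejected(self):
        d = _dist(["a"], [[0]])
        pops = [_pop("P0", {"a": 4}), _pop("P1", {"a": 4})]
        with pytest.raises(ValueError):
            amova(pops, d, None, n_perm=0)

    def test_two_level_components_sum_to_total(self, rng):
        labels = ["a", "b", "c", "d"]
        m = np.triu(rng.integers(1, 5, size=(4, 4)), 1)
        m = m + m.T
        d = _dist(labels, m)
        pops = []
        for k in range(4):
            counts = {}
            for _ in range(6):
                h = labels[int(rng.integers(4))]
                counts[h] = counts.get(h, 0) + 1
            pops.append(_pop(f"P{k}", counts))
        res = amova(pops, d, [["P0", "P1"], ["P2", "P3"]], n_perm=0)
        # F_ST consistency: (sigma_a + sigma_b) / total
        s = res.variance_components
        total = s["a"] + s["b"] + s["c"]
        assert res.phi["F_ST"] == pytest.approx((s["a"] + s["b"]) / total, abs=1e-12)


class TestPairwisePhist:
    def test_pairwise_agrees_with_amova_restricted_to_pair(self, rng):
        labels = ["a", "b", "c"]
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        d = _dist(labels, m)
        pops = [
            _pop("P0", {"a": 5, "b": 2}),
            _pop("P1", {"b": 6, "c": 2}),
            _pop("P2", {"a": 3, "c": 5}),
        ]
        codes, phi, p = pairwise_phist(pops, d, n_perm=200, seed=0)
        for i, j in itertools.combinations(range(3), 2):
            res = amova([pops[i], pops[j]], d, None, n_perm=0)
            assert phi[i, j] == pytest.approx(res.phi["F_ST"], abs=1e-12)

    def test_clone_composition_zero_and_fixed_one(self):
        d = _dist(["a", "b"], [[0, 2], [2, 0]])
        pops = [
            _pop("P0", {"a": 4, "b": 4}),
            _pop("P1", {"a": 4, "b": 4}),
            _pop("P2", {"a": 8}),
            _pop("P3", {"b": 8}),
        ]
        _, phi, _ = pairwise_phist(pops, d, n_perm=50, seed=1)
        assert phi[0, 1] <= 0 and abs(phi[0, 1]) < 0.25
        assert phi[2, 3] == pytest.approx(1.0)


class TestSamova:
    def test_planted_two_cluster_partition(self):
        pops, d, truth = planted_partition_dataset(2, within_rate=0.0, seed=3)
        res = samova(pops, d, 2, n_repetitions=3, n_steps=500, seed=7)
        assert {frozenset(g) for g in res.grouping} == {frozenset(g) for g in truth}
        assert res.F_CT == pytest.approx(1.0)

    def test_k_equal_to_populations_is_singleton_partition(self):
        pops, d, _ = planted_partition_dataset(2, pops_per_group=2, seed=0)
        res = samova(pops, d, K=len(pops), seed=0)
        assert sorted(len(g) for g in res.grouping) == [1, 1, 1, 1]

    def test_k_out_of_range(self):
        pops, d, _ = planted_partition_dataset(2, pops_per_group=2, seed=0)
        with pytest.raises(ValueError):
            samova(pops, d, 1)
        with pytest.raises(ValueError):
            samova(pops, d, 99)

    def test_matches_exhaustive_search_on_small_instance(self):
        pops, d, _ = planted_partition_dataset(2, pops_per_group=3,
                                               within_rate=0.2, seed=11)
        res = samova(pops, d, 2, n_repetitions=6, n_steps=600, seed=5)
        adj = contiguity_graph([p.lon for p in pops], [p.lat for p in pops])

        def connected(idx):
            idx = set(idx)
            seen = {next(iter(idx))}
            stack = list(seen)
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v in idx and v not in seen:
                        seen.add(v)
                        stack.append(v)
            return seen == idx

        best = -np.inf
        n = len(pops)
        for mask in range(1, 2 ** (n - 1)):
            g1 = [i for i in range(n) if mask >> i & 1]
            g2 = [i for i in range(n) if not mask >> i & 1]
            if not g2 or not connected(g1) or not connected(g2):
                continue
            grouping = [[pops[i].code for i in g1], [pops[i].code for i in g2]]
            val = amova(pops, d, grouping, n_perm=0).phi["F_CT"]
            best = max(best, val)
        assert res.F_CT == pytest.approx(best, abs=1e-9)


class TestMantel:
    @staticmethod
    def _sym(rng, n=7):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_self_correlation_is_one(self, rng):
        a = self._sym(rng)
        r, p = mantel(a, a.copy(), n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_negated_matrix_gives_minus_one(self, rng):
        a = self._sym(rng)
        r, _ = mantel(a, -a + 5.0, n_perm=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        a, b = self._sym(rng), self._sym(rng)
        r1, _ = mantel(a, b, n_perm=49, seed=3)
        r2, _ = mantel(2.0 * a + 1.0, 0.5 * b - 2.0, n_perm=49, seed=3)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_matrix_rejected(self, rng):
        a = self._sym(rng)
        with pytest.raises(ValueError):
            mantel(a, np.zeros_like(a), n_perm=9)


def test_geo_matrix_symmetric_nonnegative(rebuilt_pops):
    geo = geo_matrix(rebuilt_pops[:10])
    assert np.allclose(geo.km, geo.km.T)
    assert (geo.km >= 0).all()
    assert np.all(np.diag(geo.km) == 0)
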