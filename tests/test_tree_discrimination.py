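"""Clade-based species discrimination and neighbor-joining reconstruction."""

import numpy as np
import pytest

from halobarcode import (
    discrimination_rate,
    neighbor_joining,
    read_tree,
    split_set,
)
from halobarcode.errors import UndefinedDistanceError

from conftest import explicit_matrix

SPECIES6 = {
    "a1": "Sp a", "a2": "Sp a",
    "b1": "Sp b", "b2": "Sp b",
    "c1": "Sp c", "c2": "Sp c",
}


class TestDiscriminationRate:
    def test_all_species_fully_supported(self):
        t = read_tree(
            "(((a1:1,a2:1)1.0:1,(b1:1,b2:1)1.0:1)1.0:1,(c1:1,c2:1)1.0:1);",
            species_map=SPECIES6,
        )
        rate, per = discrimination_rate(t)
        assert rate == 100.0
        assert set(per.values()) == {"discriminated"}

    def test_one_paraphyletic_species(self):
        # Sp b's tips are split across the two sides: 2/3 discriminated
        t = read_tree(
            "(((a1:1,a2:1)1.0:1,b1:1)1.0:1,((c1:1,c2:1)1.0:1,b2:1)1.0:1);",
            species_map=SPECIES6,
        )
        rate, per = discrimination_rate(t)
        assert rate == pytest.approx(66.67, abs=0.01)
        assert per["Sp b"] == "not_discriminated"

    def test_cutoff_boundary_is_strict(self):
        t = read_tree(
            "(((a1:1,a2:1)0.90:1,(b1:1,b2:1)0.96:1)1.0:1,(c1:1,c2:1)0.95:1);",
            species_map=SPECIES6,
        )
        rate, per = discrimination_rate(t, support_cutoff=0.95)
        # 0.90 and exactly 0.95 fail ("over 95%" is strict); 0.96 passes
        assert per == {
            "Sp a": "not_discriminated",
            "Sp b": "discriminated",
            "Sp c": "not_discriminated",
        }
        assert rate == pytest.approx(100.0 / 3, abs=0.01)

    def test_monotone_in_cutoff(self):
        t = read_tree(
            "(((a1:1,a2:1)0.80:1,(b1:1,b2:1)0.99:1)1.0:1,(c1:1,c2:1)0.90:1);",
            species_map=SPECIES6,
        )
        rates = [discrimination_rate(t, c)[0] for c in (0.5, 0.85, 0.95, 0.995)]
        assert rates == sorted(rates, reverse=True)

    def test_singleton_handling(self):
        smap = {**SPECIES6, "d1": "Sp d"}
        t = read_tree(
            "((((a1:1,a2:1)1.0:1,(b1:1,b2:1)1.0:1)1.0:1,(c1:1,c2:1)1.0:1)1.0:1,d1:1);",
            species_map=smap,
        )
        rate_ex, per = discrimination_rate(t, singletons="exclude")
        assert per["Sp d"] == "singleton"
        assert rate_ex == 100.0
        rate_cf, _ = discrimination_rate(t, singletons="count-as-fail")
        assert rate_cf == 75.0

    def test_outgroup_pruned_before_evaluation(self):
        smap = {**SPECIES6, "out": "Outgroup sp"}
        t = read_tree(
            "((((a1:1,a2:1)1.0:1,(b1:1,b2:1)1.0:1)1.0:1,(c1:1,c2:1)1.0:1)1.0:1,out:9);",
            species_map=smap,
        )
        rate, per = discrimination_rate(t, outgroup=("out",))
        assert "Outgroup sp" not in per
        assert rate == 100.0

    def test_unrooted_tree_without_outgroup_refused(self):
        t = read_tree("((a1:1,a2:1)1.0:1,b1:1,b2:1);", species_map=SPECIES6)
        with pytest.raises(ValueError, match="root"):
            discrimination_rate(t)


def random_additive_tree(n_taxa, rng):
    """Random binary topology with positive branch lengths; returns
    (path-distance matrix, set of nontrivial splits)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency: node -> {neighbor: length}; grow by splitting random edges
    adj = {0: {}, 1: {}, 2: {}, 3: {}}
    nxt = 4
    center = 3
    for leaf in (0, 1, 2):
        w = rng.uniform(0.1, 1.0)
        adj[leaf][center] = w
        adj[center][leaf] = w
    leaves = [0, 1, 2]
    for leaf_i in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adj[u].pop(v)
        adj[v].pop(u)
        mid, newleaf = nxt, nxt + 1
        nxt += 2
        cut = rng.uniform(0.2, 0.8) * w
        adj[mid] = {u: cut, v: w - cut, newleaf: rng.uniform(0.1, 1.0)}
        adj[u][mid] = cut
        adj[v][mid] = w - cut
        adj[newleaf] = {mid: adj[mid][newleaf]}
        leaves.append(newleaf)

    name = {node: labels[i] for i, node in enumerate(leaves)}

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x].items():
                if y not in out:
                    out[y] = out[x] + w
                    stack.append(y)
        return out

    n = len(leaves)
    d = np.zeros((n, n))
    for i, li in enumerate(leaves):
        dd = dists_from(li)
        for j, lj in enumerate(leaves):
            d[i, j] = dd[lj]

    # splits: remove each internal edge, collect leaf side
    leafset = set(leaves)
    splits = set()
    anchor = name[min(leaves)]
    for u in adj:
        for v in adj[u]:
            if u < v and u not in leafset and v not in leafset:
                # side containing u when edge (u,v) removed
                seen = {u}
                stack = [u]
                while stack:
                    x = stack.pop()
                    for y in adj[x]:
                        if y != v and (x, y) != (u, v) and y not in seen:
                            if not (x == u and y == v):
                                seen.add(y)
                                stack.append(y)
                side = frozenset(name[l] for l in seen & leafset)
                other = frozenset(name[l] for l in leafset - seen)
                canon = side if anchor not in side else other
                if 2 <= len(canon) <= n - 2:
                    splits.add(canon)
    return [name[l] for l in leaves], d, splits


class TestNeighborJoining:
    def test_three_taxa_unique_topology(self):
        m = explicit_matrix([[0, 2, 3], [2, 0, 4], [3, 4, 0]], ids=["a", "b", "c"])
        t = neighbor_joining(m)
        assert sorted(t.tip_labels) == ["a", "b", "c"]
        assert split_set(t) == set()

    def test_recovers_additive_four_taxon_metric(self):
        # tree ((A,B),(C,D)) with all branches 1: d(A,B)=2, d(A,C)=3 ...
        v = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
            dtype=float,
        )
        t = neighbor_joining(explicit_matrix(v, ids=list("ABCD")))
        assert split_set(t) == {frozenset({"C", "D"})}

    @pytest.mark.parametrize("seed", range(15))
    def test_recovers_random_additive_metrics(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        labels, d, true_splits = random_additive_tree(n, rng)
        t = neighbor_joining(explicit_matrix(d, ids=labels))
        assert split_set(t) == true_splits

    def test_permuted_input_same_splits(self):
        rng = np.random.default_rng(77)
        labels, d, _ = random_additive_tree(7, rng)
        t1 = neighbor_joining(explicit_matrix(d, ids=labels))
        perm = rng.permutation(len(labels))
        d2 = d[np.ix_(perm, perm)]
        t2 = neighbor_joining(
            explicit_matrix(d2, ids=[labels[i] for i in perm])
        )
        assert split_set(t1) == split_set(t2)

    def test_undefined_entry_refused(self):
        v = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(UndefinedDistanceError):
            neighbor_joining(explicit_matrix(v))
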