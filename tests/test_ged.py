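"""Graph edit distance on label-fixed weighted graphs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwinet import (
    UNIT_COST,
    WEIGHT_DIFFERENCE,
    EditCostScheme,
    ged_fixed_nodes,
    ged_matrix,
)

INF = float("inf")


def brute_force_ged(edges1, edges2, nodes, scheme=WEIGHT_DIFFERENCE):
    """Minimum edit cost by exhaustive search over node bijections.

    Mapping a node to a differently-labeled node carries infinite relabel
    cost, so only the identity mapping can be optimal — this is the oracle
    the fixed-node decomposition must match.
    """
    best = INF
    for perm in itertools.permutations(nodes):
        mapping = dict(zip(nodes, perm))
        cost = sum(0.0 if a == b else INF for a, b in mapping.items())
        if cost == INF:
            continue
        mapped1 = {
            tuple(sorted((mapping[a], mapping[b]))): w
            for (a, b), w in edges1.items()
        }
        for key in set(mapped1) | set(edges2):
            if key in mapped1 and key in edges2:
                cost += scheme.substitute_cost(mapped1[key], edges2[key])
            elif key in mapped1:
                cost += scheme.insert_delete_cost(mapped1[key])
            else:
                cost += scheme.insert_delete_cost(edges2[key])
        best = min(best, cost)
    return best


def random_edge_map(rng, nodes, weights=(-1.0, -0.5, 0.5, 1.0), p_edge=0.5):
    return {
        pair: float(rng.choice(weights))
        for pair in itertools.combinations(nodes, 2)
        if rng.uniform() < p_edge
    }


class TestGedFixedNodes:
    def test_identical_graphs_distance_zero(self, rng):
        edges = random_edge_map(rng, ["a", "b", "c", "d"])
        res = ged_fixed_nodes(edges, dict(edges))
        assert res.distance == 0.0

    def test_worked_example(self):
        """{(a,b,0.5)} vs {(a,b,0.8),(b,c,-0.4)}: |0.5-0.8| + |-0.4| = 0.7."""
        res = ged_fixed_nodes(
            {("a", "b"): 0.5}, {("a", "b"): 0.8, ("b", "c"): -0.4}
        )
        assert res.distance == pytest.approx(0.7)
        assert res.n_substitutions == 1
        assert res.n_insertions == 1
        assert res.cost_substitutions == pytest.approx(0.3)
        assert res.distance == pytest.approx(
            res.cost_substitutions + res.cost_insertions + res.cost_deletions
        )

    def test_matches_brute_force_exhaustive_three_nodes(self):
        """All weighted graphs on 3 labeled nodes, both cost schemes."""
        nodes = ["a", "b", "c"]
        pairs = list(itertools.combinations(nodes, 2))
        weights = (-1.0, 0.5)
        graphs = []
        for included in itertools.product([None, *weights], repeat=3):
            graphs.append(
                {p: w for p, w in zip(pairs, included) if w is not None}
            )
        for scheme in (WEIGHT_DIFFERENCE, UNIT_COST):
            for g1, g2 in itertools.product(graphs, repeat=2):
                fast = ged_fixed_nodes(g1, g2, scheme).distance
                slow = brute_force_ged(g1, g2, nodes, scheme)
                assert fast == pytest.approx(slow), (g1, g2, scheme.name)

    def test_matches_brute_force_random_four_nodes(self, rng):
        nodes = ["a", "b", "c", "d"]
        for _ in range(200):
            g1 = random_edge_map(rng, nodes)
            g2 = random_edge_map(rng, nodes)
            fast = ged_fixed_nodes(g1, g2).distance
            assert fast == pytest.approx(brute_force_ged(g1, g2, nodes))

    def test_metric_axioms_on_random_triples(self, rng):
        """Symmetry, identity, triangle inequality over 1,000 random triples."""
        nodes = ["a", "b", "c", "d", "e"]
        for _ in range(1000):
            g1 = random_edge_map(rng, nodes, p_edge=0.4)
            g2 = random_edge_map(rng, nodes, p_edge=0.4)
            g3 = random_edge_map(rng, nodes, p_edge=0.4)
            d12 = ged_fixed_nodes(g1, g2).distance
            d21 = ged_fixed_nodes(g2, g1).distance
            d13 = ged_fixed_nodes(g1, g3).distance
            d23 = ged_fixed_nodes(g2, g3).distance
            assert d12 == pytest.approx(d21)
            assert d12 <= d13 + d23 + 1e-12
            if g1 == g2:
                assert d12 == 0.0

    def test_monotone_in_extra_edges(self, rng):
        nodes = ["a", "b", "c", "d"]
        g1 = random_edge_map(rng, nodes, p_edge=0.4)
        g2 = dict(g1)
        base = ged_fixed_nodes(g1, g2).distance
        for pair in itertools.combinations(nodes, 2):
            if pair not in g2:
                g2[pair] = 0.5
                new = ged_fixed_nodes(g1, g2).distance
                assert new >= base
                base = new

    def test_edge_listing_order_irrelevant(self, rng):
        edges = random_edge_map(rng, ["a", "b", "c", "d"])
        shuffled = dict(reversed(list(edges.items())))
        flipped = {(b, a): w for (a, b), w in edges.items()}
        other = random_edge_map(rng, ["a", "b", "c", "d"])
        assert (
            ged_fixed_nodes(edges, other).distance
            == ged_fixed_nodes(shuffled, other).distance
            == ged_fixed_nodes(flipped, other).distance
        )

    def test_invalid_scheme_rejected(self):
        broken = EditCostScheme(
            name="broken",
            substitute_cost=lambda a, b: abs(a) + abs(b),  # subst(w, w) != 0
            insert_delete_cost=lambda w: 1.0,
        )
        with pytest.raises(ValueError, match="substitute_cost"):
            ged_fixed_nodes({("a", "b"): 0.5}, {}, broken)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    weights=st.lists(
        st.floats(min_value=-1.0, max_value=1.0, allow_nan=False), min_size=3,
        max_size=3,
    )
)
def test_l1_identity_of_default_scheme(weights):
    """Default-scheme GED equals the L1 distance on edge-weight vectors."""
    pairs = [("a", "b"), ("b", "c"), ("a", "c")]
    g1 = {p: w for p, w in zip(pairs, weights) if w != 0}
    g2 = {pairs[0]: weights[1]} if weights[1] != 0 else {}
    vec1 = np.array([g1.get(p, 0.0) for p in pairs])
    vec2 = np.array([g2.get(p, 0.0) for p in pairs])
    assert ged_fixed_nodes(g1, g2).distance == pytest.approx(
        np.abs(vec1 - vec2).sum()
    )


class TestGedMatrix:
    def test_identical_graphs_all_zero(self, rng):
        edges = random_edge_map(rng, ["a", "b", "c"])
        graphs = {
            ("HC", "T0"): dict(edges),
            ("GWI_L", "T0"): dict(edges),
            ("GWI_H", "T0"): dict(edges),
        }
        mat, _ = ged_matrix(graphs, within_timepoint_only=True)
        assert np.allclose(mat.to_numpy(), 0.0)

    def test_symmetry(self, rng):
        graphs = {
            ("HC", "T0"): random_edge_map(rng, ["a", "b", "c", "d"]),
            ("GWI_L", "T0"): random_edge_map(rng, ["a", "b", "c", "d"]),
            ("GWI_H", "T0"): random_edge_map(rng, ["a", "b", "c", "d"]),
        }
        mat, _ = ged_matrix(graphs)
        arr = mat.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0.0)

    def test_cross_timepoint_pairs_excluded_by_default(self, rng):
        graphs = {
            ("HC", "T0"): random_edge_map(rng, ["a", "b", "c"]),
            ("HC", "T1"): random_edge_map(rng, ["a", "b", "c"]),
            ("GWI_L", "T0"): random_edge_map(rng, ["a", "b", "c"]),
        }
        mat, results = ged_matrix(graphs, within_timepoint_only=True)
        assert np.isnan(mat.loc["HC@T0", "HC@T1"])
        assert not np.isnan(mat.loc["HC@T0", "GWI_L@T0"])
        mat_all, _ = ged_matrix(graphs, within_timepoint_only=False)
        assert not np.isnan(mat_all.loc["HC@T0", "HC@T1"])
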