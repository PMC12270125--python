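import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qnmladder import (
    LADDER_LEVELS,
    SignedAdjacency,
    SignedDigraph,
    WebSpec,
    apply_threshold,
    build_adjacency,
    generate_foodweb,
    ladder,
    link_counts,
    mass_balance,
    to_signed_digraph,
)


@pytest.fixture
def toy_adj(toy_web):
    return build_adjacency(toy_web, mass_balance(toy_web))


def adj_from(strength, names=None):
    strength = np.asarray(strength, float)
    if names is None:
        names = tuple(f"g{i}" for i in range(strength.shape[0]))
    return SignedAdjacency(elements=tuple(names), strength=strength)


class TestBuildAdjacency:
    def test_toy_strengths(self, toy_adj):
        # DC − m2prop = 1.0 − 0.1; catch share − fprop = 1.0 − 0.25
        i, j = toy_adj.index("Phyto"), toy_adj.index("Fish")
        assert toy_adj.strength[i, j] == pytest.approx(0.9)
        assert toy_adj.strength[j, toy_adj.index("Fleet")] == pytest.approx(0.75)

    def test_absent_pair_is_zero(self, toy_adj):
        assert toy_adj.strength[toy_adj.index("Detritus"), toy_adj.index("Fish")] == 0.0

    def test_mortality_dominated_pair_negative(self):
        # a rare prey: 6% of the diet but 60% of the prey's mortality
        from qnmladder import FoodWeb, FunctionalGroup, Role
        from conftest import make_web

        groups = [
            FunctionalGroup("X", Role.PRODUCER, biomass=0.1, pb=10),
            FunctionalGroup("Y", Role.PRODUCER, biomass=100, pb=10),
            FunctionalGroup("Pred", Role.CONSUMER, biomass=1, pb=2, qb=10),
            FunctionalGroup("Detritus", Role.DETRITUS, biomass=5),
            FunctionalGroup("Fleet", Role.FLEET),
        ]
        diet = np.zeros((5, 5))
        diet[0, 2], diet[1, 2] = 0.06, 0.94
        web = make_web(groups, diet, [0, 0, 0.5, 0, 0])
        adj = build_adjacency(web, mass_balance(web))
        # m2prop(X, Pred) = (1·10·0.06 / 0.1) / 10 = 0.6 → v = 0.06 − 0.6
        assert adj.strength[0, 2] == pytest.approx(-0.54)

    def test_diagonal_zero(self, toy_adj):
        assert np.all(np.diag(toy_adj.strength) == 0.0)

    def test_strengths_bounded(self):
        web = generate_foodweb(WebSpec(n_groups=15, n_trophic_levels=3, seed=4))
        adj = build_adjacency(web, mass_balance(web))
        assert np.all(np.abs(adj.strength) <= 1 + 1e-9)


class TestThreshold:
    def test_boundary_value_retained(self):
        adj = adj_from([[0, 0.10], [0, 0]])
        out = apply_threshold(adj, 0.10)
        assert out.strength[0, 1] == 0.10  # "above or equal" is retained

    def test_below_boundary_removed(self):
        adj = adj_from([[0, -0.05], [0, 0]])
        assert apply_threshold(adj, 0.10).strength[0, 1] == 0.0

    def test_strong_link_survives_topmost_level(self):
        adj = adj_from([[0, 0.9], [0, 0]])
        assert apply_threshold(adj, 0.50).strength[0, 1] == 0.9

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        adj = adj_from(rng.uniform(-1, 1, (6, 6)))
        once = apply_threshold(adj, 0.3)
        twice = apply_threshold(once, 0.3)
        assert np.array_equal(once.strength, twice.strength)

    def test_bad_level_rejected(self, toy_adj):
        with pytest.raises(ValueError):
            apply_threshold(toy_adj, 1.0)


class TestLinkCounts:
    def test_three_node_chain(self, chain_web):
        adj = build_adjacency(chain_web, mass_balance(chain_web))
        # drop fleet/detritus noise: chain pairs plus Predator→Fleet
        assert link_counts(adj, "Phyto") == (0, 1, 1)
        assert link_counts(adj, "Herbivore") == (1, 1, 2)
        assert link_counts(adj, "Predator") == (1, 1, 2)  # + fleet link

    def test_unknown_element(self, toy_adj):
        with pytest.raises(KeyError):
            link_counts(toy_adj, "Kraken")

    def test_monotone_along_ladder(self):
        web = generate_foodweb(WebSpec(n_groups=15, n_trophic_levels=4, seed=9))
        adj = build_adjacency(web, mass_balance(web))
        for element in adj.elements:
            prev = None
            for lv in LADDER_LEVELS:
                c = link_counts(apply_threshold(adj, lv), element)
                if prev is not None:
                    assert c.inward <= prev.inward
                    assert c.outward <= prev.outward
                prev = c


class TestSignedDigraph:
    def test_single_pair_expansion(self):
        dg = to_signed_digraph(adj_from([[0, 0.9], [0, 0]], names=("Phyto", "Fish")))
        assert dg.edges == {("Phyto", "Fish", 1), ("Fish", "Phyto", -1)}
        assert dg.n == 2  # both nodes carry implicit negative self-loops
        S = dg.sign_matrix()
        assert S[1, 0] == 1 and S[0, 1] == -1
        assert S[0, 0] == -1 and S[1, 1] == -1

    def test_empty_adjacency_keeps_nodes(self):
        dg = to_signed_digraph(adj_from(np.zeros((3, 3))))
        assert dg.n == 3 and len(dg.edges) == 0
        assert np.array_equal(dg.sign_matrix(), -np.eye(3, dtype=int))

    def test_negative_strength_same_expansion(self):
        pos = to_signed_digraph(adj_from([[0, 0.4], [0, 0]]))
        neg = to_signed_digraph(adj_from([[0, -0.4], [0, 0]]))
        assert pos.edges == neg.edges

    def test_edge_count_conservation(self):
        web = generate_foodweb(WebSpec(n_groups=15, n_trophic_levels=3, seed=2))
        adj = build_adjacency(web, mass_balance(web))
        dg = to_signed_digraph(adj)
        assert len(dg.edges) == 2 * np.count_nonzero(adj.strength)

    def test_edgelist_round_trip(self, tmp_path, toy_adj):
        dg = to_signed_digraph(toy_adj)
        path = tmp_path / "graph.txt"
        dg.to_edgelist(path)
        back = SignedDigraph.from_edgelist(path)
        assert back.nodes == dg.nodes and back.edges == dg.edges

    def test_adjacency_csv_round_trip(self, tmp_path, toy_adj):
        path = tmp_path / "adj.csv"
        toy_adj.to_csv(path)
        back = SignedAdjacency.from_csv(path)
        assert back.elements == toy_adj.elements
        assert np.allclose(back.strength, toy_adj.strength)


class TestLadder:
    def test_toy_ladder_pair_counts(self):
        # strengths {0.9, 0.75, 0.15}: the 0.15 pair dies at level 0.2
        strength = np.zeros((4, 4))
        strength[0, 1], strength[1, 2], strength[2, 3] = 0.9, 0.75, 0.15
        graphs = ladder(adj_from(strength))
        assert [g.n_feeding_pairs() for g in graphs] == [3, 3, 2, 2, 2, 2]

    def test_all_strong_links_identical_graphs(self):
        strength = np.zeros((3, 3))
        strength[0, 1], strength[1, 2] = 0.8, 0.6
        graphs = ladder(adj_from(strength))
        assert all(g.edges == graphs[0].edges for g in graphs)

    def test_nested_edge_sets(self):
        web = generate_foodweb(WebSpec(n_groups=15, n_trophic_levels=4, seed=8))
        adj = build_adjacency(web, mass_balance(web))
        graphs = ladder(adj)
        for a, b in zip(graphs, graphs[1:]):
            assert b.edges <= a.edges

    def test_requires_level_zero(self, toy_adj):
        with pytest.raises(ValueError):
            ladder(apply_threshold(toy_adj, 0.2))


@settings(max_examples=30, deadline=None)
@given(
    strength=st.lists(
        st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=9, max_size=9
    ),
    level=st.sampled_from(LADDER_LEVELS),
)
def test_threshold_property(strength, level):
    adj = adj_from(np.array(strength).reshape(3, 3) * (1 - np.eye(3)))
    out = apply_threshold(adj, level)
    kept = out.strength[out.strength != 0]
    assert np.all(np.abs(kept) >= level)
    again = apply_threshold(out, level)
    assert np.array_equal(out.strength, again.strength)
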