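"""EMI score components against the published worked example, closed forms
and independent brute-force oracles."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from eminet import (
    EmiConfig,
    Network,
    analytic_family,
    emi_score,
    interactive_entropy,
    multiset_entropy,
    mutual_power,
    neighbors,
    overlap_pair_network,
    structural_entropy,
    toy_network,
)
from eminet.entropy_centrality import NotApplicableError, UndefinedEntropyError
from eminet.synthetic_networks import GeneratorSpec, random_network


def naive_entropy(values, base=10.0):
    """Independent oracle: direct -sum p log p with explicit normalisation."""
    total = sum(v for v in values if v > 0)
    ps = [v / total for v in values if v > 0 and v / total > 0]
    return -sum(p * math.log(p) / math.log(base) for p in ps)


class TestMultisetEntropy:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 1, 1], math.log10(3)),     # uniform over 3
            ([1, 1, 0], math.log10(2)),     # 0·log0 = 0 convention
            ([5], 0.0),                     # single outcome
            ([2, 3], 0.4 * math.log10(2.5) + 0.6 * math.log10(5 / 3)),
        ],
    )
    def test_known_values(self, values, expected):
        assert multiset_entropy(values) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedEntropyError):
            multiset_entropy([0, 0, 0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            multiset_entropy([1, -1])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 100, allow_nan=False), min_size=1,
                        max_size=30).filter(lambda v: sum(v) > 0),
        base=st.sampled_from([2.0, 10.0, math.e]),
    )
    def test_agrees_with_naive_oracle(self, values, base):
        assert multiset_entropy(values, base) == pytest.approx(
            naive_entropy(values, base), abs=1e-12
        )


class TestStructuralEntropy:
    def test_toy_node_a_matches_published(self, toy):
        s_in, s_out, s = structural_entropy(toy, "a")
        assert s_in == pytest.approx(0.47712, abs=1e-4)
        assert s_out == pytest.approx(0.30103, abs=1e-4)
        assert round(s, 4) == 0.7782

    def test_toy_node_b_matches_published(self, toy):
        _, _, s = structural_entropy(toy, "b")
        assert round(s, 4) == 0.5775

    def test_undirected_star_center_closed_form(self):
        for k in (3, 5, 9):
            net = analytic_family("star", k + 1)
            s_in, s_out, s = structural_entropy(net, "n0")
            assert s_in is None and s_out is None
            assert s == pytest.approx(math.log10(k), abs=1e-12)

    def test_isolated_node_scores_zero(self):
        net = Network(directed=True, weighted=True)
        net.add_node("x")
        assert structural_entropy(net, "x")[2] == 0.0


class TestInteractiveEntropy:
    def test_toy_node_a_matches_published(self, toy):
        i_in, i_out, i = interactive_entropy(toy, "a")
        assert i_in == pytest.approx(naive_entropy([1, 2, 4]), abs=1e-12)
        assert i_out == pytest.approx(naive_entropy([2, 3]), abs=1e-12)
        assert round(i, 4) == 0.7073

    def test_toy_node_c_matches_published(self, toy):
        assert round(interactive_entropy(toy, "c")[2], 4) == 0.5040

    def test_unweighted_network_rejected(self):
        net = Network(directed=True, weighted=False)
        net.add_edge("a", "b")
        with pytest.raises(NotApplicableError):
            interactive_entropy(net, "a")

    def test_unit_weights_make_interactive_equal_structural(self):
        net = random_network(
            GeneratorSpec(n=15, p=0.25, directed=True, weight_range=(1, 1),
                          seed=3)
        )
        cfg = EmiConfig()
        for v in net.nodes:
            assert interactive_entropy(net, v, cfg)[2] == pytest.approx(
                structural_entropy(net, v, cfg)[2], abs=1e-12
            )


def naive_mutual_power(net, v, base=10.0):
    """Independent oracle: literal per-pair evaluation of the penalty."""
    n_v = neighbors(net, v)
    total = 0.0
    for j in n_v:
        n_j = neighbors(net, j)
        c = len(n_v & n_j)
        if c:
            joint = len(n_v) + len(n_j)
            total += (c / joint) * math.log((joint - c) / joint, base)
    return total


class TestMutualPower:
    def test_toy_values_match_published(self, toy):
        assert round(mutual_power(toy, "a"), 5) == -0.03876
        assert round(mutual_power(toy, "b"), 5) == -0.05062
        assert round(mutual_power(toy, "c"), 5) == -0.05062
        assert mutual_power(toy, "d") == 0.0

    def test_triangle_closed_form(self, triangle):
        # each neighbor pair shares exactly the third node:
        # 2 * (1/4) * log10(3/4)
        expected = 2 * 0.25 * math.log10(0.75)
        for v in triangle.nodes:
            assert mutual_power(triangle, v) == pytest.approx(
                expected, abs=1e-12
            )
        assert expected == pytest.approx(-0.062470, abs=1e-6)

    def test_nonpositive_and_oracle_on_random_graphs(self):
        for seed in range(5):
            net = random_network(
                GeneratorSpec(n=18, p=0.25, directed=bool(seed % 2), seed=seed)
            )
            for v in net.nodes:
                mi = mutual_power(net, v)
                assert mi <= 0
                assert mi == pytest.approx(naive_mutual_power(net, v),
                                           abs=1e-12)

    def test_zero_iff_no_shared_neighbors(self):
        # path graph: adjacent nodes never share a neighbor
        net = analytic_family("path", 6)
        for v in net.nodes:
            assert mutual_power(net, v) == 0.0

    def test_adding_shared_neighbor_decreases_mi(self):
        prev = 0.0
        for shared in range(0, 6):
            net = overlap_pair_network(shared, private_a=3, private_b=3)
            mi = mutual_power(net, "hub_a")
            if shared == 0:
                assert mi == 0.0
            else:
                assert mi < prev
            prev = mi


class TestEmiScore:
    def test_toy_strict_matches_published_rows(self, toy):
        scores = {r.node: r for r in emi_score(toy)}
        assert round(scores["a"].K, 4) == pytest.approx(1.4467, abs=1e-4)
        assert scores["b"].K == pytest.approx(1.10648, abs=5e-5)
        assert scores["c"].K == pytest.approx(1.03088, abs=5e-5)
        # strict mode: the degree-one node has zero entropies
        assert scores["d"].S == 0.0 and scores["d"].I == 0.0

    def test_toy_ranking_order(self, toy):
        order = [r.node for r in emi_score(toy)]
        assert order == ["a", "b", "c", "d"]
        compat = [r.node for r in
                  emi_score(toy, EmiConfig(compat_single_neighbor=True))]
        assert compat == ["a", "b", "c", "d"]

    def test_compat_mode_reproduces_degree_one_row(self, toy):
        scores = {r.node: r
                  for r in emi_score(toy, EmiConfig(compat_single_neighbor=True))}
        assert round(scores["d"].S, 4) == 0.3010
        assert round(scores["d"].I, 4) == 0.2966
        assert scores["d"].K == pytest.approx(0.59760, abs=5e-5)

    def test_single_edge_strict_scores_zero(self):
        net = Network(directed=True, weighted=True)
        net.add_edge("u", "v", 1)
        scores = {r.node: r.K for r in emi_score(net)}
        assert scores == {"u": 0.0, "v": 0.0}

    def test_entropy_bounds(self):
        """0 <= each entropy component <= log10(|N_v|)."""
        for seed in range(4):
            net = random_network(
                GeneratorSpec(n=20, p=0.2, directed=True,
                              weight_range=(1, 9), seed=seed)
            )
            for r in emi_score(net):
                k = len(neighbors(net, r.node))
                bound = math.log10(k) + 1e-12 if k else 1e-12
                for comp in (r.S_in, r.S_out, r.I_in, r.I_out):
                    assert 0 <= comp <= bound

    def test_unit_weight_consistency_with_unweighted_ranking(self):
        """With all weights 1, K(weighted) = 2*S + MI and the induced
        ranking equals the unweighted ranking."""
        netw = random_network(
            GeneratorSpec(n=16, p=0.25, directed=True, weight_range=(1, 1),
                          seed=11)
        )
        netu = Network(directed=True, weighted=False)
        for (u, v), _ in netw.edges.items():
            netu.add_edge(u, v)
        sw = emi_score(netw)
        su = {r.node: r for r in emi_score(netu)}
        for r in sw:
            assert r.K == pytest.approx(2 * r.S + r.MI, abs=1e-12)
            assert r.K == pytest.approx(su[r.node].K + r.S, abs=1e-12)

    def test_complete_graph_symmetry(self):
        k5 = analytic_family("complete", 5)
        ks = [r.K for r in emi_score(k5)]
        assert max(ks) - min(ks) < 1e-12

    def test_isolated_node_gets_zero_not_error(self):
        net = Network(directed=True, weighted=True)
        net.add_edge("a", "b", 2)
        net.add_node("loner")
        scores = {r.node: r.K for r in emi_score(net)}
        assert scores["loner"] == 0.0

    def test_configurable_log_base(self, toy):
        s2 = {r.node: r.S for r in emi_score(toy, EmiConfig(log_base=2.0))}
        s10 = {r.node: r.S for r in emi_score(toy)}
        ratio = math.log(10) / math.log(2)
        for v in s10:
            assert s2[v] == pytest.approx(s10[v] * ratio, abs=1e-12)

    def test_mi_pair_multiplicity_expert_option(self):
        # with every common-neighbor count <= 1 both readings coincide
        net = toy_network()
        a = mutual_power(net, "a", EmiConfig())
        b = mutual_power(net, "a", EmiConfig(mi_pair_multiplicity=True))
        assert a == b
        # with a 2-node overlap they differ by the multiplicity factor
        ov = overlap_pair_network(2, 1, 1)
        strict = mutual_power(ov, "hub_a", EmiConfig())
        mult = mutual_power(ov, "hub_a", EmiConfig(mi_pair_multiplicity=True))
        assert mult < strict < 0
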