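"""Module detection, zi/pi roles and shared-node statistics against
exhaustive and brute-force oracles."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import random_signed_network
from rivernet.inference import InferenceConfig, infer_network
from rivernet.io import CoNetwork
from rivernet.modules import (
    ModulePartition,
    categorize,
    classify_roles,
    detect_modules,
    keystone_nodes,
    modularity_of,
    module_profiles,
    role_census,
    shared_nodes,
    venn_percentage,
)
from rivernet.preprocess import filter_taxa
from rivernet.synth import PlantedDesign, generate_planted_counts


# -------------------------------------------------------------- oracles
def all_partitions(items):
    """Every set partition of `items` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_formula(g: nx.Graph, communities) -> float:
    """Q = sum_c [ L_c/L - (d_c / 2L)^2 ], computed from scratch."""
    L = g.number_of_edges()
    q = 0.0
    for c in communities:
        cset = set(c)
        l_c = sum(1 for u, v in g.edges if u in cset and v in cset)
        d_c = sum(g.degree(u) for u in cset)
        q += l_c / L - (d_c / (2 * L)) ** 2
    return q


class TestDetectModules:
    def test_two_triangles_exhaustive_optimum(self, two_triangles):
        part = detect_modules(two_triangles)
        assert part.n_modules == 2
        assert part.modularity == pytest.approx(0.5, abs=1e-12)
        best = max(
            modularity_formula(two_triangles.graph, p)
            for p in all_partitions(sorted(two_triangles.graph.nodes))
        )
        assert part.modularity == pytest.approx(best, abs=1e-12)

    def test_complete_graph_single_module(self):
        g = nx.complete_graph(5)
        net = CoNetwork(nx.Graph([(str(u), str(v)) for u, v in g.edges]))
        part = detect_modules(net)
        assert part.n_modules == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_direct_recomputation(self):
        net = random_signed_network(25, 0.15, seed=2)
        part = detect_modules(net)
        assert part.modularity == pytest.approx(
            modularity_of(net, part.assignment), abs=1e-12)
        groups = {}
        for node, m in part.assignment.items():
            groups.setdefault(m, []).append(node)
        assert part.modularity == pytest.approx(
            modularity_formula(net.graph, groups.values()), abs=1e-12)

    def test_planted_blocks_recovered(self):
        matrix = generate_planted_counts(PlantedDesign(seed=0))
        net = infer_network(filter_taxa(matrix, 30), InferenceConfig(seed=1, n_permutations=500))
        part = detect_modules(net)
        member = matrix.attrs["block_membership"]
        nodes = list(net.graph.nodes)
        ari = adjusted_rand_score(
            [member[n] for n in nodes], [part.assignment[n] for n in nodes])
        assert ari >= 0.8

    def test_deterministic(self, two_triangles):
        a = detect_modules(two_triangles)
        b = detect_modules(two_triangles)
        assert a.assignment == b.assignment


class TestClassifyRoles:
    def test_all_internal_links_pi_zero(self, two_triangles):
        part = detect_modules(two_triangles)
        roles = classify_roles(two_triangles, part)
        assert (roles["pi"] == 0).all()

    def test_even_split_pi_half(self):
        g = nx.Graph()
        # hub with 4 links split evenly over two modules
        for x in ["a1", "a2", "b1", "b2"]:
            g.add_edge("hub", x)
        g.add_edge("a1", "a2")
        g.add_edge("b1", "b2")
        net = CoNetwork(g)
        part = ModulePartition({"hub": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}, 0.0, 2)
        roles = classify_roles(net, part)
        assert roles.loc["hub", "pi"] == pytest.approx(0.5)

    def test_equal_within_degrees_zi_zero(self, triangle_net):
        part = ModulePartition({"a": 0, "b": 0, "c": 0}, 0.0, 1)
        roles = classify_roles(triangle_net, part)
        assert (roles["zi"] == 0).all()
        assert (roles["category"] == "peripheral").all()

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        net = random_signed_network(20, 0.25, seed=seed)
        part = detect_modules(net)
        roles = classify_roles(net, part)
        g, assign = net.graph, part.assignment
        for node in g.nodes:
            own = assign[node]
            members = [n for n in g.nodes if assign[n] == own]
            within = {n: sum(1 for nb in g.neighbors(n) if assign[nb] == own)
                      for n in members}
            mu, sd = np.mean(list(within.values())), np.std(list(within.values()))
            zi = (within[node] - mu) / sd if sd > 0 else 0.0
            k = g.degree(node)
            per_mod = {}
            for nb in g.neighbors(node):
                per_mod[assign[nb]] = per_mod.get(assign[nb], 0) + 1
            pi = 1.0 - sum((c / k) ** 2 for c in per_mod.values())
            assert roles.loc[node, "zi"] == pytest.approx(zi, abs=1e-12)
            assert roles.loc[node, "pi"] == pytest.approx(pi, abs=1e-12)

    def test_boundary_values_fall_to_lower_category(self):
        assert categorize(2.5, 0.62) == "peripheral"
        assert categorize(2.5, 0.7) == "connector"
        assert categorize(3.0, 0.62) == "module hub"
        assert categorize(3.0, 0.7) == "network hub"

    def test_exact_pi_boundary_node_is_not_connector(self):
        # 10 links split 5/3/2 across three modules: pi = 1 - 0.38 = 0.62
        g = nx.Graph()
        for i in range(5):
            g.add_edge("hub", f"a{i}")
        for i in range(3):
            g.add_edge("hub", f"b{i}")
        for i in range(2):
            g.add_edge("hub", f"c{i}")
        assign = {"hub": 0}
        assign.update({f"a{i}": 0 for i in range(5)})
        assign.update({f"b{i}": 1 for i in range(3)})
        assign.update({f"c{i}": 2 for i in range(2)})
        roles = classify_roles(CoNetwork(g), ModulePartition(assign, 0.0, 3))
        assert roles.loc["hub", "pi"] == pytest.approx(0.62, abs=1e-12)
        assert roles.loc["hub", "category"] != "connector"

    def test_permutation_equivariance(self):
        net = random_signed_network(15, 0.3, seed=7)
        part = detect_modules(net)
        roles = classify_roles(net, part)
        mapping = {n: f"z{n}" for n in net.graph.nodes}
        net2 = CoNetwork(nx.relabel_nodes(net.graph, mapping))
        part2 = ModulePartition({mapping[n]: m for n, m in part.assignment.items()},
                                part.modularity, part.n_modules)
        roles2 = classify_roles(net2, part2)
        for n in net.graph.nodes:
            assert roles.loc[n, "zi"] == pytest.approx(roles2.loc[mapping[n], "zi"])
            assert roles.loc[n, "category"] == roles2.loc[mapping[n], "category"]


class TestRoleCensus:
    def test_fractions_sum_to_one(self):
        net = random_signed_network(20, 0.2, seed=1)
        roles = classify_roles(net, detect_modules(net))
        census = role_census(roles)
        assert census.sum() == pytest.approx(1.0)

    def test_all_peripheral_toy(self, triangle_net):
        part = ModulePartition({"a": 0, "b": 0, "c": 0}, 0.0, 1)
        census = role_census(classify_roles(triangle_net, part))
        assert census["peripheral"] == 1.0

    def test_forced_connector_fraction(self):
        """20-node network built so exactly one node splits links 50/50."""
        g = nx.Graph()
        for i in range(9):
            g.add_edge(f"a{i}", f"a{(i + 1) % 9}")
        for i in range(9):
            g.add_edge(f"b{i}", f"b{(i + 1) % 9}")
        g.add_edge("bridge", "a0")
        g.add_edge("bridge", "b0")
        assign = {f"a{i}": 0 for i in range(9)}
        assign.update({f"b{i}": 1 for i in range(9)})
        assign["bridge"] = 0
        roles = classify_roles(CoNetwork(g), ModulePartition(assign, 0.0, 2))
        assert roles.loc["bridge", "pi"] == pytest.approx(0.5)
        census = role_census(roles)
        assert census["peripheral"] == 1.0  # pi 0.5 < 0.62: still peripheral
        assert keystone_nodes(roles) == []


class TestSharedNodes:
    def test_identical_networks(self, triangle_net):
        out = shared_nodes(triangle_net, triangle_net)
        assert out["shared_pct"] == 100.0

    def test_disjoint_networks(self, triangle_net, two_triangles):
        g = nx.Graph()
        g.add_edge("x", "y")
        out = shared_nodes(triangle_net, CoNetwork(g))
        assert out["shared_pct"] == 0.0 and out["shared"] == 0

    def test_reported_venn_percentages(self):
        """Printed node counts reproduce the reported shared percentages."""
        assert venn_percentage(260, 1010, 123) == 10.7
        assert venn_percentage(257, 534, 72) == 10.0
        assert venn_percentage(317, 524, 99) == 13.3


class TestModuleProfiles:
    def test_single_module_no_inter_edges(self, triangle_net):
        part = ModulePartition({"a": 0, "b": 0, "c": 0}, 0.0, 1)
        prof = module_profiles(triangle_net, part)
        assert prof.loc[0, "inter_edges"] == 0
        assert prof.loc[0, "intra_positive"] == 3

    def test_major_module_threshold(self):
        net = random_signed_network(30, 0.3, seed=4)
        part = detect_modules(net)
        prof = module_profiles(net, part)
        tn = net.n_nodes
        for _, row in prof.iterrows():
            assert row["is_major"] == (row["size"] > 0.05 * tn)

    def test_edge_counts_partition_total(self):
        net = random_signed_network(25, 0.2, seed=9)
        part = detect_modules(net)
        prof = module_profiles(net, part)
        intra = (prof["intra_positive"] + prof["intra_negative"]).sum()
        inter_once = prof["inter_edges"].sum() / 2  # each inter edge seen from both sides
        assert intra + inter_once == net.n_edges
        assert prof["size"].sum() == net.n_nodes

    def test_planted_phylum_purity(self):
        matrix = generate_planted_counts(PlantedDesign(seed=0))
        net = infer_network(filter_taxa(matrix, 30), InferenceConfig(seed=1, n_permutations=500))
        part = detect_modules(net)
        prof = module_profiles(net, part)
        major = prof[prof["is_major"]]
        assert len(major) >= 2
        for _, row in major.iterrows():
            assert row["composition"][row["top_phylum"]] >= 0.9
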