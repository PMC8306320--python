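"""Module detection, zi/pi node roles, and module composition profiles.

Modules are detected on the unsigned graph by greedy modularity
maximization (deterministic; a seeded Louvain option is available). Node
topological roles follow the within-module degree z-score (zi) and
participation coefficient (pi) scheme: network hubs (zi > 2.5, pi > 0.62),
module hubs (zi > 2.5, pi <= 0.62), connectors (zi <= 2.5, pi > 0.62) and
peripherals (the rest). Boundary values fall to the lower category, since
the thresholds are defined by strict inequalities. Network hubs, module
hubs and connectors together form the keystone set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import CoNetwork

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

CATEGORIES = ("network hub", "module hub", "connector", "peripheral")


@dataclass
class ModulePartition:
    assignment: dict  # node -> module id (0-based, ordered by decreasing size)
    modularity: float
    n_modules: int


def detect_modules(net: CoNetwork, method: str = "greedy", seed: int = 0) -> ModulePartition:
    """Partition the unsigned graph maximizing Newman–Girvan modularity.

    The default greedy agglomeration (CNM) is deterministic; ``louvain``
    uses the given seed. Modules are renumbered by decreasing size with
    lexicographically-smallest-member tie-breaking, so ids are stable.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty network")
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(g)
    elif method == "louvain":
        communities = nx.community.louvain_communities(g, seed=seed)
    else:
        raise ValueError(f"unknown community-detection method: {method!r}")
    communities = [set(c) for c in communities]
    communities.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    assignment = {node: i for i, c in enumerate(communities) for node in c}
    q = nx.community.modularity(g, communities)
    return ModulePartition(assignment, float(q), len(communities))


def modularity_of(net: CoNetwork, assignment: dict) -> float:
    """Newman–Girvan modularity Q of an explicit node -> module assignment."""
    groups: dict = {}
    for node, mod in assignment.items():
        groups.setdefault(mod, set()).add(node)
    return float(nx.community.modularity(net.graph, groups.values()))


def categorize(zi: float, pi: float) -> str:
    """Role category from (zi, pi); boundary values fall to the lower category."""
    if zi > ZI_THRESHOLD and pi > PI_THRESHOLD:
        return "network hub"
    if zi > ZI_THRESHOLD:
        return "module hub"
    if pi > PI_THRESHOLD:
        return "connector"
    return "peripheral"


def classify_roles(net: CoNetwork, partition: ModulePartition) -> pd.DataFrame:
    """zi/pi role classification for every node.

    zi is the z-score of a node's within-module degree relative to its
    module's members (0 when the module's within-degrees have zero spread);
    pi = 1 - sum_s (k_is / k_i)^2 over modules s.
    """
    g = net.graph
    assignment = partition.assignment
    missing = set(g.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(map(str, missing))[:5]}")

    within_degree = {}
    module_links: dict = {}  # node -> {module: count}
    for node in g.nodes:
        own = assignment[node]
        per_module: dict = {}
        for nbr in g.neighbors(node):
            per_module[assignment[nbr]] = per_module.get(assignment[nbr], 0) + 1
        module_links[node] = per_module
        within_degree[node] = per_module.get(own, 0)

    # per-module mean/sd of within-degree
    by_module: dict = {}
    for node, wd in within_degree.items():
        by_module.setdefault(assignment[node], []).append(wd)
    mod_mean = {m: float(np.mean(v)) for m, v in by_module.items()}
    mod_sd = {m: float(np.std(v)) for m, v in by_module.items()}

    rows = {}
    for node in g.nodes:
        k = g.degree(node)
        own = assignment[node]
        sd = mod_sd[own]
        zi = (within_degree[node] - mod_mean[own]) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((c / k) ** 2 for c in module_links[node].values()) if k > 0 else 0.0
        rows[node] = {"module": own, "zi": zi, "pi": pi, "category": categorize(zi, pi)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "node"
    return df.sort_index()


def role_census(roles: pd.DataFrame) -> pd.Series:
    """Fraction of nodes in each role category (sums to 1)."""
    counts = roles["category"].value_counts()
    frac = pd.Series({c: counts.get(c, 0) / len(roles) for c in CATEGORIES})
    return frac


def keystone_nodes(roles: pd.DataFrame) -> list[str]:
    """Network hubs, module hubs and connectors — the keystone taxa."""
    mask = roles["category"] != "peripheral"
    return list(roles.index[mask])


def shared_nodes(net_a: CoNetwork, net_b: CoNetwork) -> dict:
    """Venn statistics between two networks' node sets.

    The shared percentage is 100 * |A intersect B| / |A union B|, rounded
    to one decimal.
    """
    a, b = set(net_a.graph.nodes), set(net_b.graph.nodes)
    inter, union = a & b, a | b
    return {
        "shared": len(inter),
        "unique_a": len(a - b),
        "unique_b": len(b - a),
        "shared_pct": round(100.0 * len(inter) / len(union), 1) if union else 0.0,
    }


def venn_percentage(n_a: int, n_b: int, n_shared: int) -> float:
    """Shared percentage of the union from raw set sizes."""
    union = n_a + n_b - n_shared
    return round(100.0 * n_shared / union, 1)


def module_profiles(
    net: CoNetwork, partition: ModulePartition, major_fraction: float = 0.05
) -> pd.DataFrame:
    """Per-module size, major flag, phylum composition and edge-sign counts.

    A module is *major* when its node count exceeds ``major_fraction`` of
    the total nodes (strictly greater). Phylum labels come from node
    attributes; nodes without one are binned "unclassified".
    """
    g = net.graph
    assignment = partition.assignment
    tn = g.number_of_nodes()
    rows = []
    for mod in sorted(set(assignment.values())):
        members = [n for n, m in assignment.items() if m == mod]
        phyla = pd.Series([g.nodes[n].get("phylum", "unclassified") for n in members])
        comp = (phyla.value_counts() / len(members)).to_dict()
        intra_pos = intra_neg = inter = 0
        for u, v, d in g.edges(members, data=True):
            if assignment[u] == mod and assignment[v] == mod:
                if d.get("sign", 1) > 0:
                    intra_pos += 1
                else:
                    intra_neg += 1
            else:
                inter += 1
        rows.append(
            {
                "module": mod,
                "size": len(members),
                "is_major": len(members) > major_fraction * tn,
                "top_phylum": max(comp, key=comp.get),
                "composition": comp,
                "intra_positive": intra_pos,
                "intra_negative": intra_neg,
                "inter_edges": inter,
            }
        )
    return pd.DataFrame(rows).set_index("module")
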