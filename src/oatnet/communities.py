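"""Community detection on weighted prescriber networks.

The primary detector is greedy agglomerative (Newman-girvan) modularity
maximization: start from singleton communities and repeatedly merge the pair
of communities with the largest modularity gain, stopping when no merge
strictly increases Q. It compares each pair's observed shared-client weight
with the weight expected by chance given the physicians' client loads
(degrees), so densely co-prescribing groups coalesce while incidental
sharing does not. Merge ties are broken by the lexicographically smallest
community-label pair, making the procedure fully deterministic.

Applied recursively, detection re-runs on each community's induced subgraph
(internal edges only) and accepts a split only when the subgraph partition
has strictly positive within-subgraph modularity — this exposes smaller
subgroups (clinic-sized practices) that a single global pass merges
together, without fragmenting indefinitely.

Louvain, Walktrap (walk length 4) and asynchronous label propagation are
provided as comparators on the same weighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

_TOL = 1e-12


class ModularityUndefinedError(ValueError):
    """Modularity is undefined on a graph with zero total edge weight."""


@dataclass(frozen=True)
class ModularityValue:
    """Weighted Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/(2m))^2],
    with per-community intra-weight e_c and incident weight d_c."""

    Q: float
    m: float
    components: dict[str, tuple[float, float]]  # label -> (e_c, d_c)


@dataclass(frozen=True)
class CommunityPartition:
    """Disjoint, exhaustive assignment of physicians to community labels."""

    assignment: dict[str, str]
    algorithm: str
    iterations: int = 1
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def communities(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def validate_against(self, network: nx.Graph) -> None:
        nodes = set(map(str, network.nodes))
        assigned = set(self.assignment)
        if nodes != assigned:
            missing = sorted(nodes - assigned)[:10]
            extra = sorted(assigned - nodes)[:10]
            raise ValueError(f"partition does not cover node set (missing={missing}, extra={extra})")


def _edge_weight(data: dict) -> float:
    return float(data.get("weight", 1.0))


def modularity(network: nx.Graph, partition) -> ModularityValue:
    """Evaluate weighted modularity of a partition (mapping node -> label)."""
    if isinstance(partition, CommunityPartition):
        mapping = partition.assignment
    else:
        mapping = dict(partition)
    nodes = set(map(str, network.nodes))
    if nodes - set(mapping):
        raise ValueError(f"partition misses nodes: {sorted(nodes - set(mapping))[:10]}")
    m = sum(_edge_weight(d) for _, _, d in network.edges(data=True))
    if m <= 0:
        raise ModularityUndefinedError("modularity undefined on a graph with no edge weight")
    intra: dict[str, float] = {}
    deg: dict[str, float] = {}
    for label in set(mapping[n] for n in nodes):
        intra[label] = 0.0
        deg[label] = 0.0
    for u, v, d in network.edges(data=True):
        w = _edge_weight(d)
        lu, lv = mapping[str(u)], mapping[str(v)]
        deg[lu] += w
        deg[lv] += w
        if lu == lv:
            intra[lu] += w
    Q = sum(intra[c] / m - (deg[c] / (2.0 * m)) ** 2 for c in intra)
    return ModularityValue(Q=Q, m=m, components={c: (intra[c], deg[c]) for c in intra})


def _greedy_merge(network: nx.Graph) -> dict[str, str]:
    """CNM-style greedy agglomeration; returns node -> community label
    (label = lexicographically smallest member id)."""
    nodes = sorted(map(str, network.nodes))
    label = {n: n for n in nodes}
    members: dict[str, list[str]] = {n: [n] for n in nodes}
    deg: dict[str, float] = {n: 0.0 for n in nodes}
    nbr: dict[str, dict[str, float]] = {n: {} for n in nodes}
    m = 0.0
    for u, v, d in network.edges(data=True):
        u, v = str(u), str(v)
        if u == v:
            continue
        w = _edge_weight(d)
        m += w
        deg[u] += w
        deg[v] += w
        nbr[u][v] = nbr[u].get(v, 0.0) + w
        nbr[v][u] = nbr[v].get(u, 0.0) + w
    if m <= 0:
        return label

    two_m = 2.0 * m
    while True:
        best_gain = _TOL
        best_pair: tuple[str, str] | None = None
        for u in sorted(nbr):
            du = deg[u]
            for v in sorted(nbr[u]):
                if v <= u:
                    continue
                # merging u,v changes Q by w_uv/m - d_u d_v / (2 m^2)
                gain = nbr[u][v] / m - du * deg[v] / (two_m * m)
                if gain > best_gain or (
                    best_pair is not None
                    and abs(gain - best_gain) <= _TOL
                    and (u, v) < best_pair
                ):
                    best_gain = gain
                    best_pair = (u, v)
        if best_pair is None:
            break
        u, v = best_pair  # u < v: merge v into u
        members[u].extend(members[v])
        deg[u] += deg[v]
        for w_nbr, w in nbr[v].items():
            if w_nbr == u:
                continue
            nbr[u][w_nbr] = nbr[u].get(w_nbr, 0.0) + w
            nbr[w_nbr][u] = nbr[w_nbr].get(u, 0.0) + w
        for w_nbr in nbr[v]:
            nbr[w_nbr].pop(v, None)
        nbr[u].pop(v, None)
        del nbr[v], members[v], deg[v]
    out = {}
    for lab, ms in members.items():
        for n in ms:
            out[n] = lab
    return out


def detect_modularity_max(network: nx.Graph) -> CommunityPartition:
    """Greedy agglomerative modularity maximization (deterministic).

    An edgeless network yields the all-singleton partition.
    """
    assignment = _greedy_merge(network)
    return CommunityPartition(assignment=assignment, algorithm="modularity", iterations=1)


def detect_recursive(network: nx.Graph, iterations: int = 2) -> CommunityPartition:
    """Recursive modularity maximization.

    Iteration 1 runs :func:`detect_modularity_max` on the whole network; each
    later iteration re-runs detection on every community's induced subgraph
    (edges between communities discarded) and accepts the split only if the
    sub-partition has strictly positive within-subgraph modularity. The
    partition at depth t+1 therefore refines the partition at depth t.
    """
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    assignment = _greedy_merge(network)
    for _ in range(iterations - 1):
        new_assignment = dict(assignment)
        comms: dict[str, list[str]] = {}
        for n, lab in assignment.items():
            comms.setdefault(lab, []).append(n)
        for lab in sorted(comms):
            members = comms[lab]
            if len(members) < 2:
                continue
            sub = network.subgraph(members)
            if sub.number_of_edges() == 0:
                continue
            sub_assignment = _greedy_merge(sub)
            if len(set(sub_assignment.values())) < 2:
                continue
            sub_q = modularity(sub, sub_assignment).Q
            if sub_q > _TOL:
                new_assignment.update(sub_assignment)
        assignment = new_assignment
    return CommunityPartition(assignment=assignment, algorithm="modularity", iterations=iterations)


def _partition_from_sets(sets, algorithm: str, seed: int | None, **params) -> CommunityPartition:
    assignment = {}
    for s in sets:
        lab = min(map(str, s))
        for n in s:
            assignment[str(n)] = lab
    return CommunityPartition(
        assignment=assignment, algorithm=algorithm, iterations=1, seed=seed, params=params
    )


def detect_baseline(network: nx.Graph, method: str, seed: int = 0) -> CommunityPartition:
    """Comparator algorithms: ``louvain``, ``walktrap`` (walk length 4, cut
    at maximum modularity) or ``label_propagation`` (asynchronous, weighted,
    seeded update order)."""
    if method == "louvain":
        sets = nx.community.louvain_communities(network, weight="weight", resolution=1.0, seed=seed)
        return _partition_from_sets(sets, "louvain", seed)
    if method == "label_propagation":
        sets = nx.community.asyn_lpa_communities(network, weight="weight", seed=seed)
        return _partition_from_sets(list(sets), "label_propagation", seed)
    if method == "walktrap":
        return _walktrap(network, seed)
    raise ValueError(f"unknown community detection method {method!r}")


def _walktrap(network: nx.Graph, seed: int | None, steps: int = 4) -> CommunityPartition:
    import igraph as ig

    nodes = sorted(map(str, network.nodes))
    if not nodes:
        return CommunityPartition(assignment={}, algorithm="walktrap", seed=seed)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[str(u)], index[str(v)]) for u, v in network.edges]
    weights = [_edge_weight(d) for _, _, d in network.edges(data=True)]
    g = ig.Graph(n=len(nodes), edges=edges)
    if not edges:
        assignment = {n: n for n in nodes}
        return CommunityPartition(
            assignment=assignment, algorithm="walktrap", seed=seed, params={"steps": steps}
        )
    clustering = g.community_walktrap(weights=weights, steps=steps).as_clustering()
    sets = [[nodes[i] for i in cluster] for cluster in clustering]
    part = _partition_from_sets(sets, "walktrap", seed, steps=steps)
    return part


def detect(network: nx.Graph, algorithm: str, seed: int = 0) -> CommunityPartition:
    """Dispatch on an algorithm spec string: ``modularity:<depth>`` (depth
    1-4, default 1), ``louvain``, ``walktrap`` or ``label_propagation``."""
    if algorithm.startswith("modularity"):
        depth = 1
        if ":" in algorithm:
            depth = int(algorithm.split(":", 1)[1])
        return detect_recursive(network, iterations=depth)
    return detect_baseline(network, algorithm, seed=seed)


def export_partition(partition: CommunityPartition, path) -> None:
    """CSV export: physician_id,community_label,algorithm,iterations,seed."""
    import pandas as pd

    rows = sorted(partition.assignment.items())
    df = pd.DataFrame(rows, columns=["physician_id", "community_label"])
    df["algorithm"] = partition.algorithm
    df["iterations"] = partition.iterations
    df["seed"] = partition.seed if partition.seed is not None else ""
    df.to_csv(path, index=False)
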