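"""Weighted median-joining networks for STR haplotypes.

Nodes are observed haplotypes (with multiplicities and population
annotations) plus inferred median vectors; the distance between haplotypes is
``sum_m w_m * |a_m - b_m|`` with each marker weighted by the reciprocal of its
mutation rate (normalised to mean 1). Construction follows the
median-joining scheme: build the minimum spanning network (all links tied
with some minimum spanning tree, relaxed by epsilon), add coordinate-wise
medians of linked triples whose connection cost is minimal, iterate to a
fixed point, then prune median vectors of degree <= 2.

Star contraction is available as preprocessing: star-like clusters (a center
with satellites within a step radius, satellites mutually farther apart) are
replaced by their center with summed multiplicity; the contraction map allows
exact re-expansion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "HaplotypeNode",
    "MJNetwork",
    "collapse_haplotypes",
    "star_contraction",
    "build_mj_network",
    "read_reference_haplotypes",
]


def read_reference_haplotypes(source, marker_set):
    """Read a reference-haplotype TSV (columns ``sample_id``, ``population``,
    then one column per marker) into ``(profiles, population_labels)`` ready
    for :func:`collapse_haplotypes`.

    This is the layout used for literature compilations of haplotypes from
    many source populations (e.g. Asian C3* reference panels).
    """
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "population") if c not in df.columns]
    if missing:
        raise ValueError(f"reference table lacks columns: {missing}")
    absent = [m for m in marker_set if m not in df.columns]
    if absent:
        raise ValueError(f"reference table lacks marker columns: {absent}")
    profiles = []
    labels = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        profiles.append({m: int(row[m]) for m in marker_set})
        labels.append(row["population"])
    return profiles, labels


@dataclass
class HaplotypeNode:
    profile: tuple
    multiplicity: int
    annotations: dict = field(default_factory=dict)


def collapse_haplotypes(profiles, marker_set, annotations=None) -> list:
    """Merge identical profiles into :class:`HaplotypeNode` entries.

    *profiles* is a sequence of STR profile dicts complete on *marker_set*;
    *annotations* an optional parallel sequence of labels (e.g. population),
    aggregated into per-node count dicts. Output is sorted by
    (multiplicity desc, profile) for determinism.
    """
    marker_set = tuple(marker_set)
    if annotations is None:
        annotations = [None] * len(profiles)
    nodes: dict = {}
    for prof, ann in zip(profiles, annotations):
        key = tuple(int(prof[m]) for m in marker_set)
        node = nodes.get(key)
        if node is None:
            node = HaplotypeNode(key, 0, {})
            nodes[key] = node
        node.multiplicity += 1
        if ann is not None:
            node.annotations[ann] = node.annotations.get(ann, 0) + 1
    return sorted(nodes.values(), key=lambda nd: (-nd.multiplicity, nd.profile))


def _step_distance(a, b) -> int:
    return int(sum(abs(x - y) for x, y in zip(a, b)))


def star_contraction(nodes, max_radius: int = 1, min_rays: int = 3):
    """Contract star-like clusters to their centers.

    A center absorbs satellites within *max_radius* unweighted mutational
    steps that are mutually farther than *max_radius* from each other; a
    genuine star needs at least *min_rays* satellites (so chains do not
    contract). Passes repeat until a fixed point. Returns
    ``(contracted_nodes, contraction_map)`` where the map sends each absorbed
    profile to its (final) center profile.
    """
    nodes = [HaplotypeNode(n.profile, n.multiplicity, dict(n.annotations)) for n in nodes]
    mapping: dict = {}
    changed = True
    while changed:
        changed = False
        order = sorted(nodes, key=lambda nd: (-nd.multiplicity, nd.profile))
        absorbed: set = set()
        for center in order:
            if center.profile in absorbed:
                continue
            sats = [
                nd
                for nd in order
                if nd.profile != center.profile
                and nd.profile not in absorbed
                and _step_distance(center.profile, nd.profile) <= max_radius
            ]
            sats = [
                s
                for s in sats
                if all(
                    _step_distance(s.profile, t.profile) > max_radius
                    for t in sats
                    if t.profile != s.profile
                )
            ]
            if len(sats) < min_rays:
                continue
            for s in sats:
                center.multiplicity += s.multiplicity
                for k, v in s.annotations.items():
                    center.annotations[k] = center.annotations.get(k, 0) + v
                absorbed.add(s.profile)
                mapping[s.profile] = center.profile
                changed = True
        nodes = [nd for nd in nodes if nd.profile not in absorbed]
    # compose chains (satellite -> center -> supercenter)
    final_map = {}
    for src in mapping:
        dst = mapping[src]
        while dst in mapping:
            dst = mapping[dst]
        final_map[src] = dst
    return nodes, final_map


@dataclass
class MJNetwork:
    graph: nx.Graph
    epsilon: float
    weights: dict

    @property
    def observed(self):
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def median_vectors(self):
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]

    def path_length(self, a, b) -> float:
        """Weighted length of the shortest network path between two nodes."""
        return nx.shortest_path_length(self.graph, a, b, weight="length")

    def path_steps(self, a, b) -> int:
        """Mutational steps along the shortest (by weighted length) path."""
        path = nx.shortest_path(self.graph, a, b, weight="length")
        return sum(_step_distance(u, v) for u, v in zip(path, path[1:]))

    def to_edge_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("node_a\tnode_b\tlength\tsteps\n")
            for u, v, d in self.graph.edges(data=True):
                fh.write(
                    f"{'-'.join(map(str, u))}\t{'-'.join(map(str, v))}\t"
                    f"{d['length']:.6g}\t{d['steps']}\n"
                )

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(
                "-".join(map(str, n)),
                observed=bool(d["observed"]),
                multiplicity=int(d["multiplicity"]),
                annotations=";".join(
                    f"{k}:{v}" for k, v in sorted(d["annotations"].items())
                ),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(
                "-".join(map(str, u)),
                "-".join(map(str, v)),
                length=float(d["length"]),
                steps=int(d["steps"]),
            )
        nx.write_graphml(g, path)


def _weighted_distance_matrix(profiles, w):
    x = np.array(profiles, dtype=float)
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = np.abs(x - x[i]).dot(w)
    return d


def _msn_edges(profiles, d, epsilon):
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u, v) belongs to the network iff its length is at most the
    minimax-path distance between u and v (largest step on the best path)
    plus epsilon; at epsilon = 0 this is exactly the union of all minimum
    spanning trees.
    """
    n = len(profiles)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=d[i, j])
    mst = nx.minimum_spanning_tree(g, weight="weight")
    # minimax path distances from the MST
    minimax = np.zeros((n, n))
    for src in range(n):
        seen = {src: 0.0}
        stack = [(src, 0.0)]
        while stack:
            u, best = stack.pop()
            for v in mst.neighbors(u):
                if v not in seen:
                    val = max(best, mst[u][v]["weight"])
                    seen[v] = val
                    stack.append((v, val))
        for v, val in seen.items():
            minimax[src, v] = val
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= minimax[i, j] + epsilon + 1e-9:
                edges.append((i, j))
    return edges


def build_mj_network(nodes, marker_set, weights=None, epsilon: float = 0.0) -> MJNetwork:
    """Median-joining network over collapsed haplotype nodes.

    *weights* maps marker -> positive weight (defaults to 1 everywhere; pass
    ``panel.weight`` for inverse-mutation-rate weighting). Ties in median
    insertion are broken lexicographically on (cost, profile) so the result
    is independent of input order.
    """
    marker_set = tuple(marker_set)
    if weights is None:
        w = np.ones(len(marker_set))
    else:
        w = np.array([weights[m] for m in marker_set], dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    observed = {nd.profile: nd for nd in nodes}
    if len(observed) < 2:
        raise ValueError("need at least two distinct haplotypes")
    current = sorted(observed)

    for _ in range(200):  # fixed-point iteration; bounded lattice guarantees exit
        d = _weighted_distance_matrix(current, w)
        edges = _msn_edges(current, d, epsilon)
        adj: dict = {i: set() for i in range(len(current))}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)
        # candidate medians from connected triples (u - v - w via MSN links)
        candidates: dict = {}
        for v in range(len(current)):
            for u, t in itertools.combinations(sorted(adj[v]), 2):
                med = tuple(
                    int(np.median([current[u][m], current[v][m], current[t][m]]))
                    for m in range(len(marker_set))
                )
                if med in observed or med in set(current):
                    continue
                cost = float(
                    sum(
                        np.abs(np.array(current[i]) - np.array(med)).dot(w)
                        for i in (u, v, t)
                    )
                )
                if med not in candidates or cost < candidates[med]:
                    candidates[med] = cost
        if not candidates:
            break
        best = min(candidates.values())
        new = sorted(
            m for m, c in candidates.items() if c <= best + epsilon + 1e-9
        )
        current = sorted(set(current) | set(new))
    # cleanup: drop median vectors of degree <= 2, re-deriving the MSN
    while True:
        d = _weighted_distance_matrix(current, w)
        edges = _msn_edges(current, d, epsilon)
        deg = {i: 0 for i in range(len(current))}
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        drop = [
            current[i]
            for i in range(len(current))
            if current[i] not in observed and deg[i] <= 2
        ]
        if not drop:
            break
        current = [p for p in current if p not in set(drop)]

    g = nx.Graph()
    for p in current:
        nd = observed.get(p)
        g.add_node(
            p,
            observed=nd is not None,
            multiplicity=nd.multiplicity if nd else 0,
            annotations=dict(nd.annotations) if nd else {},
        )
    d = _weighted_distance_matrix(current, w)
    for i, j in _msn_edges(current, d, epsilon):
        g.add_edge(
            current[i],
            current[j],
            length=float(d[i, j]),
            steps=_step_distance(current[i], current[j]),
        )
    return MJNetwork(graph=g, epsilon=epsilon, weights=dict(zip(marker_set, w)))
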