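"""Median-joining haplotype networks, star contraction and network groups.

The network construction follows the median-joining idea of Bandelt,
Forster & Roehl (1999): starting from the minimum spanning network (MSN,
the union of all minimum spanning trees) over observed haplotypes, the
node set is iteratively augmented with majority-consensus median (Steiner)
sequences of linked triplets, keeping in each round the candidates whose
connection cost is within epsilon of the best, until closure.  A final
MP-style pruning keeps only median vectors that lie on a shortest
connection between observed haplotypes, so the result is free of
superfluous vectors and reticulation-inducing links.

Determinism: haplotypes are canonicalized by lexicographic sequence sort,
and all tie-breaks are lexicographic.  Distances are Hamming steps,
computed vectorised so networks of a few hundred haplotypes stay fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping
import warnings

import networkx as nx
import numpy as np

from .seqio import HaplotypeTable

__all__ = [
    "HaplotypeNetwork",
    "hamming",
    "build_mj_network",
    "star_contraction",
    "partition_groups",
    "group_breed_matrix",
]


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _encode(seqs: list[str]) -> np.ndarray:
    L = len(seqs[0])
    return np.frombuffer("".join(seqs).encode("ascii"), dtype="S1").reshape(
        len(seqs), L
    )


def _distance_matrix(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    D = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        D[i] = (M != M[i]).sum(axis=1)
    return D


@dataclass
class HaplotypeNetwork:
    """Graph of observed haplotypes plus inferred median vectors.

    Nodes are keyed by sequence string; node attributes: ``observed``
    (bool), ``count``, ``members``.  Edge attribute ``steps`` holds the
    number of mutational steps (Hamming distance).
    """

    graph: nx.Graph
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def observed(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def medians(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if not d["observed"]]

    def total_length(self) -> int:
        return sum(d["steps"] for _, _, d in self.graph.edges(data=True))


def _msn_edge_indices(D: np.ndarray) -> list[tuple[int, int, int]]:
    """Minimum spanning network over a distance matrix: process distance
    classes in increasing order, keeping every edge that joins components
    formed by strictly smaller classes; stop once connected."""
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = D[iu, ju]
    order = np.lexsort((ju, iu, w))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, int]] = []
    n_comp = n
    k = 0
    m = len(w)
    while k < m and n_comp > 1:
        cls_w = w[order[k]]
        cls = []
        while k < m and w[order[k]] == cls_w:
            e = order[k]
            cls.append((int(iu[e]), int(ju[e])))
            k += 1
        added = [(i, j) for i, j in cls if find(i) != find(j)]
        edges.extend((i, j, int(cls_w)) for i, j in added)
        for i, j in added:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                n_comp -= 1
    return edges


def _majority_median(rows: np.ndarray) -> np.ndarray:
    """Per-site majority consensus of three encoded sequences; ties take
    the state of the first row (rows are supplied in sorted order)."""
    a, b, c = rows
    out = a.copy()
    bc = (b == c) & (a != b)
    out[bc] = b[bc]
    return out


def build_mj_network(
    ht: HaplotypeTable, epsilon: int = 0, max_iter: int = 50
) -> HaplotypeNetwork:
    """Construct the median-joining network of a haplotype table.

    ``epsilon`` relaxes the greediness of median addition: in each round
    all candidate medians whose connection cost is within ``epsilon`` of
    the round's best are added.  The default 0 yields the most parsimonious
    (and deterministic) network.
    """
    if ht.H < 2:
        raise ValueError("need at least two haplotypes")
    lengths = {len(h) for h, _, _ in ht.haplotypes}
    if len(lengths) != 1:
        raise ValueError("haplotypes differ in length")
    info = {
        seq: {"observed": True, "count": count, "members": list(members)}
        for seq, count, members in ht.haplotypes
    }
    nodes = sorted(info)  # canonical order

    for _ in range(max_iter):
        M = _encode(nodes)
        D = _distance_matrix(M)
        edges = _msn_edge_indices(D)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _w in edges:
            adj[i].add(j)
            adj[j].add(i)
        node_set = set(nodes)
        candidates: dict[str, int] = {}
        seen_triples: set[tuple[int, int, int]] = set()
        for i, j, _w in edges:
            for k in adj[i] | adj[j]:
                if k in (i, j):
                    continue
                trip = tuple(sorted((i, j, k)))
                if trip in seen_triples:
                    continue
                seen_triples.add(trip)
                med = _majority_median(M[list(trip)])
                med_s = bytes(med).decode("ascii")
                if med_s in node_set:
                    continue
                cost = int((M[list(trip)] != med).sum())
                if med_s not in candidates or cost < candidates[med_s]:
                    candidates[med_s] = cost
        if not candidates:
            break
        best = min(candidates.values())
        new = sorted(m for m, c in candidates.items() if c <= best + epsilon)
        nodes = sorted(node_set | set(new))
    else:
        warnings.warn("median-joining did not close within max_iter rounds")

    G = nx.Graph()
    for v in nodes:
        if v in info:
            G.add_node(v, **info[v])
        else:
            G.add_node(v, observed=False, count=0, members=[])
    M = _encode(nodes)
    D = _distance_matrix(M)
    for i, j, w in _msn_edge_indices(D):
        G.add_edge(nodes[i], nodes[j], steps=w)
    _prune_medians(G)
    return HaplotypeNetwork(G)


def _prune_medians(G: nx.Graph) -> None:
    """MP-style pruning: drop median vectors not on any shortest connection
    between observed haplotypes, then splice out degree-<=2 medians."""
    from scipy.sparse.csgraph import shortest_path

    changed = True
    while changed:
        changed = False
        order = sorted(G.nodes)
        idx = {v: i for i, v in enumerate(order)}
        A = nx.to_scipy_sparse_array(G, nodelist=order, weight="steps")
        SP = shortest_path(A, method="D", directed=False)
        obs = [i for i, v in enumerate(order) if G.nodes[v]["observed"]]
        C = SP[np.ix_(obs, obs)]
        for v in order:
            if G.nodes[v]["observed"]:
                continue
            k = idx[v]
            slack = SP[obs, k][:, None] + SP[k, obs][None, :] - C
            if not np.any(np.isclose(slack, 0.0)):
                G.remove_node(v)
                changed = True
        # splice chains: a median of degree <= 2 adds no branching information
        for v in [u for u, d in G.nodes(data=True) if not d["observed"]]:
            deg = G.degree(v)
            if deg <= 1:
                G.remove_node(v)
                changed = True
            elif deg == 2:
                u, w = list(G.neighbors(v))
                G.remove_node(v)
                if not G.has_edge(u, w):
                    G.add_edge(u, w, steps=hamming(u, w))
                changed = True


def star_contraction(ht: HaplotypeTable, radius: int = 1) -> HaplotypeTable:
    """Collapse satellite haplotypes onto star hubs to shrink large tables.

    Greedy hub-first rule: repeatedly pick the haplotype with the most
    remaining neighbours within ``radius`` mutational steps (ties broken by
    higher multiplicity, then lexicographic sequence); if it has at least
    two such satellites, absorb them (counts and member ids accumulate on
    the hub).  Stops when no haplotype centres a star.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    entries = {seq: (count, list(members)) for seq, count, members in ht.haplotypes}
    while True:
        seqs = sorted(entries)
        D = _distance_matrix(_encode(seqs))
        within = (D <= radius) & ~np.eye(len(seqs), dtype=bool)
        best_hub_i = -1
        best_key = None
        for i, hub in enumerate(seqs):
            nsat = int(within[i].sum())
            if nsat < 2:
                continue
            key = (nsat, entries[hub][0], hub)
            if best_key is None or key > best_key:
                best_key, best_hub_i = key, i
        if best_hub_i < 0:
            break
        hub = seqs[best_hub_i]
        count, members = entries[hub]
        for j in np.flatnonzero(within[best_hub_i]):
            c, m = entries.pop(seqs[j])
            count += c
            members += m
        entries[hub] = (count, members)
    haps = [(s, c, sorted(m)) for s, (c, m) in entries.items()]
    haps.sort(key=lambda h: (-h[1], h[0]))
    return HaplotypeTable(haps, n=ht.n)


def partition_groups(net: HaplotypeNetwork, cutoff: int) -> dict[str, str]:
    """Partition the network into groups by removing long edges.

    Edges with more than ``cutoff`` mutational steps are cut; the connected
    components that remain are the groups.  Components are labelled
    ``G1, G2, ...`` in order of their smallest member id (medians follow
    their component), making labels deterministic.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    H = nx.Graph()
    H.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        if d["steps"] <= cutoff:
            H.add_edge(u, v)
    comps = list(nx.connected_components(H))
    if len(comps) == net.graph.number_of_nodes() and net.graph.number_of_edges():
        warnings.warn("cutoff smaller than every edge: all nodes isolated")

    def comp_key(comp: set[str]) -> str:
        members = sorted(
            m for v in comp for m in net.graph.nodes[v].get("members", [])
        )
        return members[0] if members else min(comp)

    comps.sort(key=comp_key)
    labels: dict[str, str] = {}
    for k, comp in enumerate(comps, start=1):
        for v in comp:
            labels[v] = f"G{k}"
    net.groups = labels
    return labels


def group_breed_matrix(
    net: HaplotypeNetwork,
    groups: Mapping[str, str],
    metadata: Mapping[str, Mapping[str, str]],
):
    """Tally individuals by (breed, network group).

    Each observed haplotype contributes its members to the group it sits
    in; row sums equal per-breed sample sizes.
    """
    import pandas as pd

    rows: dict[str, dict[str, int]] = {}
    for v, d in net.graph.nodes(data=True):
        if not d["observed"]:
            continue
        g = groups[v]
        for sid in d["members"]:
            breed = metadata[sid]["breed"]
            rows.setdefault(breed, {})
            rows[breed][g] = rows[breed].get(g, 0) + 1
    breeds = sorted(rows)
    cols = sorted({g for r in rows.values() for g in r})
    M = pd.DataFrame(0, index=breeds, columns=cols, dtype=int)
    for b, r in rows.items():
        for g, c in r.items():
            M.loc[b, g] = c
    return M
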