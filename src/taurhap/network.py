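"""Haplotype collapsing, minimum-spanning networks and median-joining networks.

``collapse_haplotypes`` reduces an alignment to distinct haplotypes over the
included sites (complete-column deletion: any column containing a gap or N in
any sequence is dropped before comparison).  ``minimum_spanning_network``
generalises Kruskal's minimum-spanning-tree construction by keeping *every*
edge of a weight class that joins two components as of the start of that
class — the union of all minimum spanning trees.  ``median_joining`` adds
inferred intermediate haplotypes (median vectors): per-site majority
consensus of connected triples, admitted greedily while they shorten the
network, in the spirit of the maximum-parsimony heuristic; inferred nodes of
degree < 3 are pruned at the end.  All tie-breaks are lexicographic on the
haplotype sequence, so results are deterministic for a given input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np

from ._util import encode


class EmptyAlignmentError(ValueError):
    """All columns were dropped (or no sites left) when collapsing."""


@dataclass
class HaplotypeTable:
    sequences: list          # distinct haplotype strings over included sites
    multiplicity: list
    members: list            # list of lists of input ids
    included_sites: list     # original 1-based positions of retained columns
    dropped_columns: list    # original 1-based positions removed (gap/N)

    def __len__(self):
        return len(self.sequences)

    @property
    def n_sequences(self) -> int:
        return sum(self.multiplicity)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({
            "haplotype": [f"H{i + 1:02d}" for i in range(len(self.sequences))],
            "multiplicity": self.multiplicity,
            "members": [",".join(m) for m in self.members],
            "sequence": self.sequences,
        }).to_csv(str(path), sep="\t", index=False)


def collapse_haplotypes(sequences, region=None) -> HaplotypeTable:
    """Group equal-length sequences into haplotypes over clean columns.

    ``sequences`` is a dict id->sequence or list of (id, sequence).
    ``region`` restricts to a list of 1-based inclusive intervals (or a
    single (start, end) tuple) before column filtering.
    """
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = [(i, s) for i, s in sequences]
    if not items:
        raise ValueError("no sequences supplied")
    lengths = {len(s) for _i, s in items}
    if len(lengths) != 1:
        raise ValueError(f"sequences must be equal length, got lengths {sorted(lengths)}")
    L = lengths.pop()

    if region is None:
        site_positions = list(range(1, L + 1))
    else:
        if isinstance(region, tuple) and len(region) == 2 and \
                all(isinstance(x, int) for x in region):
            region = [region]
        site_positions = []
        for lo, hi in region:
            if not (1 <= lo <= hi <= L):
                raise ValueError(f"region {lo}..{hi} outside 1..{L}")
            site_positions.extend(range(lo, hi + 1))

    ids = [i for i, _s in items]
    mat = np.vstack([encode(s)[np.asarray(site_positions) - 1] for _i, s in items])
    clean = (mat < 4).all(axis=0)
    dropped = [site_positions[j] for j in np.flatnonzero(~clean)]
    kept = [site_positions[j] for j in np.flatnonzero(clean)]
    if not kept:
        raise EmptyAlignmentError(
            f"no columns left after dropping {len(dropped)} gap/N columns "
            f"from {len(site_positions)} sites")
    sub = mat[:, clean]

    groups: dict = {}
    order = []
    for row_id, row in zip(ids, sub):
        key = row.tobytes()
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(row_id)
    from ._util import decode
    seqs = [decode(np.frombuffer(key, dtype=np.uint8)) for key in order]
    return HaplotypeTable(
        sequences=seqs,
        multiplicity=[len(groups[k]) for k in order],
        members=[groups[k] for k in order],
        included_sites=kept,
        dropped_columns=dropped)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _hamming_matrix(seqs: list) -> np.ndarray:
    mat = np.vstack([encode(s) for s in seqs])
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[ra] = rb


def _msn_edges(seqs: list, epsilon: int = 0):
    """Edges (i, j, w) of the epsilon-relaxed minimum spanning network.

    An edge of weight w is admitted iff its endpoints are in different
    components of the graph formed by all admitted edges of weight
    <= w - 1 - epsilon; with epsilon = 0 this is exactly the union of all
    minimum spanning trees (every tied edge kept).
    """
    n = len(seqs)
    if n == 1:
        return [], np.zeros((1, 1), dtype=int)
    D = _hamming_matrix(seqs)
    pairs = sorted(
        ((int(D[i, j]), i, j) for i, j in combinations(range(n), 2)),
        key=lambda t: t[0])
    edges = []
    weights = sorted({w for w, _i, _j in pairs})
    connected_at = None
    for w in weights:
        if connected_at is not None and w > connected_at + epsilon:
            break
        uf = _UnionFind(n)
        for ew, i, j in edges:
            if ew <= w - 1 - epsilon:
                uf.union(i, j)
        for pw, i, j in pairs:
            if pw == w and uf.find(i) != uf.find(j):
                edges.append((pw, i, j))
        if connected_at is None:
            full = _UnionFind(n)
            for _ew, i, j in edges:
                full.union(i, j)
            if len({full.find(i) for i in range(n)}) == 1:
                connected_at = w
    return [(i, j, w) for w, i, j in edges], D


def _total_length(seqs: list, epsilon: int = 0) -> int:
    edges, _D = _msn_edges(seqs, epsilon)
    return sum(w for _i, _j, w in edges)


def _build_graph(seqs, labels, multiplicity, members, inferred, epsilon):
    edges, _D = _msn_edges(seqs, epsilon)
    G = nx.Graph()
    for idx, lab in enumerate(labels):
        G.add_node(lab, sequence=seqs[idx], multiplicity=multiplicity[idx],
                   inferred=bool(inferred[idx]),
                   members=",".join(members[idx]) if members[idx] else "")
    for i, j, w in edges:
        G.add_edge(labels[i], labels[j], weight=int(w))
    return G


def minimum_spanning_network(table: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Minimum spanning network over the haplotype table (no medians)."""
    if len(table) < 1:
        raise ValueError("need at least one haplotype")
    labels = [f"H{i + 1:02d}" for i in range(len(table))]
    return _build_graph(table.sequences, labels, table.multiplicity,
                        table.members, [False] * len(table), epsilon)


def _majority_median(a: str, b: str, c: str) -> str:
    """Per-site majority of three haplotypes; three-way ties take the
    lexicographically smallest state (deterministic)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min(x, y, z))
    return "".join(out)


def median_joining(table: HaplotypeTable, epsilon: int = 0,
                   max_iter: int = 100, exhaustive_triples: bool = True) -> nx.Graph:
    """Median-joining network: MSN plus inferred median vectors.

    Each round builds the MSN, forms the per-site majority median of every
    triple of nodes sharing a connected component (``exhaustive_triples``
    considers all same-component triples; it is the default at the scale this
    package targets), and adds the candidate giving the largest reduction in
    total network length; ties are broken lexicographically.  Rounds repeat
    until no candidate shortens the network or ``max_iter`` is reached, after
    which inferred nodes of degree < 3 are pruned (repeatedly).  The returned
    graph carries ``converged`` in ``G.graph``.
    """
    if len(table) < 2:
        raise ValueError("need at least two haplotypes")
    observed = list(table.sequences)
    seqs = list(observed)
    medians: list = []
    converged = False
    for _round in range(max_iter):
        edges, _D = _msn_edges(seqs, epsilon)
        G = nx.Graph()
        G.add_nodes_from(range(len(seqs)))
        G.add_edges_from((i, j) for i, j, _w in edges)
        comps = list(nx.connected_components(G))
        current = sum(w for _i, _j, w in edges)

        candidates = set()
        existing = set(seqs)
        for comp in comps:
            nodes = sorted(comp)
            if len(nodes) < 3:
                continue
            for i, j, k in combinations(nodes, 3):
                m = _majority_median(seqs[i], seqs[j], seqs[k])
                if m not in existing:
                    candidates.add(m)
        best = None
        for m in sorted(candidates):
            new_total = _total_length(seqs + [m], epsilon)
            if new_total < current and (best is None or new_total < best[0]):
                best = (new_total, m)
        if best is None:
            converged = True
            break
        assert best[0] < current  # a median never lengthens the network
        seqs.append(best[1])
        medians.append(best[1])

    # prune inferred nodes of degree < 3 (iteratively, as removal may
    # expose further low-degree medians)
    while True:
        edges, _D = _msn_edges(seqs, epsilon)
        deg = {i: 0 for i in range(len(seqs))}
        for i, j, _w in edges:
            deg[i] += 1
            deg[j] += 1
        removable = [i for i in range(len(seqs))
                     if i >= len(observed) and deg[i] < 3]
        if not removable:
            break
        keep = [i for i in range(len(seqs)) if i not in set(removable)]
        seqs = [seqs[i] for i in keep]

    labels, mult, members, inferred = [], [], [], []
    mv = 0
    for idx, s in enumerate(seqs):
        if idx < len(observed):
            labels.append(f"H{idx + 1:02d}")
            mult.append(table.multiplicity[idx])
            members.append(table.members[idx])
            inferred.append(False)
        else:
            mv += 1
            labels.append(f"mv{mv}")
            mult.append(0)
            members.append([])
            inferred.append(True)
    G = _build_graph(seqs, labels, mult, members, inferred, epsilon)
    G.graph["converged"] = converged
    G.graph["epsilon"] = epsilon
    return G


def total_network_length(G: nx.Graph) -> int:
    return sum(d["weight"] for _u, _v, d in G.edges(data=True))


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def write_edgelist(G: nx.Graph, path: str | Path) -> None:
    import pandas as pd
    nodes = pd.DataFrame(
        [(n, d.get("multiplicity", 0), d.get("inferred", False),
          d.get("members", ""), d.get("sequence", ""))
         for n, d in sorted(G.nodes(data=True))],
        columns=["node", "multiplicity", "inferred", "members", "sequence"])
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in sorted(G.edges(data=True))],
        columns=["node_a", "node_b", "weight"])
    with open(path, "w") as fh:
        fh.write("#nodes\n")
        nodes.to_csv(fh, sep="\t", index=False)
        fh.write("#edges\n")
        edges.to_csv(fh, sep="\t", index=False)
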