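"""Reduced-median haplotype networks on binary-recoded variable sites.

The reduced-median construction augments the observed haplotypes with
inferred *median vectors* — per-character majorities of node triples —
whose inclusion shortens the most-parsimonious network, then links the
augmented node set with every edge that participates in some minimum
spanning tree.  Variable columns are first recoded to binary characters
(multi-state columns split against the consensus state), the preprocessing
this algorithm family requires.

The construction here is deterministic: candidate medians are admitted
greedily by how much they reduce the spanning length, subject to a
frequency-based reduction criterion with parameter ``r`` (larger ``r``
admits less-supported medians), and finally pruned to the medians lying on
a shortest path between two observed haplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .haplotypes import HaplotypeTable
from .io import GAP

__all__ = [
    "BinaryRecoding",
    "HaploNetwork",
    "recode_binary",
    "build_rm_network",
    "network_components",
    "write_gml",
    "write_dot",
]


@dataclass(frozen=True)
class BinaryRecoding:
    """Binary character matrix (H × C) plus per-character provenance."""

    matrix: np.ndarray                      # uint8 0/1, shape (H, C)
    columns: list[int]                      # alignment column per character
    states: list[str]                       # the non-consensus base per character
    consensus: list[str]                    # consensus base per character

    @property
    def n_characters(self) -> int:
        return self.matrix.shape[1]


def recode_binary(haps: HaplotypeTable) -> BinaryRecoding:
    """Recode variable columns as binary characters against the consensus.

    The consensus state of a column is its most frequent base weighted by
    haplotype multiplicities (ties: alphabetically first).  A biallelic
    column yields one character; a column with k > 2 states yields k-1
    characters, one per non-consensus state.  Invariant columns are dropped.
    """
    mat = haps.matrix()
    if (mat >= GAP).any():
        raise ValueError("binary recoding requires complete haplotypes (A/C/G/T only)")
    counts = np.asarray(haps.counts)
    chars, cols, states, consensus = [], [], [], []
    for j in range(haps.length):
        col = mat[:, j]
        freq = np.bincount(col, weights=counts, minlength=4)
        present = np.flatnonzero(freq > 0)
        if present.size < 2:
            continue
        cons = int(present[np.argmax(freq[present])])  # argmax ties → lowest code
        for st in present:
            if st == cons:
                continue
            chars.append((col == st).astype(np.uint8))
            cols.append(j)
            states.append("ACGT"[st])
            consensus.append("ACGT"[cons])
    matrix = (np.column_stack(chars) if chars
              else np.zeros((haps.n_haplotypes, 0), dtype=np.uint8))
    return BinaryRecoding(matrix=matrix, columns=cols, states=states,
                          consensus=consensus)


@dataclass
class HaploNetwork:
    graph: nx.Graph
    recoding: BinaryRecoding
    haplotypes: HaplotypeTable
    r: float
    observed_nodes: list[str] = field(default_factory=list)
    median_nodes: list[str] = field(default_factory=list)

    def total_length(self) -> int:
        """Minimum spanning length over the augmented node set."""
        return _mst_length_graph(self.graph)

    def edges_table(self) -> list[dict]:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            rows.append({"from": u, "to": v, "weight": d["weight"],
                         "columns": ",".join(str(c) for c in d["columns"])})
        return rows


def _hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def _mst_length(vectors: list[np.ndarray]) -> int:
    """Prim's algorithm over Hamming distances; small-n exact."""
    n = len(vectors)
    if n <= 1:
        return 0
    V = np.vstack(vectors)
    dist = (V[:, None, :] != V[None, :, :]).sum(axis=2)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = dist[0].astype(float)
    best[0] = np.inf
    total = 0
    for _ in range(n - 1):
        j = int(np.argmin(best))
        total += int(best[j])
        in_tree[j] = True
        best = np.minimum(best, dist[j].astype(float))
        best[in_tree] = np.inf
    return total


def _prim_mst(Dm: np.ndarray) -> tuple[int, list[tuple[int, int]]]:
    """(length, edge list) of an MST over a dense distance matrix."""
    n = Dm.shape[0]
    if n <= 1:
        return 0, []
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = Dm[0].astype(float)
    best_from = np.zeros(n, dtype=int)
    best[0] = np.inf
    total = 0
    edges = []
    for _ in range(n - 1):
        j = int(np.argmin(best))
        total += int(best[j])
        edges.append((int(best_from[j]), j))
        in_tree[j] = True
        closer = Dm[j] < best
        best_from[closer] = j
        best = np.minimum(best, Dm[j])
        best[in_tree] = np.inf
    return total, edges


def _mst_augmented(tree_edges: list[tuple[int, int]], Dm: np.ndarray,
                   dvec: np.ndarray) -> int:
    """MST length after adding one vertex with distances ``dvec``.

    Kruskal over the old MST edges plus the new vertex's star edges.
    """
    n = Dm.shape[0]
    cand = [(int(Dm[a, b]), a, b) for a, b in tree_edges]
    cand += [(int(dvec[i]), i, n) for i in range(n)]
    cand.sort(key=lambda t: t[0])
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total = 0
    joined = 0
    for w, a, b in cand:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            total += w
            joined += 1
            if joined == n:
                break
    return total


def _mst_length_graph(g: nx.Graph) -> int:
    t = nx.minimum_spanning_tree(g, weight="weight")
    return int(sum(d["weight"] for _, _, d in t.edges(data=True)))


def build_rm_network(haps: HaplotypeTable, r: float = 2.0) -> HaploNetwork:
    """Construct the reduced-median network of a haplotype table.

    Median vectors are added greedily: every triple of current nodes
    proposes its per-character majority; proposals that strictly reduce the
    minimum spanning length and whose frequency support is at least ``1/r``
    of the best-supported proposal of the round are admissible, and the one
    with the largest reduction (ties: larger support, then lexicographically
    smallest vector) is added.  This repeats to a fixed point; medians not
    lying on any shortest path between two observed haplotypes are then
    discarded (unless their removal would lengthen the network), and the
    final edges are the union of all minimum spanning trees over the
    remaining nodes.

    A single haplotype yields a trivial one-node network.
    """
    rec = recode_binary(haps)
    H = haps.n_haplotypes
    obs_vectors = [rec.matrix[i] for i in range(H)]

    # deduplicate identical binary vectors (possible when haplotypes differ
    # only at columns dropped by recoding — cannot happen on complete data,
    # but keep the construction safe)
    vectors: list[np.ndarray] = []
    weights: list[float] = []
    observed_of: list[list[int]] = []
    seen: dict[bytes, int] = {}
    for i, v in enumerate(obs_vectors):
        key = v.tobytes()
        if key in seen:
            k = seen[key]
            weights[k] += haps.counts[i]
            observed_of[k].append(i)
        else:
            seen[key] = len(vectors)
            vectors.append(v.copy())
            weights.append(float(haps.counts[i]))
            observed_of.append([i])
    n_observed = len(vectors)

    # --- greedy median closure -------------------------------------------
    # Dm holds pairwise Hamming distances among current nodes and is grown
    # incrementally; per-candidate MST deltas use the fact that the MST of
    # G ∪ {m} only needs MST(G)'s edges plus the edges incident to m.
    n_now = len(vectors)
    Dm = np.zeros((n_now, n_now), dtype=np.int32)
    V = np.vstack(vectors)
    for i in range(n_now):
        Dm[i] = (V != V[i]).sum(axis=1)
    max_medians = 4 * n_observed + 32
    while len(vectors) - n_observed < max_medians:
        n_now = len(vectors)
        base_len, tree_edges = _prim_mst(Dm)
        proposals: dict[bytes, tuple[float, np.ndarray]] = {}
        for a, b, c in itertools.combinations(range(n_now), 3):
            m = _majority(vectors[a], vectors[b], vectors[c])
            key = m.tobytes()
            if key in seen:
                continue
            support = weights[a] + weights[b] + weights[c]
            prev = proposals.get(key)
            if prev is None or support > prev[0]:
                proposals[key] = (support, m)
        if not proposals:
            break
        V = np.vstack(vectors)
        scored = []
        for key, (support, m) in proposals.items():
            dvec = (V != m).sum(axis=1)
            delta = base_len - _mst_augmented(tree_edges, Dm, dvec)
            if delta > 0:
                scored.append((delta, support, key, m))
        if not scored:
            break
        max_support = max(s for _, s, _, _ in scored)
        admissible = [t for t in scored if t[1] * r >= max_support]
        if not admissible:
            break
        admissible.sort(key=lambda t: (-t[0], -t[1], t[2]))
        _, support, key, m = admissible[0]
        seen[key] = len(vectors)
        dvec = (V != m).sum(axis=1)
        Dm = np.pad(Dm, ((0, 1), (0, 1)))
        Dm[-1, :-1] = dvec
        Dm[:-1, -1] = dvec
        vectors.append(m)
        weights.append(1.0)  # inferred node: unit pseudo-frequency
        observed_of.append([])

    # --- geodesic pruning -------------------------------------------------
    keep = list(range(n_observed))
    med_idx = list(range(n_observed, len(vectors)))
    V = np.vstack(vectors) if vectors else np.zeros((0, rec.n_characters), np.uint8)
    dist = (V[:, None, :] != V[None, :, :]).sum(axis=2)
    for m in med_idx:
        on_geodesic = any(
            dist[u, m] + dist[m, v] == dist[u, v]
            for u in range(n_observed)
            for v in range(u + 1, n_observed)
        )
        if on_geodesic:
            keep.append(m)
        else:
            # keep anyway if dropping it would lengthen the network
            trial = [vectors[i] for i in keep + [x for x in med_idx if x > m]]
            if _mst_length(trial) > _mst_length(trial + [vectors[m]]):
                keep.append(m)
    keep_sorted = sorted(keep)

    # --- union of all minimum spanning trees ------------------------------
    graph = nx.Graph()
    names = {}
    for rank, i in enumerate(keep_sorted):
        if i < n_observed:
            name = f"H{min(observed_of[i]) + 1}"
            graph.add_node(
                name,
                observed=True,
                count=int(weights[i]),
                haplotype_indices=list(observed_of[i]),
                sequence=haps.haplotypes[observed_of[i][0]],
            )
        else:
            name = f"mv{i - n_observed + 1}"
            graph.add_node(name, observed=False, count=0)
        names[i] = name

    pairs = sorted(
        ((int(dist[i, j]), i, j) for i, j in itertools.combinations(keep_sorted, 2)),
        key=lambda t: (t[0], names[t[1]], names[t[2]]),
    )
    # Kruskal-style union-of-MSTs: an edge belongs to some MST iff its ends
    # are disconnected using strictly shorter edges only
    parent = {i: i for i in keep_sorted}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    k = 0
    while k < len(pairs):
        d = pairs[k][0]
        block = []
        while k < len(pairs) and pairs[k][0] == d:
            block.append(pairs[k])
            k += 1
        added = []
        for d_, i, j in block:
            if find(i) != find(j):
                cols = _mutated_columns(rec, V[i], V[j])
                graph.add_edge(names[i], names[j], weight=int(d_), columns=cols)
                added.append((i, j))
        for i, j in added:
            parent[find(i)] = find(j)

    net = HaploNetwork(
        graph=graph, recoding=rec, haplotypes=haps, r=r,
        observed_nodes=[names[i] for i in keep_sorted if i < n_observed],
        median_nodes=[names[i] for i in keep_sorted if i >= n_observed],
    )
    return net


def _majority(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return ((a.astype(np.int16) + b + c) >= 2).astype(np.uint8)


def _mutated_columns(rec: BinaryRecoding, a: np.ndarray, b: np.ndarray) -> list[int]:
    return sorted({rec.columns[k] for k in np.flatnonzero(a != b)})


def network_components(net: HaploNetwork, cut: float) -> list[set[str]]:
    """Connected components of observed haplotypes after removing edges
    heavier than ``cut`` mutational steps."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    g.add_edges_from(
        (u, v) for u, v, d in net.graph.edges(data=True) if d["weight"] <= cut
    )
    comps = []
    for comp in nx.connected_components(g):
        obs = {n for n in comp if net.graph.nodes[n].get("observed")}
        if obs:
            comps.append(obs)
    # merge components connected only through median nodes is already handled
    return sorted(comps, key=lambda s: sorted(s))


def write_gml(net: HaploNetwork, path) -> None:
    g = net.graph.copy()
    for _, _, d in g.edges(data=True):
        d["columns"] = ",".join(str(c) for c in d["columns"])
    for _, d in g.nodes(data=True):
        if "haplotype_indices" in d:
            d["haplotype_indices"] = ",".join(str(i) for i in d["haplotype_indices"])
        d["observed"] = int(d.get("observed", False))
    nx.write_gml(g, str(path))


def write_dot(net: HaploNetwork, path) -> None:
    lines = ["graph haplonetwork {"]
    for n, d in sorted(net.graph.nodes(data=True)):
        shape = "circle" if d.get("observed") else "point"
        lines.append(f'  "{n}" [shape={shape}, count={d.get("count", 0)}];')
    for u, v, d in sorted(net.graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [label="{d["weight"]}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
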