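import itertools

import numpy as np

from coiphylo.haplotypes import collapse_haplotypes
from coiphylo.io import Alignment
from coiphylo.network import (
    build_rm_network,
    network_components,
    recode_binary,
)

from conftest import aln_from_strings


def table_from_strings(seqs, counts=None):
    expanded = []
    for i, s in enumerate(seqs):
        expanded.extend([s] * (counts[i] if counts else 1))
    return collapse_haplotypes(aln_from_strings(expanded))


def random_compatible_instance(rng, max_nodes=8, max_observed=6, max_chars=8):
    """Random perfect-phylogeny binary data with known parsimony length.

    Characters are tree edges (possibly duplicated); with every leaf
    observed each character is non-constant, so any network connecting the
    observed haplotypes needs at least one mutation per character.
    """
    while True:
        m = int(rng.integers(4, max_nodes + 1))
        edges = [(i, int(rng.integers(0, i))) for i in range(1, m)]
        deg = np.zeros(m, int)
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        leaves = [i for i in range(m) if deg[i] == 1]
        if len(leaves) > max_observed:
            continue
        chars = list(range(len(edges)))
        while len(chars) < max_chars and rng.random() < 0.3:
            chars.append(int(rng.integers(0, len(edges))))
        adj = {}
        for k, (a, b) in enumerate(edges):
            adj.setdefault(a, []).append((b, k))
            adj.setdefault(b, []).append((a, k))
        vec = {0: np.zeros(len(chars), np.uint8)}
        stack, seen = [0], {0}
        while stack:
            u = stack.pop()
            for v, e in adj[u]:
                if v in seen:
                    continue
                seen.add(v)
                w = vec[u].copy()
                for c, ci in enumerate(chars):
                    if ci == e:
                        w[c] ^= 1
                vec[v] = w
                stack.append(v)
        internals = [i for i in range(m) if i not in leaves]
        rng.shuffle(internals)
        extra = internals[: max(0, max_observed - len(leaves))]
        obs = (leaves + extra)[:max_observed]
        if len(obs) >= 2:
            return [vec[i] for i in obs], len(chars)


def binary_to_table(vectors):
    seqs = ["".join("AG"[int(b)] for b in v) for v in vectors]
    return table_from_strings(seqs)


class TestRecodeBinary:
    def test_biallelic_column_single_character(self):
        table = table_from_strings(["AAA", "AGA"])
        rec = recode_binary(table)
        assert rec.n_characters == 1
        assert rec.columns == [1]

    def test_triallelic_column_splits(self):
        table = table_from_strings(["AAA", "AGA", "ATA", "AAA"], counts=[2, 1, 1, 1])
        rec = recode_binary(table)
        assert rec.n_characters == 2
        assert rec.consensus == ["A", "A"]
        assert sorted(rec.states) == ["G", "T"]

    def test_width_is_states_minus_one_per_variable_column(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            n, L = int(rng.integers(2, 7)), 12
            mat = rng.integers(0, 4, size=(n, L)).astype(np.uint8)
            aln = Alignment([f"s{i}" for i in range(n)], mat)
            table = collapse_haplotypes(aln)
            hap_mat = table.matrix()
            expected = sum(
                max(0, len(set(hap_mat[:, j].tolist())) - 1) for j in range(L)
            )
            assert recode_binary(table).n_characters == expected


class TestBuildNetwork:
    def test_single_haplotype_trivial_network(self):
        net = build_rm_network(table_from_strings(["ACGT"]))
        assert len(net.graph.nodes) == 1
        assert len(net.graph.edges) == 0

    def test_two_haplotypes_single_weighted_edge(self):
        net = build_rm_network(table_from_strings(["AAAA", "GGGG"]))
        assert net.median_nodes == []
        edges = net.edges_table()
        assert len(edges) == 1 and edges[0]["weight"] == 4

    def test_conflict_triple_gets_median(self):
        # binary 110/101/011: the median 111 turns a 4-step chain into a
        # 3-edge star through one inferred vector
        net = build_rm_network(table_from_strings(["GGA", "GAG", "AGG"]))
        assert len(net.median_nodes) == 1
        weights = sorted(d["weight"] for _, _, d in net.graph.edges(data=True))
        assert weights == [1, 1, 1]
        assert net.total_length() == 3

    def test_compatible_data_reaches_parsimony_bound(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            vectors, n_chars = random_compatible_instance(rng)
            net = build_rm_network(binary_to_table(vectors))
            assert net.total_length() == n_chars

    def test_exact_steiner_brute_force_tiny(self):
        """Network length equals the exact Steiner minimum on tiny instances."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            h = int(rng.integers(3, 5))
            c = 4
            vecs = set()
            while len(vecs) < h:
                vecs.add(tuple(rng.integers(0, 2, size=c).tolist()))
            vectors = [np.array(v, np.uint8) for v in vecs]
            net = build_rm_network(binary_to_table(vectors))
            best = _steiner_minimum(vectors, c)
            assert net.total_length() == best

    def test_length_never_exceeds_observed_mst(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            c = int(rng.integers(2, 8))
            h = int(rng.integers(2, min(2**c, 6) + 1))
            vecs = set()
            while len(vecs) < h:
                vecs.add(tuple(rng.integers(0, 2, size=c).tolist()))
            vectors = [np.array(v, np.uint8) for v in vecs]
            net = build_rm_network(binary_to_table(vectors))
            assert net.total_length() <= _mst_len(vectors)
            # connectivity over observed haplotypes
            import networkx as nx

            assert nx.is_connected(net.graph)


def _mst_len(vectors):
    import networkx as nx

    g = nx.Graph()
    for i, j in itertools.combinations(range(len(vectors)), 2):
        g.add_edge(i, j, weight=int((vectors[i] != vectors[j]).sum()))
    if len(vectors) == 1:
        return 0
    t = nx.minimum_spanning_tree(g)
    return sum(d["weight"] for _, _, d in t.edges(data=True))


def _steiner_minimum(vectors, c):
    """Exact Steiner tree length in the c-cube by exhaustive augmentation."""
    universe = [np.array(v, np.uint8) for v in itertools.product([0, 1], repeat=c)]
    obs_keys = {tuple(v.tolist()) for v in vectors}
    candidates = [v for v in universe if tuple(v.tolist()) not in obs_keys]
    best = _mst_len(vectors)
    # adding more than h-2 Steiner points never helps in a tree
    for k in range(1, max(1, len(vectors) - 1)):
        for extra in itertools.combinations(range(len(candidates)), k):
            aug = vectors + [candidates[e] for e in extra]
            best = min(best, _mst_len(aug))
    return best


class TestComponents:
    def test_cut_extremes(self):
        net = build_rm_network(table_from_strings(["AAAA", "GGGG", "GGGA"]))
        one = network_components(net, cut=10)
        assert len(one) == 1
        isolated = network_components(net, cut=0)
        assert len(isolated) == 3

    def test_two_clade_dataset_splits_in_two(self, small_two_clade):
        ds = small_two_clade
        from coiphylo.haplotypes import collapse_haplotypes as collapse

        table = collapse(ds.alignment)
        net = build_rm_network(table)
        comps = network_components(net, cut=5)
        assert len(comps) == 2
        # components congruent with simulated clade labels
        hap_clade = {}
        for h, members in enumerate(table.members):
            clades = {ds.clades[m] for m in members}
            assert len(clades) == 1
            hap_clade[f"H{h + 1}"] = clades.pop()
        comp_clades = [{hap_clade[n] for n in comp} for comp in comps]
        assert all(len(cc) == 1 for cc in comp_clades)
        assert {cc.pop() for cc in comp_clades} == {"A", "B"}
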