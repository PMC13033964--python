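import itertools

import numpy as np
import pytest

from coiphylo.amova import AmovaDesign, amova
from coiphylo.distances import DistanceMatrix


def naive_amova_components(D2, groups, clades):
    """Brute-force expected-mean-squares oracle.

    Sums of squares by explicit loops over pairs; EMS coefficients from
    their definitional sums; components solved with a triangular linear
    system.  Everything written independently of the implementation.
    """
    ids = list(D2.keys())
    N = len(ids)
    group_names = sorted({groups[i] for i in ids})
    clade_names = sorted({clades[g] for g in group_names})
    G, C = len(group_names), len(clade_names)

    def ss_of(sets):
        total = 0.0
        for members in sets:
            for a, b in itertools.combinations(members, 2):
                total += D2[a][b] / len(members)
        return total

    group_sets = [[i for i in ids if groups[i] == g] for g in group_names]
    clade_sets = [
        [i for i in ids if clades[groups[i]] == c] for c in clade_names
    ]
    ss_total = ss_of([ids])
    ss_wg = ss_of(group_sets)
    ss_wc = ss_of(clade_sets)
    ss_ag = ss_wc - ss_wg
    ss_ac = ss_total - ss_wc

    n_g = {g: len(s) for g, s in zip(group_names, group_sets)}
    n_c = {c: len(s) for c, s in zip(clade_names, clade_sets)}
    A = sum(sum(n_g[g] ** 2 for g in group_names if clades[g] == c) / n_c[c]
            for c in clade_names)
    n1 = (N - A) / (G - C)
    n2 = (A - sum(n_g[g] ** 2 for g in group_names) / N) / (C - 1)
    n3 = (N - sum(n_c[c] ** 2 for c in clade_names) / N) / (C - 1)

    ms = np.array([ss_ac / (C - 1), ss_ag / (G - C), ss_wg / (N - G)])
    # E[MS] = M @ (sigma_a, sigma_b, sigma_c)
    M = np.array([[n3, n2, 1.0], [0.0, n1, 1.0], [0.0, 0.0, 1.0]])
    sigma = np.linalg.solve(M, ms)
    return {
        "ss": (ss_ac, ss_ag, ss_wg),
        "df": (C - 1, G - C, N - G),
        "sigma": tuple(sigma),
    }


def random_design(rng):
    n_clades = int(rng.integers(2, 4))
    groups = {}
    clades = {}
    gi = 0
    for c in range(n_clades):
        # at least one clade carries two groups so the among-group stratum
        # has degrees of freedom
        for _ in range(2 if c == 0 else int(rng.integers(1, 3))):
            clades[f"g{gi}"] = f"c{c}"
            gi += 1
    while len(clades) > 6:
        clades.pop(sorted(clades)[-1])
    ids = []
    assignment = {}
    for g in sorted(clades):
        for k in range(int(rng.integers(2, 6))):
            sid = f"{g}_{k}"
            ids.append(sid)
            assignment[sid] = g
    pts = rng.normal(size=(len(ids), 5))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    return ids, D, assignment, clades


class TestVarianceComponents:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            ids, D, groups, clades = random_design(rng)
            n = len(ids)
            if n > 30:
                continue
            dm = DistanceMatrix(ids, D)
            design = AmovaDesign(groups=groups, clades=clades)
            res = amova(dm, design, n_perm=0)
            D2 = {a: {b: D[i, j] ** 2 for j, b in enumerate(ids)}
                  for i, a in enumerate(ids)}
            oracle = naive_amova_components(D2, groups, clades)
            assert res.ss["among_clades"] == pytest.approx(oracle["ss"][0], abs=1e-8)
            assert res.ss["among_groups"] == pytest.approx(oracle["ss"][1], abs=1e-8)
            assert res.ss["within_groups"] == pytest.approx(oracle["ss"][2], abs=1e-8)
            assert res.sigma2["among_clades"] == pytest.approx(oracle["sigma"][0], abs=1e-8)
            assert res.sigma2["among_groups"] == pytest.approx(oracle["sigma"][1], abs=1e-8)
            assert res.sigma2["within_groups"] == pytest.approx(oracle["sigma"][2], abs=1e-8)
            # df identity (C-1) + (G-C) + (N-G) = N-1
            assert sum(res.df.values()) == n - 1
            assert tuple(res.df.values()) == oracle["df"]

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(9)
        ids, D, groups, clades = random_design(rng)
        res = amova(DistanceMatrix(ids, D), AmovaDesign(groups, clades), n_perm=0)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=0.1)

    def test_all_zero_distances_degenerate(self):
        ids = [f"s{i}" for i in range(8)]
        D = DistanceMatrix(ids, np.zeros((8, 8)))
        groups = {sid: f"g{i % 4}" for i, sid in enumerate(ids)}
        clades = {"g0": "c0", "g1": "c0", "g2": "c1", "g3": "c1"}
        res = amova(D, AmovaDesign(groups, clades), n_perm=0)
        assert all(v == 0.0 for v in res.ss.values())
        assert any("degenerate" in n for n in res.notes)


def _two_clade_line_design():
    """6 groups split 2/4; observed split uniquely most extreme."""
    centers = {"g0": 0.0, "g1": 1.0, "g2": 100.0, "g3": 101.0,
               "g4": 102.0, "g5": 103.0}
    clades = {"g0": "A", "g1": "A", "g2": "B", "g3": "B", "g4": "B", "g5": "B"}
    ids, xs, groups = [], [], {}
    for g, c in centers.items():
        for k in range(3):
            sid = f"{g}_{k}"
            ids.append(sid)
            xs.append(c + 0.05 * k)
            groups[sid] = g
    xs = np.array(xs)
    D = np.abs(xs[:, None] - xs[None, :])
    return DistanceMatrix(ids, D), AmovaDesign(groups, clades)


class TestPermutationTests:
    def test_among_clade_exhaustive_enumeration_gives_one_fifteenth(self):
        """With 6 groups split 2/4 there are C(6,2)=15 distinct clade
        assignments, so a uniquely most extreme observed split has p=1/15."""
        D, design = _two_clade_line_design()
        res = amova(D, design, n_perm=1000, seed=0)
        assert res.exhaustive["among_clades"]
        assert res.n_permutations["among_clades"] == 15
        assert res.p_values["among_clades"] == pytest.approx(1 / 15)

    def test_structured_data_among_groups_significant(self):
        D, design = _two_clade_line_design()
        res = amova(D, design, n_perm=199, seed=1)
        assert res.p_values["among_groups"] <= 0.05

    def test_same_seed_reproducible(self):
        D, design = _two_clade_line_design()
        r1 = amova(D, design, n_perm=99, seed=7)
        r2 = amova(D, design, n_perm=99, seed=7)
        assert r1.p_values == r2.p_values

    def test_single_group_per_clade_flagged(self):
        ids = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(D, 0)
        groups = {sid: ("g0" if i < 3 else "g1") for i, sid in enumerate(ids)}
        clades = {"g0": "c0", "g1": "c1"}
        res = amova(DistanceMatrix(ids, (D + D.T) / 2),
                    AmovaDesign(groups, clades), n_perm=0)
        assert any("Phi_SC" in note for note in res.notes)

    def test_unknown_id_rejected(self):
        D, design = _two_clade_line_design()
        bad = AmovaDesign(groups={k: v for k, v in list(design.groups.items())[:-1]},
                          clades=design.clades)
        with pytest.raises(ValueError, match="without group"):
            amova(D, bad, n_perm=0)


def test_design_validation():
    with pytest.raises(ValueError, match="at least two clades"):
        AmovaDesign(groups={"a": "g0"}, clades={"g0": "c0"})
    with pytest.raises(ValueError, match="without a clade"):
        AmovaDesign(groups={"a": "g0", "b": "g1"}, clades={"g0": "c0"})
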