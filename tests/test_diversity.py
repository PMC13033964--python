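import itertools
import math

import numpy as np
import pytest

from coiphylo.diversity import (
    diversity_metrics,
    exhaustive_rarefaction,
    rarefied_metrics,
    tajima_coefficients,
    tajimas_d,
)
from coiphylo.io import Alignment

from conftest import aln_from_strings


def tajima_oracle(n, S, k_bar):
    """Independent re-derivation of D from the published coefficient chain."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_bar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))


def mean_pairwise_differences(aln):
    """Brute-force mean pairwise difference count."""
    tot, cnt = 0, 0
    for i, j in itertools.combinations(range(aln.n), 2):
        tot += int((aln.matrix[i] != aln.matrix[j]).sum())
        cnt += 1
    return tot / cnt


class TestDiversityMetrics:
    def test_monomorphic(self):
        m = diversity_metrics(aln_from_strings(["ACGT"] * 5))
        assert (m.S, m.H, m.Hd, m.pi) == (0, 1, 0.0, 0.0)

    def test_all_distinct_singletons_give_hd_one(self):
        seqs = ["AAAA", "AAAC", "AACA", "ACAA", "CAAA"]
        m = diversity_metrics(aln_from_strings(seqs))
        assert m.H == 5
        assert m.Hd == pytest.approx(1.0)

    def test_pis_requires_two_alleles_twice(self):
        # column 0: two alleles each x2 (informative); column 3: singleton allele
        aln = aln_from_strings(["AAAA", "AAAA", "CAAA", "CAAT"])
        m = diversity_metrics(aln)
        assert m.S == 2
        assert m.PIS == 1

    def test_single_sequence_flags_undefined(self):
        m = diversity_metrics(aln_from_strings(["ACGT"]))
        assert m.Hd is None and m.pi is None

    def test_pi_equals_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n, L = int(rng.integers(2, 8)), 20
            mat = rng.integers(0, 4, size=(n, L)).astype(np.uint8)
            aln = Alignment([f"s{i}" for i in range(n)], mat)
            m = diversity_metrics(aln)
            assert m.pi == pytest.approx(mean_pairwise_differences(aln) / L)

    def test_relabelling_and_column_permutation_invariance(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 4, size=(6, 15)).astype(np.uint8)
        aln = Alignment([f"s{i}" for i in range(6)], mat)
        m1 = diversity_metrics(aln)
        perm_rows = rng.permutation(6)
        perm_cols = rng.permutation(15)
        aln2 = Alignment([f"t{i}" for i in range(6)],
                         mat[perm_rows][:, perm_cols])
        m2 = diversity_metrics(aln2)
        assert (m1.S, m1.PIS, m1.H) == (m2.S, m2.PIS, m2.H)
        assert m1.Hd == pytest.approx(m2.Hd)
        assert m1.pi == pytest.approx(m2.pi)


class TestTajimasD:
    def test_undefined_when_no_segregating_sites(self):
        res = tajimas_d(aln_from_strings(["ACGT"] * 6))
        assert res.D is None and res.p_value is None

    def test_small_alignment_matches_oracle(self):
        seqs = ["ACGTACGTAC", "ACGAACGTAC", "ACGAACGTAT", "TCGTACGTAC", "ACGTACGGAC"]
        aln = aln_from_strings(seqs)
        res = tajimas_d(aln)
        from coiphylo.io import variable_sites

        S = len(variable_sites(aln))
        expected = tajima_oracle(aln.n, S, mean_pairwise_differences(aln))
        assert res.D == pytest.approx(expected, abs=1e-10)

    def test_random_alignments_match_oracle(self):
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(60):
            n = int(rng.integers(4, 21))
            L = int(rng.integers(10, 101))
            mat = rng.integers(0, 4, size=(n, L)).astype(np.uint8)
            aln = Alignment([f"s{i}" for i in range(n)], mat)
            res = tajimas_d(aln)
            if res.D is None:
                continue
            expected = tajima_oracle(n, res.S, mean_pairwise_differences(aln))
            assert res.D == pytest.approx(expected, abs=1e-10)
            checked += 1
        assert checked > 40

    def test_p_value_in_unit_interval_and_small_for_extreme_d(self):
        # many singleton mutations on one sequence -> strongly negative D
        base = "A" * 40
        seqs = [base] * 9 + ["C" * 10 + base[10:]]
        res = tajimas_d(aln_from_strings(seqs))
        assert res.D < 0
        assert 0.0 <= res.p_value <= 1.0
        sym = tajimas_d(aln_from_strings(["A" * 40, "C" * 3 + "A" * 37] * 3))
        assert 0.0 <= sym.p_value <= 1.0

    def test_coefficient_chain_values(self):
        c = tajima_coefficients(5)
        assert c["a1"] == pytest.approx(1 + 1 / 2 + 1 / 3 + 1 / 4)
        assert c["b1"] == pytest.approx(6 / 12)


class TestRarefaction:
    def test_k_equal_group_size_reproduces_raw(self, small_two_clade):
        aln = small_two_clade.alignment.subset(small_two_clade.alignment.ids[:8])
        raw = diversity_metrics(aln)
        rar = rarefied_metrics(aln, k=8, R=50, seed=4)
        assert rar.metrics.S == pytest.approx(raw.S)
        assert rar.metrics.H == pytest.approx(raw.H)
        assert rar.metrics.Hd == pytest.approx(raw.Hd)
        assert rar.metrics.pi == pytest.approx(raw.pi)

    def test_same_seed_is_deterministic(self, small_two_clade):
        aln = small_two_clade.alignment.subset(small_two_clade.alignment.ids[:10])
        r1 = rarefied_metrics(aln, k=5, R=300, seed=42)
        r2 = rarefied_metrics(aln, k=5, R=300, seed=42)
        assert r1 == r2

    def test_sampled_agrees_with_exhaustive_enumeration(self):
        seqs = ["ACGTACGTAC", "ACGAACGTAC", "ACGAACGTAT", "TCGTACGTAC",
                "ACGTACGGAC"]
        aln = aln_from_strings(seqs)
        exact = exhaustive_rarefaction(aln, k=4)
        R = 20_000
        rar = rarefied_metrics(aln, k=4, R=R, seed=0, with_tajima=False)
        # MC standard error from the 5 possible subset values
        for attr in ("S", "H", "Hd", "pi"):
            vals = []
            for idx in itertools.combinations(range(5), 4):
                sub = Alignment([aln.ids[i] for i in idx], aln.matrix[list(idx)])
                m = diversity_metrics(sub)
                vals.append(getattr(m, attr))
            se = np.std(vals) / math.sqrt(R)
            assert abs(getattr(rar.metrics, attr) - getattr(exact, attr)) <= \
                max(3 * se, 1e-12)

    def test_subsampled_s_never_exceeds_raw(self, small_two_clade):
        ds = small_two_clade
        for group in ("NEA", "AFR", "MED"):
            ids = [s for s in ds.alignment.ids if ds.groups[s] == group]
            sub = ds.alignment.subset(ids)
            raw = diversity_metrics(sub)
            rar = rarefied_metrics(sub, k=max(2, len(ids) - 4), R=100, seed=1,
                                   with_tajima=False)
            assert rar.metrics.S <= raw.S + 1e-12

    def test_k_larger_than_group_rejected(self):
        aln = aln_from_strings(["ACGT"] * 4)
        with pytest.raises(ValueError, match="k=5"):
            rarefied_metrics(aln, k=5, R=10)


def test_expansion_demography_gives_negative_median_d():
    """Star-like genealogies from exponential growth depress Tajima's D."""
    from coiphylo.simulate import SimulationConfig, simulate_dataset

    Ds = []
    for rep in range(60):
        cfg = SimulationConfig(
            seed=7000 + rep, sample_sizes={"NEA": 20}, group_clade={"NEA": "A"},
            subclade_split_times={"A": 1.5e6}, growth_rate=1e-4,
        )
        ds = simulate_dataset(cfg)
        res = tajimas_d(ds.alignment)
        if res.D is not None:
            Ds.append(res.D)
    assert len(Ds) > 30
    assert np.median(Ds) < 0
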