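"""Diversity metrics, Tajima's D, and subsampling (rarefaction) normalisation.

Metrics follow the conventions of the ape/pegas toolkit lineage:

* ``S``   — segregating (polymorphic) sites;
* ``PIS`` — parsimony-informative sites (≥2 alleles each in ≥2 sequences);
* ``H``   — number of distinct haplotypes;
* ``Hd``  — haplotype diversity, (n/(n-1))·(1 - Σ pᵢ²);
* ``π``   — nucleotide diversity, the mean pairwise p-distance per site
            (a K2P-corrected variant is available behind a flag).

Tajima's D contrasts π-based and S-based estimates of θ; its p-value uses
the beta-distribution approximation of the statistic's null density.
Unequal group sizes are normalised by repeated subsampling without
replacement to a common size k, reporting the mean of every metric.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist

from .io import GAP, Alignment, variable_sites

__all__ = [
    "DiversityMetrics",
    "NeutralityResult",
    "RarefiedMetrics",
    "diversity_metrics",
    "tajimas_d",
    "tajima_coefficients",
    "rarefied_metrics",
    "parsimony_informative_sites",
]


@dataclass(frozen=True)
class DiversityMetrics:
    n: int
    S: float
    PIS: float
    H: float
    Hd: float | None
    pi: float | None

    def as_tuple(self) -> tuple:
        return (self.n, self.S, self.PIS, self.H, self.Hd, self.pi)


@dataclass(frozen=True)
class NeutralityResult:
    D: float | None
    p_value: float | None
    S: int
    n: int
    k_bar: float | None = None
    coefficients: dict | None = None

    @property
    def defined(self) -> bool:
        return self.D is not None


@dataclass(frozen=True)
class RarefiedMetrics:
    k: int
    R: int
    seed: int | None
    metrics: DiversityMetrics
    D: float | None
    D_p_value: float | None
    n_undefined_D: int = 0


def parsimony_informative_sites(aln: Alignment) -> list[int]:
    """Columns with at least two bases each carried by ≥2 sequences."""
    mat = aln.matrix
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
    return np.flatnonzero((counts >= 2).sum(axis=0) >= 2).tolist()


def _pairwise_diff_stats(mat: np.ndarray) -> tuple[float, float]:
    """(mean pairwise difference count, mean pairwise p-distance per site).

    Pairwise deletion over unambiguous positions; assumes ≥2 rows.
    """
    n = mat.shape[0]
    tot_diff = 0.0
    tot_p = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            shared = (a < GAP) & (b < GAP)
            ns = int(shared.sum())
            if ns == 0:
                continue
            diff = int((a[shared] != b[shared]).sum())
            tot_diff += diff
            tot_p += diff / ns
            npairs += 1
    if npairs == 0:
        return math.nan, math.nan
    return tot_diff / npairs, tot_p / npairs


def diversity_metrics(aln: Alignment, *, corrected_pi: bool = False) -> DiversityMetrics:
    """S, PIS, H, Hd and π for one (sub)alignment.

    ``corrected_pi`` switches π from the p-distance convention to a mean
    pairwise K2P distance, for sensitivity analyses.
    """
    if aln.n == 0:  # pragma: no cover - Alignment forbids this
        raise ValueError("empty alignment")
    S = len(variable_sites(aln))
    PIS = len(parsimony_informative_sites(aln))
    # haplotype census on raw coded rows (complete data expected here)
    keys = {}
    for i in range(aln.n):
        k = aln.matrix[i].tobytes()
        keys[k] = keys.get(k, 0) + 1
    H = len(keys)
    if aln.n == 1:
        return DiversityMetrics(n=1, S=S, PIS=PIS, H=H, Hd=None, pi=None)
    n = aln.n
    freqs = np.array(list(keys.values())) / n
    Hd = (n / (n - 1)) * (1.0 - float(np.sum(freqs**2)))
    if corrected_pi:
        from .distances import distance_matrix

        D = distance_matrix(aln)
        pi = float(D.condensed().mean())
    else:
        _, pi = _pairwise_diff_stats(aln.matrix)
    return DiversityMetrics(n=n, S=S, PIS=PIS, H=H, Hd=Hd, pi=pi)


def tajima_coefficients(n: int) -> dict:
    """The a₁…e₂ coefficient chain of Tajima's D for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(aln: Alignment) -> NeutralityResult:
    """Tajima's D with its beta-approximation p-value.

    Undefined (flagged, not an exception) when S = 0 or n < 4.  The p-value
    rescales D onto its theoretical [Dmin, Dmax] support and folds both
    tails of the fitted beta density.
    """
    n = aln.n
    S = len(variable_sites(aln))
    if n < 4 or S == 0:
        return NeutralityResult(D=None, p_value=None, S=S, n=n)
    coef = tajima_coefficients(n)
    k_bar, _ = _pairwise_diff_stats(aln.matrix)
    a1, e1, e2 = coef["a1"], coef["e1"], coef["e2"]
    var = e1 * S + e2 * S * (S - 1)
    D = (k_bar - S / a1) / math.sqrt(var)

    # beta approximation on the support [Dmin, Dmax]
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    tmp1 = 1.0 + dmin * dmax
    tmp2 = dmax - dmin
    a = -tmp1 * dmax / tmp2
    b = tmp1 * dmin / tmp2
    x = (D - dmin) / tmp2
    p = float(beta_dist.cdf(x, b, a))
    p = 2.0 * p if p < 0.5 else 2.0 * (1.0 - p)
    p = min(max(p, 0.0), 1.0)
    return NeutralityResult(D=D, p_value=p, S=S, n=n, k_bar=k_bar, coefficients=coef)


def rarefied_metrics(
    aln: Alignment,
    k: int,
    R: int = 10_000,
    seed: int | None = 0,
    *,
    with_tajima: bool = True,
) -> RarefiedMetrics:
    """Mean diversity metrics over R subsamples of size k without replacement.

    Repeated draws of the same index set reuse the cached evaluation, so
    exhaustive-like cases (small groups) cost only one metric evaluation per
    distinct subset.  Tajima's D is averaged over the replicates where it is
    defined; the count of undefined replicates is reported.
    """
    if not 2 <= k <= aln.n:
        raise ValueError(f"subsample size k={k} must be in [2, {aln.n}]")
    rng = np.random.default_rng(seed)
    cache: dict[tuple, tuple] = {}
    sums = np.zeros(5)  # S, PIS, H, Hd, pi
    d_sum = 0.0
    p_sum = 0.0
    d_count = 0
    for _ in range(R):
        idx = tuple(sorted(rng.choice(aln.n, size=k, replace=False).tolist()))
        if idx not in cache:
            sub = Alignment([aln.ids[i] for i in idx], aln.matrix[list(idx)])
            m = diversity_metrics(sub)
            if with_tajima:
                t = tajimas_d(sub)
                cache[idx] = (m, t.D, t.p_value)
            else:
                cache[idx] = (m, None, None)
        m, D, p = cache[idx]
        sums += np.array([m.S, m.PIS, m.H, m.Hd if m.Hd is not None else 0.0,
                          m.pi if m.pi is not None else 0.0])
        if D is not None:
            d_sum += D
            p_sum += p
            d_count += 1
    mean = sums / R
    metrics = DiversityMetrics(n=k, S=mean[0], PIS=mean[1], H=mean[2],
                               Hd=mean[3], pi=mean[4])
    return RarefiedMetrics(
        k=k, R=R, seed=seed, metrics=metrics,
        D=(d_sum / d_count) if d_count else None,
        D_p_value=(p_sum / d_count) if d_count else None,
        n_undefined_D=R - d_count,
    )


def exhaustive_rarefaction(aln: Alignment, k: int) -> DiversityMetrics:
    """Exact mean over all C(n, k) subsets — test-scale oracle companion."""
    sums = np.zeros(5)
    count = 0
    for idx in itertools.combinations(range(aln.n), k):
        sub = Alignment([aln.ids[i] for i in idx], aln.matrix[list(idx)])
        m = diversity_metrics(sub)
        sums += np.array([m.S, m.PIS, m.H, m.Hd or 0.0, m.pi or 0.0])
        count += 1
    mean = sums / count
    return DiversityMetrics(n=k, S=mean[0], PIS=mean[1], H=mean[2], Hd=mean[3], pi=mean[4])
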