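"""Kimura two-parameter (K2P) distances and group-level summaries.

The K2P model corrects observed divergence for multiple hits while letting
transitions (A↔G, C↔T) and transversions accrue at separate rates:

    d = -1/2 · ln(1 - 2P - Q) - 1/4 · ln(1 - 2Q)

with P and Q the transition and transversion proportions over the positions
both sequences observe unambiguously (pairwise deletion).  Distances are
kept in substitutions/site internally; percentages only appear in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GAP, Alignment

__all__ = [
    "PairwiseDistance",
    "DistanceMatrix",
    "SaturationError",
    "IncomparablePairError",
    "k2p_distance",
    "k2p_from_proportions",
    "distance_matrix",
    "group_distance_summary",
]


class SaturationError(ValueError):
    """The K2P logarithm argument is ≤ 0: divergence beyond correctability."""

    def __init__(self, P: float, Q: float, pair: tuple[str, str] | None = None):
        self.P, self.Q, self.pair = P, Q, pair
        where = f" for pair {pair}" if pair else ""
        super().__init__(
            f"K2P distance saturated{where}: P={P:.4f}, Q={Q:.4f} "
            f"(1-2P-Q={1 - 2 * P - Q:.4f}, 1-2Q={1 - 2 * Q:.4f})"
        )


class IncomparablePairError(ValueError):
    """Two sequences share no mutually observed unambiguous position."""


@dataclass(frozen=True)
class PairwiseDistance:
    P: float
    Q: float
    L_shared: int
    d: float


# transitions: A(0)<->G(2), C(1)<->T(3); i.e. codes differing by exactly 2
def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    shared = (a < GAP) & (b < GAP)
    n = int(shared.sum())
    if n == 0:
        return 0, 0, 0
    da, db = a[shared], b[shared]
    diff = da != db
    ts = int((diff & (np.abs(da.astype(np.int8) - db.astype(np.int8)) == 2)).sum())
    tv = int(diff.sum()) - ts
    return ts, tv, n


def k2p_from_proportions(P: float, Q: float) -> float:
    """Evaluate the K2P formula; raises :class:`SaturationError` at the boundary."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(P, Q)
    return -0.5 * log(w1) - 0.25 * log(w2)


def k2p_distance(a: np.ndarray | str, b: np.ndarray | str, *,
                 ids: tuple[str, str] | None = None) -> PairwiseDistance:
    """K2P distance between two coded rows (or raw sequence strings)."""
    from .io import encode_sequence

    if isinstance(a, str):
        a = encode_sequence(a)
    if isinstance(b, str):
        b = encode_sequence(b)
    ts, tv, n = _pq_counts(np.asarray(a), np.asarray(b))
    if n == 0:
        raise IncomparablePairError(
            f"no mutually observed unambiguous positions{f' for {ids}' if ids else ''}"
        )
    P, Q = ts / n, tv / n
    try:
        d = k2p_from_proportions(P, Q)
    except SaturationError:
        raise SaturationError(P, Q, pair=ids) from None
    return PairwiseDistance(P=P, Q=Q, L_shared=n, d=d)


class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample ids."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(values < 0):
            raise ValueError("distances must be non-negative")
        self.ids = list(ids)
        self.values = values
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self._index[pair[0]], self._index[pair[1]]
        return float(self.values[i, j])

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{v:.8f}" for v in self.values[i])
                fh.write(f"{sid:<12s}{row}\n")


def distance_matrix(aln: Alignment, *, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix (K2P or uncorrected p) with pairwise deletion.

    Identical rows are deduplicated internally, so cost scales with the
    number of distinct sequences rather than the number of samples.
    """
    keys = [aln.matrix[i].tobytes() for i in range(aln.n)]
    uniq: dict[bytes, int] = {}
    rep_rows: list[int] = []
    for i, k in enumerate(keys):
        if k not in uniq:
            uniq[k] = len(rep_rows)
            rep_rows.append(i)
    u_idx = np.array([uniq[k] for k in keys])
    U = len(rep_rows)
    sub = np.zeros((U, U))
    for a in range(U):
        ra = aln.matrix[rep_rows[a]]
        for b in range(a + 1, U):
            rb = aln.matrix[rep_rows[b]]
            ts, tv, n = _pq_counts(ra, rb)
            if n == 0:
                raise IncomparablePairError(
                    f"pair ({aln.ids[rep_rows[a]]!r}, {aln.ids[rep_rows[b]]!r}) "
                    "shares no observed positions"
                )
            P, Q = ts / n, tv / n
            if model == "p":
                d = P + Q
            else:
                try:
                    d = k2p_from_proportions(P, Q)
                except SaturationError:
                    raise SaturationError(
                        P, Q, pair=(aln.ids[rep_rows[a]], aln.ids[rep_rows[b]])
                    ) from None
            sub[a, b] = sub[b, a] = d
    return DistanceMatrix(list(aln.ids), sub[np.ix_(u_idx, u_idx)])


def _pair_indicators(aln: Alignment, pairs: list[tuple[int, int]]):
    """Per-pair per-column transition/transversion/valid indicators."""
    L = aln.length
    ts = np.zeros((len(pairs), L), dtype=np.int8)
    tv = np.zeros((len(pairs), L), dtype=np.int8)
    ok = np.zeros((len(pairs), L), dtype=np.int8)
    for k, (i, j) in enumerate(pairs):
        a, b = aln.matrix[i], aln.matrix[j]
        shared = (a < GAP) & (b < GAP)
        diff = shared & (a != b)
        is_ts = diff & (np.abs(a.astype(np.int8) - b.astype(np.int8)) == 2)
        ok[k] = shared
        ts[k] = is_ts
        tv[k] = diff & ~is_ts
    return ts, tv, ok


def group_distance_summary(
    aln: Alignment,
    partition: dict[str, str],
    *,
    n_boot: int = 1000,
    seed: int | None = 0,
    within: bool = True,
) -> pd.DataFrame:
    """Mean K2P distance between (and optionally within) groups, with a
    bootstrap-over-sites standard error.

    For each ordered group pair the mean is taken over all cross-group
    sequence pairs; the SE is the standard deviation of that mean over
    ``n_boot`` resamplings of alignment columns with replacement (the MEGA
    convention for distance standard errors).  Returns a tidy frame with
    columns ``group1 group2 mean_d se n_pairs`` in substitutions/site.
    """
    labels = sorted(set(partition.values()))
    members = {g: [sid for sid in aln.ids if partition.get(sid) == g] for g in labels}
    for g in labels:
        if not members[g]:
            raise ValueError(f"group {g!r} has no members in the alignment")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g1 in enumerate(labels):
        for g2 in labels[gi if within else gi + 1:]:
            if g1 == g2:
                idx = [aln.index_of(s) for s in members[g1]]
                pairs = [(idx[a], idx[b]) for a in range(len(idx))
                         for b in range(a + 1, len(idx))]
            else:
                idx1 = [aln.index_of(s) for s in members[g1]]
                idx2 = [aln.index_of(s) for s in members[g2]]
                pairs = [(i, j) for i in idx1 for j in idx2]
            if not pairs:
                continue
            ts, tv, ok = _pair_indicators(aln, pairs)
            with np.errstate(divide="ignore", invalid="ignore"):
                P = ts.sum(axis=1) / ok.sum(axis=1)
                Q = tv.sum(axis=1) / ok.sum(axis=1)
            mean_d = float(np.mean([k2p_from_proportions(p, q) for p, q in zip(P, Q)]))
            # bootstrap columns: multinomial weights over sites
            W = rng.multinomial(aln.length, np.full(aln.length, 1 / aln.length),
                                size=n_boot).T.astype(np.float64)  # (L, n_boot)
            tsw = ts.astype(np.float64) @ W  # (pairs, n_boot)
            tvw = tv.astype(np.float64) @ W
            okw = ok.astype(np.float64) @ W
            with np.errstate(divide="ignore", invalid="ignore"):
                Pw = tsw / okw
                Qw = tvw / okw
                w1 = 1.0 - 2.0 * Pw - Qw
                w2 = 1.0 - 2.0 * Qw
                dw = np.where((w1 > 0) & (w2 > 0),
                              -0.5 * np.log(np.maximum(w1, 1e-300))
                              - 0.25 * np.log(np.maximum(w2, 1e-300)),
                              np.nan)
            import warnings

            with warnings.catch_warnings():
                # replicates where every pair saturated yield empty slices
                warnings.simplefilter("ignore", RuntimeWarning)
                rep_means = np.nanmean(dw, axis=0)
                se = float(np.nanstd(rep_means, ddof=1))
            rows.append({"group1": g1, "group2": g2, "mean_d": mean_d,
                         "se": se, "n_pairs": len(pairs)})
    return pd.DataFrame(rows)
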