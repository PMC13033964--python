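"""Two-level hierarchical AMOVA on squared distances with permutation tests.

Individuals are nested in geographic groups, groups in clades.  Sums of
squares follow the distance-based decomposition in which the SS of a set of
sequences equals the sum of its squared pairwise distances divided by the
set size.  Variance components (σ²_a among clades, σ²_b among groups within
clades, σ²_c within groups) are solved from the expected mean squares with
the standard unequal-sample-size coefficients, and Φ-statistics are formed
from them:

    Φ_CT = σ²_a / σ²_tot       Φ_SC = σ²_b / (σ²_b + σ²_c)
    Φ_ST = (σ²_a + σ²_b) / σ²_tot

Significance is assessed by permutation, with a different permutable unit
per stratum: whole groups among clades for Φ_CT (enumerated exhaustively
when the assignment space is small — with six groups split 2/4 there are
only C(6,2) = 15 distinct assignments, so the smallest achievable p-value
is 1/15 ≈ 0.067), individuals among groups within clades for Φ_SC, and
individuals among groups without restriction for Φ_ST.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

__all__ = ["AmovaDesign", "AmovaResult", "amova"]


@dataclass(frozen=True)
class AmovaDesign:
    """id → group and group → clade maps defining the nested design."""

    groups: dict[str, str]
    clades: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.groups.values()) - set(self.clades)
        if missing:
            raise ValueError(f"groups without a clade assignment: {sorted(missing)}")
        if len(set(self.clades.values())) < 2:
            raise ValueError("hierarchical design requires at least two clades")

    def clade_of(self, sid: str) -> str:
        return self.clades[self.groups[sid]]


@dataclass
class AmovaResult:
    df: dict[str, int]
    ss: dict[str, float]
    sigma2: dict[str, float]
    percent: dict[str, float]
    phi: dict[str, float | None]
    p_values: dict[str, float | None]
    n_permutations: dict[str, int]
    exhaustive: dict[str, bool]
    seed: int | None
    negative_components: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "df": self.df, "ss": self.ss, "sigma2": self.sigma2,
            "percent": self.percent, "phi": self.phi, "p_values": self.p_values,
            "n_permutations": self.n_permutations, "exhaustive": self.exhaustive,
            "seed": self.seed, "negative_components": self.negative_components,
            "notes": self.notes,
        }

    def summary(self) -> str:
        lines = [
            f"{'Source of variation':<32}{'df':>5}{'SS':>12}{'sigma2':>10}"
            f"{'%':>8}{'p':>10}",
        ]
        label = {
            "among_clades": "Among clades",
            "among_groups": "Among groups within clades",
            "within_groups": "Within groups",
        }
        for k in ("among_clades", "among_groups", "within_groups"):
            p = self.p_values[k]
            lines.append(
                f"{label[k]:<32}{self.df[k]:>5}{self.ss[k]:>12.2f}"
                f"{self.sigma2[k]:>10.4f}{self.percent[k]:>8.1f}"
                f"{('-' if p is None else format(p, '.4g')):>10}"
            )
        phi = ", ".join(
            f"{k}={'-' if v is None else format(v, '.4f')}" for k, v in self.phi.items()
        )
        lines.append(phi)
        return "\n".join(lines)


def _ss_partition(D2: np.ndarray, sets: list[np.ndarray]) -> float:
    """Σ over sets of (sum of squared distances within the set)/set size."""
    total = 0.0
    for idx in sets:
        if idx.size == 0:
            continue
        sub = D2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * idx.size)
    return total


def _decompose(D2: np.ndarray, group_of: np.ndarray, clade_of_group: np.ndarray,
               n_clades: int, n_groups: int):
    """SS per stratum and variance components for one labelling."""
    N = D2.shape[0]
    all_idx = np.arange(N)
    group_sets = [np.flatnonzero(group_of == g) for g in range(n_groups)]
    clade_sets = [
        np.concatenate([group_sets[g] for g in range(n_groups)
                        if clade_of_group[g] == c] or [np.empty(0, int)])
        for c in range(n_clades)
    ]
    ss_total = _ss_partition(D2, [all_idx])
    ss_within_groups = _ss_partition(D2, group_sets)
    ss_within_clades = _ss_partition(D2, clade_sets)
    ss_among_groups = ss_within_clades - ss_within_groups
    ss_among_clades = ss_total - ss_within_clades

    df_a = n_clades - 1
    df_b = n_groups - n_clades
    df_c = N - n_groups

    n_g = np.array([s.size for s in group_sets], dtype=float)
    n_c = np.array([s.size for s in clade_sets], dtype=float)
    # unequal-size coefficients of the expected mean squares
    sum_ng2_over_nc = sum(
        (n_g[clade_of_group == c] ** 2).sum() / n_c[c]
        for c in range(n_clades) if n_c[c] > 0
    )
    n1 = (N - sum_ng2_over_nc) / df_b if df_b > 0 else np.nan
    n2 = (sum_ng2_over_nc - (n_g**2).sum() / N) / df_a
    n3 = (N - (n_c**2).sum() / N) / df_a

    ms_c = ss_within_groups / df_c if df_c > 0 else np.nan
    sigma_c = ms_c
    if df_b > 0:
        ms_b = ss_among_groups / df_b
        sigma_b = (ms_b - sigma_c) / n1
    else:
        sigma_b = 0.0
    ms_a = ss_among_clades / df_a
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    return (
        {"among_clades": ss_among_clades, "among_groups": ss_among_groups,
         "within_groups": ss_within_groups, "total": ss_total},
        {"among_clades": df_a, "among_groups": df_b, "within_groups": df_c},
        sigma_a, sigma_b, sigma_c,
    )


def _phi_stats(sigma_a, sigma_b, sigma_c):
    tot = sigma_a + sigma_b + sigma_c
    phi_ct = sigma_a / tot if tot != 0 else None
    phi_st = (sigma_a + sigma_b) / tot if tot != 0 else None
    denom = sigma_b + sigma_c
    phi_sc = sigma_b / denom if denom != 0 else None
    return phi_ct, phi_sc, phi_st


def amova(
    D: DistanceMatrix,
    design: AmovaDesign,
    n_perm: int = 10_000,
    seed: int | None = 0,
    *,
    squared: bool = True,
    truncate_negative: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA of a distance matrix under a two-level design.

    ``squared`` applies the Arlequin convention of squaring distances
    before the decomposition.  Negative variance components are reported as
    computed (flagged) unless ``truncate_negative`` zeroes them for the
    percentage calculation.  ``n_perm = 0`` skips the permutation tests.

    The among-clade test permutes whole groups among clades keeping the
    clade sizes (in groups) fixed, enumerating all distinct assignments
    when there are at most ``n_perm`` of them; p is then the fraction of
    assignments at least as extreme as the observed one.  Sampled tests use
    the (hits + 1)/(draws + 1) estimator.
    """
    ids = D.ids
    missing = [i for i in ids if i not in design.groups]
    if missing:
        raise ValueError(f"ids without group assignment: {missing[:5]}")

    group_names = sorted(set(design.groups[i] for i in ids))
    clade_names = sorted(set(design.clades[g] for g in group_names))
    g_index = {g: k for k, g in enumerate(group_names)}
    c_index = {c: k for k, c in enumerate(clade_names)}
    group_of = np.array([g_index[design.groups[i]] for i in ids])
    clade_of_group = np.array([c_index[design.clades[g]] for g in group_names])
    n_groups, n_clades = len(group_names), len(clade_names)
    N = len(ids)

    D2 = D.values**2 if squared else D.values.copy()
    ss, df, sigma_a, sigma_b, sigma_c = _decompose(
        D2, group_of, clade_of_group, n_clades, n_groups
    )
    notes = []
    negative = min(sigma_a, sigma_b, sigma_c) < 0
    if negative:
        notes.append("negative variance component(s) present")
    sa, sb, sc = sigma_a, sigma_b, sigma_c
    if truncate_negative:
        sa, sb, sc = max(sa, 0.0), max(sb, 0.0), max(sc, 0.0)
    tot = sa + sb + sc
    if tot == 0:
        percent = {"among_clades": np.nan, "among_groups": np.nan,
                   "within_groups": np.nan}
        notes.append("degenerate: all variance components are zero")
    else:
        percent = {"among_clades": 100.0 * sa / tot,
                   "among_groups": 100.0 * sb / tot,
                   "within_groups": 100.0 * sc / tot}
    phi_ct, phi_sc, phi_st = _phi_stats(sigma_a, sigma_b, sigma_c)
    single_group_clades = [
        c for k, c in enumerate(clade_names)
        if int((clade_of_group == k).sum()) < 2
    ]
    if len(single_group_clades) == n_clades:
        notes.append("every clade has a single group; Phi_SC undefined")

    p_values = {"among_clades": None, "among_groups": None, "within_groups": None}
    n_used = {"among_clades": 0, "among_groups": 0, "within_groups": 0}
    exhaustive = {"among_clades": False, "among_groups": False,
                  "within_groups": False}

    if n_perm > 0:
        rng = np.random.default_rng(seed)

        # --- among clades: permute whole groups among clades -------------
        sizes = [int((clade_of_group == c).sum()) for c in range(n_clades)]
        n_assign = _count_assignments(n_groups, sizes)
        stat_obs = phi_ct if phi_ct is not None else -np.inf
        if n_assign <= n_perm:
            assignments = _distinct_assignments(n_groups, sizes)
            hits = 0
            for assign in assignments:
                _, _, pa, pb, pc = _decompose(D2, group_of, np.array(assign),
                                              n_clades, n_groups)
                p_ct, _, _ = _phi_stats(pa, pb, pc)
                if p_ct is not None and p_ct >= stat_obs - 1e-12:
                    hits += 1
            p_values["among_clades"] = hits / len(assignments)
            n_used["among_clades"] = len(assignments)
            exhaustive["among_clades"] = True
        else:
            hits = 0
            for _ in range(n_perm):
                assign = _random_assignment(rng, n_groups, sizes)
                _, _, pa, pb, pc = _decompose(D2, group_of, assign,
                                              n_clades, n_groups)
                p_ct, _, _ = _phi_stats(pa, pb, pc)
                if p_ct is not None and p_ct >= stat_obs - 1e-12:
                    hits += 1
            p_values["among_clades"] = (hits + 1) / (n_perm + 1)
            n_used["among_clades"] = n_perm

        # --- among groups within clades: permute individuals within clades
        clade_of_ind = clade_of_group[group_of]
        stat_obs_sc = phi_sc if phi_sc is not None else -np.inf
        hits = 0
        for _ in range(n_perm):
            perm_groups = group_of.copy()
            for c in range(n_clades):
                idx = np.flatnonzero(clade_of_ind == c)
                perm_groups[idx] = group_of[idx][rng.permutation(idx.size)]
            _, _, pa, pb, pc = _decompose(D2, perm_groups, clade_of_group,
                                          n_clades, n_groups)
            _, p_sc, _ = _phi_stats(pa, pb, pc)
            if p_sc is not None and p_sc >= stat_obs_sc - 1e-12:
                hits += 1
        p_values["among_groups"] = (hits + 1) / (n_perm + 1)
        n_used["among_groups"] = n_perm

        # --- within groups: permute individuals without restriction ------
        stat_obs_st = phi_st if phi_st is not None else -np.inf
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            _, _, pa, pb, pc = _decompose(D2, group_of[perm], clade_of_group,
                                          n_clades, n_groups)
            _, _, p_st = _phi_stats(pa, pb, pc)
            if p_st is not None and p_st >= stat_obs_st - 1e-12:
                hits += 1
        p_values["within_groups"] = (hits + 1) / (n_perm + 1)
        n_used["within_groups"] = n_perm

    return AmovaResult(
        df=df,
        ss={k: ss[k] for k in ("among_clades", "among_groups", "within_groups")},
        sigma2={"among_clades": sigma_a, "among_groups": sigma_b,
                "within_groups": sigma_c},
        percent=percent,
        phi={"Phi_CT": phi_ct, "Phi_SC": phi_sc, "Phi_ST": phi_st},
        p_values=p_values,
        n_permutations=n_used,
        exhaustive=exhaustive,
        seed=seed,
        negative_components=negative,
        notes=notes,
    )


def _count_assignments(n_groups: int, sizes: list[int]) -> int:
    """Number of distinct group→clade assignments (multinomial coefficient)."""
    import math

    total = math.factorial(n_groups)
    for s in sizes:
        total //= math.factorial(s)
    return total


def _distinct_assignments(n_groups: int, sizes: list[int]) -> list[tuple[int, ...]]:
    """All distinct group→clade assignments with the given clade sizes."""
    out = []
    groups = list(range(n_groups))

    def rec(remaining: list[int], clade: int, current: dict[int, int]):
        if clade == len(sizes) - 1:
            assign = dict(current)
            for g in remaining:
                assign[g] = clade
            out.append(tuple(assign[g] for g in range(n_groups)))
            return
        # clades are labelled, so plain combinations per clade suffice
        for combo in itertools.combinations(remaining, sizes[clade]):
            nxt = dict(current)
            for g in combo:
                nxt[g] = clade
            rec([g for g in remaining if g not in combo], clade + 1, nxt)

    rec(groups, 0, {})
    return out


def _random_assignment(rng, n_groups: int, sizes: list[int]) -> np.ndarray:
    perm = rng.permutation(n_groups)
    assign = np.empty(n_groups, dtype=int)
    start = 0
    for c, s in enumerate(sizes):
        assign[perm[start:start + s]] = c
        start += s
    return assign
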