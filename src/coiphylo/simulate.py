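"""Synthetic two-clade COI barcode data with known truth labels.

The generator emulates the statistical structure of a deeply split
mitochondrial barcode dataset: two clades separated by several percent of
K2P divergence, one of them essentially panmictic and the other sorted
into geographically restricted subclades; recent-expansion demographies
that push Tajima's D negative; and end-truncated sequences that exercise
the missing-segment imputation.

Genealogies come from the single-locus Kingman coalescent (msprime) with
per-group exponential growth, groups joined at subclade and clade split
times.  Sequences then evolve along the genealogy under a two-parameter
(transition/transversion) substitution process: mutations fall as a
Poisson process at rate μ·L per year on each branch, and each mutation is
a transition with probability κ/(κ+2), otherwise one of the two
transversions equiprobably.  Multiple hits are allowed, so saturation
behaviour is exercised at deep divergences.

Defaults mirror a John Dory-like study design: L = 620 sites, a mutation
rate of 9.94e-9 substitutions/site/year, six groups of sizes 86/26/48/4/16/12
split 2/4 between the clades, and a clade split deep enough to put the
expected inter-clade divergence near 0.074 substitutions/site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import tskit

from .io import Alignment, GeoGroup, SampleMetadata

__all__ = [
    "SimulationConfig",
    "Genealogy",
    "SimulatedDataset",
    "simulate_genealogy",
    "evolve_sequences",
    "truncate_ends",
    "simulate_dataset",
]


def _default_sample_sizes() -> dict[str, int]:
    return {"NEA": 86, "MED": 26, "AFR": 48, "SA": 4, "AUS": 16, "ASI": 12}


def _default_group_clade() -> dict[str, str]:
    return {"NEA": "A", "MED": "A", "AFR": "B", "SA": "B", "AUS": "B", "ASI": "B"}


def _default_subclade_times() -> dict[str, float]:
    # clade A effectively unstructured; clade B subclades sorted ~0.5 Myr ago
    return {"A": 2.0e4, "B": 5.0e5}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic generator.

    Times are in years (one generation per year by default); the mutation
    rate is per site per year; ``kappa`` is the transition/transversion
    rate ratio; ``effective_size`` and ``growth_rate`` may be scalars or
    per-group dicts.
    """

    seed: int
    L: int = 620
    sample_sizes: dict[str, int] = field(default_factory=_default_sample_sizes)
    group_clade: dict[str, str] = field(default_factory=_default_group_clade)
    clade_split_time: float = 3.5e6
    subclade_split_times: dict[str, float] = field(default_factory=_default_subclade_times)
    ancestral_size: float = 2.0e5
    effective_size: float | dict[str, float] = 2.0e5
    growth_rate: float | dict[str, float] = 2.0e-5
    mu: float = 9.94e-9
    kappa: float = 10.0
    truncation_fraction: float = 0.0
    truncation_target_length: int = 408
    generation_time: float = 1.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.sample_sizes.values()):
            bad = [g for g, n in self.sample_sizes.items() if n <= 0]
            raise ValueError(f"sample size must be positive for groups {bad}")
        if set(self.sample_sizes) - set(self.group_clade):
            raise ValueError("every sampled group needs a clade assignment")
        if self.mu < 0 or self.kappa < 0:
            raise ValueError("rates must be non-negative")
        for clade, t in self.subclade_split_times.items():
            if t >= self.clade_split_time:
                raise ValueError(
                    f"subclade split of clade {clade!r} ({t}) must predate "
                    f"the clade split ({self.clade_split_time})"
                )

    def size_of(self, group: str) -> float:
        if isinstance(self.effective_size, dict):
            return self.effective_size[group]
        return self.effective_size

    def growth_of(self, group: str) -> float:
        if isinstance(self.growth_rate, dict):
            return self.growth_rate[group]
        return self.growth_rate


@dataclass(frozen=True)
class Genealogy:
    """A single ultrametric genealogy with branch lengths in years."""

    tree_sequence: tskit.TreeSequence
    sample_ids: list[str]          # per tskit sample node, in node order
    groups: dict[str, str]
    clades: dict[str, str]
    generation_time: float

    @property
    def tree(self) -> tskit.Tree:
        return self.tree_sequence.first()

    def newick(self) -> str:
        labels = {
            node: self.sample_ids[i]
            for i, node in enumerate(self.tree_sequence.samples())
        }
        return self.tree.as_newick(node_labels=labels)

    def tmrca(self) -> float:
        tree = self.tree
        return tree.time(tree.root) * self.generation_time


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: Alignment
    groups: dict[str, str]
    clades: dict[str, str]
    genealogy: Genealogy
    branch_mutations: dict[int, int]     # tskit child node -> mutation count
    config: SimulationConfig
    truth: Alignment | None = None       # pre-truncation alignment

    def truth_alignment(self) -> Alignment:
        return self.truth if self.truth is not None else self.alignment


def simulate_genealogy(cfg: SimulationConfig) -> Genealogy:
    """Coalescent genealogy for the configured group/clade design.

    Each group is a population with its own size and exponential growth
    rate; groups of a clade merge into a constant-size clade ancestor at
    the clade's subclade split time, and the clade ancestors merge at the
    clade split time.  Node times are converted to years via the
    generation time.
    """
    groups = sorted(cfg.sample_sizes)
    clades = sorted(set(cfg.group_clade[g] for g in groups))
    dem = msprime.Demography()
    for g in groups:
        dem.add_population(
            name=g, initial_size=cfg.size_of(g), growth_rate=cfg.growth_of(g)
        )
    for c in clades:
        dem.add_population(name=f"anc_{c}", initial_size=cfg.ancestral_size)
    dem.add_population(name="root", initial_size=cfg.ancestral_size)
    gen = cfg.generation_time
    for c in clades:
        derived = [g for g in groups if cfg.group_clade[g] == c]
        dem.add_population_split(
            time=cfg.subclade_split_times.get(c, 0.0) / gen,
            derived=derived,
            ancestral=f"anc_{c}",
        )
    dem.add_population_split(
        time=cfg.clade_split_time / gen,
        derived=[f"anc_{c}" for c in clades],
        ancestral="root",
    )
    dem.sort_events()
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(cfg.sample_sizes[g], population=g, ploidy=1)
            for g in groups
        ],
        demography=dem,
        ploidy=1,
        random_seed=(cfg.seed % (2**31 - 2)) + 1,
    )
    sample_ids = []
    group_of: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    counters = {g: 0 for g in groups}
    pop_name = {i: p.name for i, p in enumerate(dem.populations)}
    for node in ts.samples():
        g = pop_name[ts.node(node).population]
        counters[g] += 1
        sid = f"{g}_{counters[g]:03d}"
        sample_ids.append(sid)
        group_of[sid] = g
        clade_of[sid] = cfg.group_clade[g]
    return Genealogy(
        tree_sequence=ts, sample_ids=sample_ids, groups=group_of,
        clades=clade_of, generation_time=gen,
    )


# K2P-style mutation targets: for each base, its transition partner and
# the two transversion alternatives (codes A=0, C=1, G=2, T=3)
_TRANSITION = np.array([2, 3, 0, 1])
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def evolve_sequences(gen: Genealogy, cfg: SimulationConfig) -> SimulatedDataset:
    """Evolve sequences down the genealogy under the two-parameter process."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    tree = gen.tree
    ts = gen.tree_sequence
    L = cfg.L
    root = tree.root
    seqs: dict[int, np.ndarray] = {root: rng.integers(0, 4, size=L, dtype=np.uint8)}
    branch_mutations: dict[int, int] = {}
    p_transition = cfg.kappa / (cfg.kappa + 2.0) if cfg.kappa + 2.0 > 0 else 0.0

    for node in tree.nodes(order="preorder"):
        if node == root:
            continue
        parent = tree.parent(node)
        t_years = (tree.time(parent) - tree.time(node)) * gen.generation_time
        seq = seqs[parent].copy()
        n_mut = int(rng.poisson(cfg.mu * L * t_years))
        branch_mutations[node] = n_mut
        for _ in range(n_mut):
            site = int(rng.integers(0, L))
            base = seq[site]
            if rng.random() < p_transition:
                seq[site] = _TRANSITION[base]
            else:
                seq[site] = _TRANSVERSIONS[base][int(rng.integers(0, 2))]
        seqs[node] = seq

    sample_nodes = list(ts.samples())
    matrix = np.vstack([seqs[n] for n in sample_nodes])
    metadata = {}
    for sid in gen.sample_ids:
        g = gen.groups[sid]
        metadata[sid] = SampleMetadata(
            id=sid,
            group_override=GeoGroup(g) if g in GeoGroup.__members__ else None,
            region=f"simulated:{g}",
        )
    aln = Alignment(list(gen.sample_ids), matrix, metadata)
    return SimulatedDataset(
        alignment=aln, groups=dict(gen.groups), clades=dict(gen.clades),
        genealogy=gen, branch_mutations=branch_mutations, config=cfg,
    )


def truncate_ends(
    ds: SimulatedDataset,
    cfg: SimulationConfig | None = None,
    *,
    n_truncate: int | None = None,
    n_remove: int | None = None,
) -> SimulatedDataset:
    """Mask terminal segments of a random subset of sequences.

    A fraction of the sequences (``cfg.truncation_fraction``, or exactly
    ``n_truncate`` records) lose ``L - truncation_target_length`` positions
    (or exactly ``n_remove``), split randomly between the 5′ and 3′ ends.
    The complete alignment is retained on ``truth`` so recovery can be
    scored.  A zero truncation fraction is the identity.
    """
    cfg = cfg or ds.config
    aln = ds.alignment
    L = aln.length
    if n_remove is None:
        if cfg.truncation_target_length >= L:
            return ds
        n_remove = L - cfg.truncation_target_length
    if n_remove <= 0:
        return ds
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    if n_truncate is None:
        n_truncate = int(round(cfg.truncation_fraction * aln.n))
    if n_truncate == 0:
        return ds
    from .io import MISSING

    chosen = rng.choice(aln.n, size=n_truncate, replace=False)
    matrix = aln.matrix.copy()
    for i in chosen:
        left = int(rng.integers(0, n_remove + 1))
        right = n_remove - left
        if left:
            matrix[i, :left] = MISSING
        if right:
            matrix[i, L - right:] = MISSING
    truncated = Alignment(list(aln.ids), matrix, aln.metadata)
    return replace(ds, alignment=truncated, truth=ds.truth_alignment())


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Genealogy → sequences → optional end-truncation, in one call."""
    ds = evolve_sequences(simulate_genealogy(cfg), cfg)
    if cfg.truncation_fraction > 0 and cfg.truncation_target_length < cfg.L:
        ds = truncate_ends(ds, cfg)
    return ds
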