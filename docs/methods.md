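# Methods

`coiphylo` implements the analysis chain used in single-marker
phylogeography of mitochondrial COI barcodes: terminal-segment imputation,
Kimura-2-parameter (K2P) distances, a reduced-median haplotype network,
diversity and neutrality statistics with subsampling normalisation, a
two-level hierarchical AMOVA, and distance-threshold MOTU delimitation —
together with a coalescent generator that produces data with the same
statistical structure, so the whole chain can be validated offline.

## Data model

An alignment is a fixed-length matrix over {A, C, G, T, `-`, missing}.
Terminal runs of `N` or `-` are recoded as *missing*: COI barcodes are
length-conserved, so ragged ends reflect sequencing length, not indels.
Internal `-` is kept as a fifth state but never enters distance or
diversity calculations (pairwise deletion over unambiguous bases).
Ambiguity codes other than `N` are rejected at parse time.

Samples map to six geographic groups (NEA, MED, AFR, SA, AUS, ASI) from
country/region/coordinate metadata. Moroccan Atlantic samples are split at
Cape Boujdour (26.13° N): latitude ≥ 26.13 goes to the Northeast Atlantic
group, south of it to Atlantic Africa. The paper-grade group definitions
use capes rather than polygons; latitude alone is the only rule that can be
applied to point metadata, and an explicit `group_override` column
accommodates records (e.g. a Mid-Atlantic Bight annotation) that must be
excluded from group-wise statistics. Unresolvable records become
UNASSIGNED and are dropped from group statistics and the AMOVA.

## Missing-segment imputation

Each record with missing terminal cells is completed from a *donor*: among
records that observe the focal record's entire missing span, the one with
the smallest mismatch proportion over mutually observed unambiguous
positions. Ties prefer donors whose exact sequence is shared by more
records, then the lexicographically smallest donor id. Observed positions
are never altered, and imputing a complete alignment is the identity.

A network-guided reconstruction would need complete data to build the
network first; nearest-donor matching breaks that circularity and
coincides with the nearest network neighbour whenever the truncated
sequence belongs to a shared or closely related haplotype — the situation
the procedure is designed for. On the default synthetic fixture
(50 sequences, 10 truncated by 150 positions) the recovery of truncated
cells is measured at ≈99.8%, and the test suite enforces ≥90%.

## K2P distances

For a sequence pair, `P` and `Q` are the transition (A↔G, C↔T) and
transversion proportions over shared unambiguous positions, and

    d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q).

A non-positive logarithm argument raises an explicit saturation error
carrying `P` and `Q`. Matrices deduplicate identical sequences before the
pairwise pass, so cost scales with the number of haplotypes. Distances are
substitutions/site internally; reports multiply by 100. Group-level
summary tables report the mean over cross-group pairs with a standard
error from bootstrapping alignment columns (default 1000 replicates,
seeded) — the convention of the MEGA lineage of tools. The uncorrected
p-distance is available behind a flag (`model="p"`), and the K2P
correction is asserted in tests to dominate it.

## Diversity and neutrality

Segregating sites `S`, parsimony-informative sites (≥2 alleles each in ≥2
sequences), haplotype count `H`, haplotype diversity
`Hd = n/(n−1)·(1 − Σ pᵢ²)` and nucleotide diversity `π` (mean pairwise
p-distance per site; a K2P-based variant behind a flag) follow the
ape/pegas conventions. Tajima's D uses the standard coefficient chain
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) and is flagged undefined when `S = 0` or
`n < 4` rather than raising. Its p-value is the beta-distribution
approximation on the statistic's theoretical support [Dmin, Dmax], with
both tails folded. No multiple-testing correction is applied across
groups.

Unequal group sizes are normalised by rarefaction: R subsamples of size k
without replacement (defaults k = 12, R = 10,000, seeded), reporting the
arithmetic mean of every metric; fractional means for counts are expected.
Repeated index sets reuse cached evaluations, so small groups cost one
evaluation per distinct subset. `k` equal to the group size reproduces the
raw metrics exactly, and subsampling can only lower the mean `S` — both
asserted in tests.

## Reduced-median network

Variable columns are recoded to binary characters against the
multiplicity-weighted consensus (k-state columns yield k−1 characters),
the preprocessing the reduced-median family requires. The construction
then adds *median vectors* — per-character majorities of node triples —
greedily: each round, every triple proposes its majority vector; proposals
that strictly reduce the minimum spanning length and whose frequency
support (summed counts of the generating nodes; inferred nodes count 1)
is at least `1/r` of the round's best-supported proposal are admissible,
and the largest-reduction proposal (ties: support, then lexicographic
vector) is added, to a fixed point. Medians on no shortest path between
two observed haplotypes are then discarded unless removal would lengthen
the network, and the final edge set is the union of all minimum spanning
trees over the augmented nodes (an edge belongs to some MST exactly when
its endpoints are disconnected using strictly shorter edges).

The commercial implementation's exact reduction heuristics are not fully
published; this construction keeps the published ingredients (median
closure, frequency-based reduction parameter `r`, default 2, geodesic
pruning) in a deterministic greedy form. On compatible (perfect-phylogeny)
binary data it attains the parsimony lower bound — one mutation per
character — verified against an exhaustive Steiner search on tiny
instances, and equivalence with published network figures is assessed
topologically (two deep components; subclade sorting), not edge-for-edge.

## Hierarchical AMOVA

Individuals nest in groups, groups in clades. Sums of squares follow the
distance-based decomposition (SS of a set = Σ d²ᵢⱼ / set size, squared
distances by the Arlequin convention; plain distances behind a flag);
variance components σ²_a, σ²_b, σ²_c come from the expected mean squares
with the standard unequal-size coefficients, and Φ_CT, Φ_SC, Φ_ST from
their ratios. Negative components are reported as computed (flagged), with
an optional truncation. Permutation tests use stratum-appropriate units:

* among clades — whole groups among clades, *exhaustively enumerated*
  whenever the number of distinct assignments is at most `n_perm`. With
  six groups split 2/4 there are C(6,2) = 15 assignments, so the smallest
  achievable p-value is 1/15 ≈ 0.067 — a floor the package reproduces
  exactly;
* among groups within clades — individuals among groups within clades;
* overall — individuals without restriction.

Sampled tests use the (hits + 1)/(draws + 1) estimator; exhaustive tests
use hits/total. The among-group test's type-I error at α = 0.05 is
verified to sit inside the binomial 99% CI over 500 simulated null
datasets.

## MOTU delimitation

Single-linkage partitions are evaluated at every midpoint between
consecutive distinct pairwise distances and ranked by *stability* — the
width of the threshold interval over which the partition is unchanged.
Partitions are nested by construction; the single-MOTU partition (stable
on an unbounded interval) and the all-singleton partition are excluded
from the ranking. A barcode gap report gives the maximum intra-MOTU and
minimum inter-MOTU distances. This transparent threshold-stability scan
stands in for proprietary or score-based delimitation algorithms: it
exposes the same nested partition series (e.g. the 2-MOTU clade split, and
finer partitions separating subclades) without their composite scores,
which are out of scope.

## Synthetic data generator

Genealogies are single-locus Kingman coalescents (msprime) with one
population per geographic group. Defaults describe a John-Dory-like study
design and are the conditions under which the test suite's claims hold:

| parameter | default | rationale |
|---|---|---|
| L | 620 sites | barcode alignment length |
| sample sizes | NEA 86, MED 26, AFR 48, SA 4, AUS 16, ASI 12 | study-scale group sizes (N = 192) |
| clades | A = {NEA, MED}; B = {AFR, SA, AUS, ASI} | two-clade design, 2/4 split |
| μ | 9.94 × 10⁻⁹ /site/yr | COI rate estimate for the system |
| κ | 10 | transition/transversion ratio typical of fish mtDNA |
| clade split | 3.5 Myr | calibrated so the realised mean inter-clade K2P ≈ 0.074 subs/site (see below) |
| subclade splits | A: 0.02 Myr; B: 0.5 Myr | clade A effectively panmictic; clade B geographically sorted (~1% divergence) |
| Nₑ (per group) | 2 × 10⁵ | within-group π in the 10⁻³ range |
| growth rate | 2 × 10⁻⁵ /yr | recent expansion; negative Tajima's D |
| generation time | 1 yr | converts coalescent units to years; configurable |
| truncation | target 408 of 620 positions | emulates ragged barcode ends |

Sequences evolve by a Poisson process at rate μ·L per year per branch;
each mutation is a transition with probability κ/(κ+2), else one of the
two transversions. Multiple hits are allowed (finite sites), so K2P
saturation behaviour is exercised at deep divergences. No among-site rate
heterogeneity is applied by default.

The clade split is *calibrated*, not the naive 0.074/(2μ) = 3.72 Myr: the
realised cross-clade coalescence adds the root-population coalescent time
(~0.3 Myr in expectation with several lineages entering the root) and the
K2P estimator is slightly convex, so 3.5 Myr centres the realised mean
inter-clade K2P on 0.074 substitutions/site (measured 0.0743 ± 0.0016
over 80 replicates). A single replicate is noisy (SD ≈ 0.013, dominated by
the Poisson draw on the two deep stem branches), which is why replicate
means are used wherever that quantity is checked.

What the generator does *not* emulate: recombination (correct for
mtDNA), migration or secondary contact between clades, selection,
among-site rate variation, sequencing error, and base-composition bias
(the root sequence is uniform over A/C/G/T). Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under a clean two-clade history — not robustness to contamination,
misalignment or rate heterogeneity in real data.

## Numerical and design choices

* Haplotype ordering is by descending multiplicity then lexicographic
  sequence; all tie-breaks in the network (MST union, median choice) are
  lexicographic, so every output is deterministic given the seed.
* The pipeline manifest records the seed and per-file SHA-256 checksums and
  contains no timestamps; re-running a configuration reproduces the bundle
  byte for byte.
* Pipeline order is exclude (unassignable records) → impute → analyse;
  imputation runs before haplotype collapse because collapse requires
  complete data.
* Clade labels for the AMOVA come from simulation truth when available,
  otherwise from the 2-MOTU single-linkage partition with per-group
  majority vote.
* Degenerate inputs are flagged rather than raised where a value is
  legitimately undefined (Hd/π at n = 1, Tajima's D at S = 0, Φ_SC with
  one group per clade, barcode gap with one MOTU); true input errors
  (unequal lengths, unknown symbols, k larger than the group) raise with
  the offending record or column named.
* Problem sizes in the validation suite (subsample replicate counts,
  permutation depths, replicate simulations) are scaled to keep the full
  suite in the order of a minute while leaving Monte-Carlo error well
  inside the asserted tolerances; the acceptance script uses 2000
  permutations per sampled AMOVA stratum (the among-clade stratum is
  always exhaustive at this design) and 10 replicate simulations for the
  divergence summary.

## Known limitations

* The imputation surrogate is nearest-donor, not network-guided; for
  truncated sequences that are *not* close to any complete haplotype the
  donor choice can differ from a network-based reconstruction.
* The reduced-median construction is a deterministic greedy variant; on
  heavily conflicting data it may return fewer medians than the full
  median closure would.
* ASAP-style composite scores, BOLD's RESL/BIN refinement, Bayesian tree
  inference, skyline plots and model selection are deliberately out of
  scope; the threshold scan is a surrogate whose partitions, not scores,
  are comparable.
* Tajima's D p-values rely on the beta approximation, which is known to be
  approximate in small samples and at extreme S.
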