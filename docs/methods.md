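# Methods

`ompfam` re-implements, as one tested pipeline, the multi-stage
classification procedure used to resolve the Omp85/TpsB outer-membrane
protein superfamily into subfamilies. This note records the models and
procedures, their assumptions, the parameters that matter, and the
design decisions taken where the design was genuinely open.

## Pipeline overview

The stages run in a fixed order:

1. **Profile search.** Two barrel profiles (Omp85-class and TpsB-class)
   are built from seed alignments and searched against all input
   sequences with a permissive reporting threshold (E ≤ 10 by default),
   mirroring the practice of retaining hits below the formal inclusion
   thresholds (1.0 and 0.1) because genuinely divergent members score
   below them. Targets hit by both profiles keep the higher-scoring hit.
2. **Duplicate collapse.** Identical full-length sequences are grouped
   (the desk-scale analogue of UniRef100 grouping) and one
   representative — the lexicographically smallest id — continues.
3. **All-vs-all alignment and curation clustering.** Smith–Waterman with
   BLOSUM62 and 11/1 affine gaps; pairs with E ≤ 1e-2 become edges
   weighted −log10(E) (capped at 200); Markov clustering at inflation
   1.5.
4. **Contaminant propagation.** Cluster-level label propagation: a
   cluster containing contaminant annotations and no superfamily
   annotations is discarded wholly, a cluster containing superfamily
   annotations and no contaminants is kept wholly, unknown-only clusters
   are kept (the profile search retrieved them for a reason), and mixed
   clusters are flagged ambiguous and discarded with a loud warning —
   silent keeping would defeat the curation.
5. **Length filter.** Sequences shorter than 250 aa are removed
   (strictly: exactly 250 is kept).
6. **Final clustering.** MCL at inflation 1.3 on the curated set; these
   clusters are the subfamily calls. Cluster names come from a
   user-supplied subfamily map by majority vote (on synthetic data, the
   generator's truth table).
7. **Domain partition.** The best profile hit's envelope start is the
   barrel's N-terminal border: barrel = [env_start, end of sequence],
   N-terminal region = [1, env_start − 1] when at least 20 aa remain.
8. **POTRA carving.** Iterated profile scanning of the N-terminal
   region (best hit, mask, repeat; single-sequence E ≤ 0.1), a 25–125 aa
   length band, and one POTRA set per cluster: sequences exceeding the
   cluster's modal repeat count keep their highest-scoring repeats,
   renumbered N→C; missing repeats are never invented.
9. **Lipoprotein signals.** A lipobox rule replaces an external
   predictor: motif `[LVI][ASTVIG][GAS]C` with the cysteine at position
   15–40 and a mean Kyte–Doolittle hydropathy above 1.0 over the eight
   residues preceding the motif.
10. **Similarity networks.** Per region (full-length, barrel,
    N-terminus, POTRA): greedy centroid reduction (identity 0.80;
    0.50 on the POTRA path), all-vs-all alignment of centroids, edges at
    E ≤ 1e-5 (1e-3 for POTRAs), no self-loops. FtsQ POTRAs can be added
    to the POTRA network as an outgroup.
11. **Taxonomic distribution.** Restricted to complete proteomes:
    per-phylum presence percentages and per-genome copy numbers.

Given one config (including its seed) the pipeline is deterministic and
reruns are byte-identical.

## Profile search model

The profile is a position-specific scoring matrix over match columns
(≥ 50% residue occupancy in the seed alignment), with emissions
`log2(((count_a + w·p_a) / (total + w)) / p_a)` in bits. The pipeline
default pseudocount weight is w = 8 (a strong prior is needed when a
12-row seed must generalize across subfamilies; with w = 1 the
zero-count penalty of ≈ −3.7 bits per absent residue makes remote
members unalignable). Alignment to a target is the same affine-gap local
dynamic program used for pairwise alignment (default gap scores −4 bits
open, −0.5 bits extend), so a hit carries a bit score, target envelope,
and the profile columns covered.

E-values come from empirical extreme-value calibration: the profile
scores n ≥ 200 (default 500) i.i.d. sequences drawn from the background
composition (default length 350, a typical barrel), a Gumbel law is
fitted by maximum likelihood, and
`E = db_size · (1 − exp(−exp(−λ(S − μ))))` with db_size = number of
sequences searched. This replaces a full profile-HMM forward pipeline;
the pipeline-relevant outputs (bit score, E-value, envelope) are
preserved, which is the deviation that makes the core desk-scale and
oracle-testable. The "envelope" is the optimal-alignment span, not a
posterior-probability envelope.

For POTRA scanning specifically, the recorded repeat envelope is the
alignment span *projected out to the full profile length* using the
covered profile columns (clipped to the sequence and to previously
assigned repeats). Local alignment trims diverged repeat ends; without
the projection, genuine repeats fragment below the 25 aa filter and
repeat counts are systematically undercounted.

## Pairwise alignment and statistics

Smith–Waterman with affine gaps under the convention that a gap of
length L costs `gap_open + L·gap_extend` (11 + L with the defaults, the
convention under which the published gapped Karlin–Altschul constants
λ = 0.267, K = 0.041 for BLOSUM62 apply). Traceback is deterministic:
ties break diagonal > up > left, and the optimal cell is the first
maximum in row-major order. `X` scores 0 against everything. Identity is
matches over all alignment columns, gaps included — the stricter
convention. E = K·m·n·exp(−λS).

Greedy centroid clustering processes sequences in decreasing length
(ties by id) and joins each to the *first* centroid reaching the
identity threshold, mirroring fast centroid tools. Because
local-alignment identity is degenerate over tiny spans (any shared
5-mer scores identity 1.0), the pipeline's network reductions impose a
coverage floor (`min_columns` = 100 for the 0.80 reductions, 40 on the
POTRA path); the floor also yields a provable score lower bound for
qualifying alignments (worst-case per-column scoring), letting a cheap
score-only pass skip comparisons that cannot qualify. The floor defaults
to 0 (off) in the library function.

## Markov clustering

Dense-matrix MCL: add self-loops (weight 1.0), column-normalize,
iterate expansion (matrix power 2), inflation (entrywise power, then
renormalize), and pruning (entries < 1e-5) until the matrix change drops
below 1e-9 or 100 iterations. Attractors are nodes with positive
diagonal; each attractor's row support is a cluster; nodes appearing in
several supports go to the smallest-index attractor (canonical MCL
tolerates overlaps; the downstream curation needs a partition).
Isolated nodes become singletons. Non-convergence returns the current
interpretation with a warning. The −log10(E) weight transform stands in
for the reference tool's undocumented "scheme 7".

## Synthetic superfamily generator

The generator is the package's study system: it emulates the structure
that makes the classification problem what it is, at desk scale.

**Hierarchy.** A shared domain consensus library (the superfamily
ancestor: Omp85-class barrel 380 aa; TpsB-class barrel 300 aa derived
at 60% substitution, ~40% residual identity; POTRA 75 aa; WD40 280 aa;
patatin 230 aa; metallopeptidase 150 aa; 20 aa lipoprotein signal) →
per-subfamily consensus variants at `family_divergence` = 0.6 →
individual sequences at `divergence` = 0.25, with indels (rate 0.01 per
site) confined to the 10 aa inter-domain linkers so ground-truth domain
coordinates stay exact (an option allows in-domain indels). All residues
draw from the Robinson–Robinson background composition, so the published
alignment statistics hold on generated data; with uniform composition
the Karlin–Altschul tail is optimistic by an order of magnitude and
phantom network edges appear.

**Position-specific conservation.** Real domains are not uniformly
diverged, and two pipeline-critical properties are impossible under
uniform divergence: a single profile must detect POTRA repeats and
barrels across all subfamilies, while cross-subfamily pairwise E-values
must mostly miss the 1e-2 clustering cutoff (otherwise MCL at inflation
1.3 merges subfamily cliques through dense fields of weak edges — real
BLAST graphs are sparse across remote subfamilies). The generator
therefore freezes small structural cores at the subfamily level: every
8th POTRA position and every 10th barrel position. Seed alignments
(12 rows at divergence 0.45, cores preserved) model Pfam-style
family-diverse seeds, so the derived profiles carry strong anchor
columns. Log-odds scoring rewards an anchored match roughly twice as
much as BLOSUM62 does, which is exactly the asymmetry that lets
profiles see what pairwise alignment does not.

**Exact-count family divergence.** Subfamily variants mutate an exact
fraction of non-frozen positions rather than each position
independently: a binomial draw gives subfamily pairs a spread of
realized distances, and one lucky pair merges under MCL.
Sequence-level sampling keeps independent per-site substitution.

**Lipoproteins.** The signal consensus ends in L-A-G-C with an 8-residue
Leu/Ile/Val/Phe core before it. The four lipobox residues never mutate
(the cysteine is invariant in real lipoproteins), and core positions
substitute only within the hydrophobic alphabet (purifying selection on
h-regions). The Lipo architecture is confined to one phylum
(Bacteroidetes in the default layout) so the distribution matrix shows
a clean 100%/0% contrast.

**Contaminants.** Five families of 10 random proteins (280–420 aa),
each carrying a family-conserved 60-residue segment derived from the
Omp85 barrel at 40% identity — enough that the permissive profile
search retrieves whole families, far too little for subfamily-level
clustering, which is precisely the curation problem the pipeline
solves. Members are annotated with probability 0.9 (contaminants come
from established, well-annotated families); true members only with
probability 0.5 (novel superfamily members are the poorly annotated
ones).

**Taxon table.** Four phyla × five taxa, the last taxon of each phylum
flagged incomplete to exercise the complete-proteome restriction.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real substitution processes (no
rate heterogeneity beyond the frozen cores, no indel saturation),
real Pfam emission statistics, fragmentary database entries,
paralog-specific domain gains/losses within a subfamily, genome context,
and real phylogenetic signal. Tests against it validate the pipeline's
mechanics and decision rules, not database-scale biology.

## Numerical choices and degenerate inputs

- Alignment kernels use float64; scores under the integer BLOSUM62
  scheme are exact. A score-0 (empty) local alignment is reported with
  identity 0 and all-zero coordinates.
- E-value conversion uses `expm1` for tail stability and saturates at
  P = 1 deep in the left tail.
- The duplicate-collapse representative, MCL overlap assignment, greedy
  first-match rule, merge-hits tie-breaks (score, then E-value, then
  profile name) and traceback tie-breaks are all fixed so identical
  inputs give byte-identical outputs.
- Phyla without complete genomes produce missing cells (not 0%) in the
  presence matrix.
- Stage reports written to disk omit wall-clock times so reruns are
  byte-identical.

## Problem sizes

The reference validation runs ten architectures × 30 sequences plus 50
contaminants (350 proteins, mean length ≈ 600 aa) — large enough that
every stage (two MCL passes, four region networks, repeat scans on
~300 N-terminal regions) operates on non-trivial input, small enough
that the complete run finishes in a few minutes on one core. Oracle
comparisons run on exhaustively checkable sizes: alignments up to
length 6, graphs up to 6 nodes.

## Known limitations

- The profile search is a calibrated PSSM, not a profile HMM: no
  forward-algorithm statistics, no multi-domain per-target splitting,
  no biased-composition correction.
- Karlin–Altschul constants are fixed published values; composition-
  based adjustment is out of scope, so pairwise E-values on sequences
  with unusual composition are approximate.
- `all_vs_all` is an exact O(n²) scan; no seeding heuristics. Desk
  scale (hundreds to a few thousand sequences) is the intended regime.
- Subfamily naming on real data requires a user-supplied annotation
  table; the pipeline does not harvest database annotations.
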