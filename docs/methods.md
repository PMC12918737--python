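# Methods

## Scope and model

`tadscan` detects and classifies Tad (type IVc) pilus gene clusters in
bacterial genome assemblies by reference-guided homology search. The
canonical reference layout follows the four clusters of *Bradyrhizobium
diazoefficiens* USDA 110, numbered by chromosomal order:

| cluster | roles (genomic order) | character |
|---|---|---|
| 1 | tadV, rcpC, tadZ, tadA, tadB, tadC | degraded duplicate of cluster 2; lacks the pilin (flp) and secretin (rcpA) genes |
| 2 | flp, tadV, rcpC, rcpA, tadZ, tadA, tadB, tadC | complete export apparatus |
| 3 | flp, tadV, rcpC, rcpA, tadZ, tadA, tadB, tadC | complete apparatus of independent evolutionary origin |
| 4 | tadE, tadF, tadG | pseudopilins; frequently scattered rather than clustered |

Role flags drive completeness: `rcpC` is flagged accessory and never
required; all other roles of a cluster must be found for a *complete*
call. The role lists and flags live in `tadscan.references` and can be
replaced wholesale by a user-supplied reference directory (protein +
nucleotide FASTA with `c<cluster>|<role>` ids plus a JSON manifest), e.g.
real USDA 110 sequences.

## Alignment backend

Alignments use affine-gap Gotoh dynamic programming (numba-compiled) with
deterministic traceback (diagonal > up > left at ties). Defaults follow
BLAST conventions: nucleotide match/mismatch +2/−3, gap open/extend 5/2,
word size 11; protein BLOSUM62, gaps 11/1. E-values use fixed
Karlin–Altschul parameters (nucleotide λ=0.625, K=0.41; protein λ=0.267,
K=0.041) without edge-effect correction — downstream filters operate on
bitscores, so calibration precision is non-critical.

The seeded search finds exact k-mer seeds on both strands, groups seeds
within one query length on the subject, extends the group ungapped with
an x-drop of 30 raw points, and runs full local DP in a window spanning
the ungapped extent plus 128 nt padding. Seed groups whose best ungapped
score stays below a *gap trigger* (0.6 × the requested bitscore floor;
zero, i.e. no pruning, when no floor is requested) are discarded — the
standard two-stage heuristic that keeps genome scans at desk scale. The
seeded score therefore never exceeds the full Smith–Waterman optimum,
and attains it with k=1 and no thresholds on small instances.

Any external search tool can substitute the internal backend through the
12-column BLAST `outfmt 6` dialect (minus-strand subject intervals
encoded as `sstart > send`); the pipeline consumes only HSP records.

## Chaining and calling

HSPs on one replicon are chained into segments when their subject
intervals are within `max_gap` of each other (overlap = gap 0) — the
connected components of the interval-proximity graph, computed by a
linear sweep. Defaults: `max_gap` 5,000 nt (Tad clusters span ~10 kb with
genes on either strand, so chaining is strand-blind), segment score floor
100 bits. Both are free parameters.

Each segment is assigned exclusively to the reference cluster with the
greatest summed bitscore among its member HSPs (ties to the lower cluster
id, flagged): clusters 1 and 2 are close homologs, and exclusive
assignment prevents one locus from being counted for both. Within the
assigned segments, a gene role counts as *found* when its best HSP
identity is ≥ 60% (nucleotide) and the union of its HSP query intervals
covers ≥ 50% of the reference gene. Status rules:

* **complete** — all required roles found; when they sit in a single
  segment, their positional order must match the reference order (or its
  reverse) within ±1 rank;
* **partial** — at least 2 roles found (configurable);
* **absent** — otherwise; an absent call carries no segment.

On contig/scaffold assemblies, segments within 200 nt of a contig edge
on *different* contigs are additionally considered as one joined
candidate locus, so a cluster split by the assembly is called
complete/partial with `fragmented_assembly=true` rather than absent.
Scattered genes on one replicon never join (they are farther apart than
`max_gap`), preserving the distinction between canonical presence and
the protein-level fallback: pseudopilins (TadE/TadF/TadG) are also
sought anywhere in the proteome by reciprocal best hit (E ≤ 1e-5,
identity ≥ 30%, coverage ≥ 50% of the shorter protein, bitscore ties
broken by identity then lexicographic id; residual ties make a hit
ambiguous and never reciprocal). Genomes without annotated CDS fall back
to a nucleotide search for the pseudopilin genes.

## Cluster comparison

`link_clusters` aligns all protein pairs of two clusters end-gap-free
globally; identity is matches over the full alignment extent including
unaligned terminal overhangs (identity over the aligned core alone lets
short chance matches between unrelated proteins pass the 30% threshold).
Mutual-best pairs at ≥ 30% identity become links. Colinearity is the
longest orientation-consistent chain — links of equal relative
orientation in increasing order, or opposite orientation in decreasing
order — divided by the number of links (0 with no links). This makes the
score invariant to reversing one cluster's gene order and strands.

## Distances and trees

* **Marker distance**: taxa supply TadA, TadB, TadC proteins (taxa
  missing any are dropped with a warning); the concatenation (fixed
  order) is globally aligned per pair and the p-distance is the fraction
  of non-identical columns among gap-free columns. No substitution-model
  correction by default (desk-scale divergences); a Poisson correction
  is available via flag.
* **ANI**: genome A is chopped into 1,020-nt fragments (tails shorter
  than half a fragment discarded); each fragment's best hit in genome B
  is kept at identity ≥ 70% and coverage ≥ 70%, and ANI is the mean kept
  identity — undefined below 5 kept fragments. ANI is asymmetric; trees
  use `1 − (ANI(a,b)+ANI(b,a))/200`, with undefined pairs set to
  distance 1.0 (warned).
* **Trees**: canonical neighbor joining with deterministic tie-breaking
  (minimum Q, ties by the lexicographic pair of smallest-leaf labels);
  negative branch lengths are clamped to zero with the deficit moved to
  the sibling; the last three nodes use the three-point closed form.
  UPGMA is available for ultrametric comparisons. Newick round-trips at
  6 decimals. Presence-matrix rows are ordered by the ladderized leaf
  order (children sorted by subtree size, then smallest leaf name); rows
  missing from the tree are appended alphabetically with a warning.

## Synthetic data

The generator emits genomes as i.i.d. background sequence at a requested
GC (default 0.64, rhizobial-like) with implanted clusters: reference
genes diverged to a per-implant protein-identity target (substitutions
only, placed uniformly; codons of mutated residues are re-drawn at the
genome GC so synonymous positions stay intact and nucleotide identity
stays alignable), joined by 20–120 nt spacers, one role (`rcpC`)
antisense. Partial targets delete a stated core role before implanting;
fragmented targets split the cluster between two genes across two
contigs with no sequence loss; scattered pseudopilins are placed ≥ 50 kb
from any cluster and ≥ 8 kb apart (beyond chaining reach). Random decoy
CDS provide RBH negatives. Everything derives from
`numpy.random.default_rng` streams of one seed: identical configs yield
byte-identical GenBank/FASTA/manifest output.

Default genome length is 180 kb — the smallest size honouring the
spatial constraints; real rhizobial genomes are ~50× larger, so absolute
run times, E-values and the spurious-seed load all scale up on real
data even though the per-locus logic is unchanged.

The packaged reference set is itself generated (fixed seed 20110):
random proteins of realistic lengths (Flp ~62 aa, ATPase ~400 aa,
TadG ~545 aa), cluster 1 derived from cluster 2 at 85% identity,
cluster 3 independent. Synthetic references preserve the *structure* of
the detection problem (homologous duplicates, shared roles, scattered
genes) but not real sequence composition: passing tests demonstrate the
pipeline's logic, not sensitivity on real *Bradyrhizobium* data — for
that, substitute real reference sequences via `--refs`.

Two stock configurations define the study conditions: `survey_config`
reproduces the genus-survey composition as exact fractions (95% of
genomes carry clusters 1 and 2, 50% cluster 3, 48.5% a canonical
cluster 4 with scattered pseudopilins bringing TadG to 95%, 5% empty
contig-level genomes, 10% of carriers with cluster 2 split across
contigs), assignment randomised by seed; `recovery_config` draws
per-cluster statuses uniformly from {complete, partial, absent} at
protein identities in [0.7, 1.0] for truth-recovery benchmarking.

## Numerical and degenerate-input choices

* Ambiguous IUPAC nucleotides are normalised to N, which mismatches
  everything (including N–N).
* GenBank coordinates convert 1-based inclusive ↔ 0-based half-open only
  at the format boundary; compound (join) CDS locations are kept only
  when colinear on one replicon, else skipped with a warning; CDS with
  internal stop codons are excluded as pseudogenes with a warning.
* Empty alignment (score ≤ 0) yields no HSP rather than a zero-length
  one; empty query sets yield empty results; an all-absent genome yields
  absent calls with no segments.
* `mutate_to_identity` computes the exact substitution count
  `round((1−t)·L)`, keeping realised identity within ±0.02 of the target
  for sequences ≥ 25 residues.

## Limitations

* No indel simulation within genes and no intra-cluster rearrangement in
  the generator; the colinearity score is exercised by constructed
  swaps, not simulated evolution.
* No HMM or reference-free cluster discovery; sensitivity is bounded by
  nucleotide-level similarity to the references (exact 11-mer seeding
  needs roughly ≥ 75% nucleotide identity to be reliable).
* Karlin–Altschul parameters are fixed constants; reported E-values are
  indicative, not calibrated per scoring scheme.
* Translated (tblastn-style) search is not implemented: protein search
  runs against extracted proteomes, nucleotide search against replicons.
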