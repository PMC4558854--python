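# Methods

`symcore` re-implements, as one tested pipeline, the comparative-genomics
workflow used to place and characterize uncultured-until-recently bacterial
gut symbionts against their free-living relatives: reciprocal-best-hit
(RBH) orthology, genus core genomes, reconstruction of the core genome of
the last common ancestor (LCA) of two genera, gene-loss accounting for a
reduced target genome, reference pan-genome presence/absence scanning,
concatenated gene-by-gene neighbor-joining phylogeny, and genome-wide
pairwise dN/dS with saturation flagging. A synthetic genome-evolution
generator with recorded ground truth makes every stage testable without
downloading genomes.

## Similarity search

`align_pair` is exact affine-gap local alignment (Smith–Waterman/Gotoh,
executed by Biopython's C aligner). Defaults: match +2, mismatch −3, gap of
length L costs 5 + 2L. Identity is matches over aligned columns (gap
columns included); query coverage is the fraction of the query inside the
local alignment. Non-ACGT letters are accepted and score as universal
mismatches (N never matches N). Both strands are tried and the better kept.
Hits below `min_score` (default 50) are suppressed; at these parameters the
best local score between unrelated ~300-nt CDS concentrates near 20–25, so
the cutoff plays the role an E-value threshold plays in database search
tools.

The all-vs-all engine (`best_hits`) seeds candidates by shared 11-mers
(either strand, ≥1 shared word), then applies a second seed-extension
stage: the best ungapped segment score along the seed diagonals must reach
`min(35, min_score)` before a candidate gets the full dynamic-programming
pass (an in-repo numba Gotoh kernel, scoring only). Both stages are
classical database-search heuristics; they only skip candidates, and every
reported score/identity/coverage comes from the exact aligner on the
winning subject. On substitution-divergent sequences the best ungapped
segment tracks the full local score almost exactly, so at the default
thresholds the gate is effectively lossless while making 1,500-gene
all-vs-all searches run in seconds.

Ties for best hit break by higher identity, then lexicographically smallest
subject locus — fully deterministic.

## Orthology, cores, loss accounting

Two genes are orthologs operationally when each is the other's
highest-scoring hit (RBH); tables are one-to-one by construction. A genus
core is the set of loci of a caller-designated *reference* genome with an
RBH partner in every member genome; expressing cores in reference
coordinates keeps intersections well-defined without multi-genome
clustering, and paralog copy number is deliberately ignored
(presence/absence only). The LCA core of two genera intersects their cores
through a single RBH "bridge" table between the two reference genomes, and
is reported in the first core's coordinates. Loss accounting partitions the
LCA core into loci retained vs lost by a target genome (RBH against the
LCA reference); lost counts are tallied per functional category, with
unlabeled loci pooled under `hypothetical`.

A missing ortholog table is an error, never an implicit absence.

## Pan-genome

Genes from all genomes are clustered greedily in decreasing length order
(ties: genome id, locus id): a gene joins the first existing locus whose
representative it matches under the allelic-variant criterion — identity
≥ 70% over coverage ≥ 10% — else founds a new locus. Coverage is measured
against the longer of (gene, representative): this is the reading under
which a 30%-length truncated gene copy merges at the 10% threshold but
founds its own locus at 70%, which is the discriminating behavior the
parameter sweep is meant to probe; a `coverage_mode="shorter"` option
provides the permissive alternative. Matches must additionally clear the
similarity `min_score`, so short high-identity local matches cannot bridge
unrelated loci. Thresholds are inclusive (≥), so results are bit-stable at
the printed precision.

Scanning marks a (locus, genome) cell present when any gene of the genome
matches the locus representative under the same criterion; the
best-identity matching gene per cell is recorded and later used to pull
sequences for the core-locus tree. Core loci at prevalence *p* are those
present in ≥ ceiling(p·n) genomes (a small epsilon guards the ceiling
against float fuzz). `query_scan` applies the same criterion to named query
genes — the virulence-factor use case — and reports the best identity and
coverage seen per genome even when below threshold.

## Phylogeny

Gene alignment is deterministic center-star: the center minimizes the sum
of pairwise global-alignment distances (non-match columns), and the other
sequences merge against it under "once a gap, always a gap". Nucleotide
pairwise steps use the similarity scoring above; protein steps use
BLOSUM62 with gap costs 11 + L. Supermatrices record a half-open, 0-based
partition interval per gene; `drop-incomplete` keeps only taxa present in
every gene (gap-free in the taxon dimension, the MLSA convention), while
`pad-gaps` (the pipeline default for the core-locus tree, where a reduced
target would otherwise be ejected) fills missing taxa with gap rows.

Distances use pairwise deletion (each pair uses the columns where both
carry an unambiguous residue) under p, Jukes–Cantor, Kimura-2-parameter
(nucleotide) or p/Poisson (amino acid) models. Pairs whose correction is
undefined are flagged saturated and capped at 5.0 substitutions/site — the
cap only exists so NJ still has a finite entry; capped entries carry a flag.

Trees come from canonical Saitou–Nei neighbor joining (Q criterion;
deterministic smallest-index tie-break). Negative branch lengths are
clamped to zero with the deficit moved to the sister branch, preserving the
path length of the joined pair. With an outgroup, the tree is rooted at the
midpoint of the outgroup's pendant edge. Bootstrap support resamples
supermatrix columns with replacement (genes instead, behind a flag),
rebuilds the NJ tree per replicate, and reports the percentage of
replicates containing each internal bipartition of the point tree;
deterministic given the seed. On exactly additive matrices NJ recovers the
generating topology and branch lengths exactly (checked against dendropy's
independent NJ and against trees of known length).

## dN/dS (NG86)

Ortholog pairs are aligned codon-aware: translate (bacterial code, table
11; terminal stop trimmed, internal stop is an error), globally align the
proteins, map gaps back to codons, and drop codon columns containing a
gap, an ambiguous base or a stop. Pairs retaining fewer than 30 codon
columns are rejected — the declared stand-in for a "gap-rich alignments
removed" manual filter.

Counting follows Nei–Gojobori (1986). Per codon, the synonymous site count
is the sum over positions of the fraction of the three possible changes
that are synonymous; changes creating stop codons count as nonsynonymous.
Sites are averaged over the two sequences, so S + N = 3 × codons exactly.
Codons differing at 2–3 positions are resolved by equal-weight averaging
over all minimal mutational pathways, excluding pathways through stop
codons (all pathways are used in the degenerate case where every pathway is
blocked). Both proportions receive the Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p). A pair is flagged saturated when either
correction is undefined or dS exceeds the saturation threshold (default
3.0); ω = dN/dS is reported only for unsaturated pairs with dS > 0. The
per-pair (Sd, Nd) table over all 61×61 sense-codon pairs is verified
exactly against an exhaustive pathway enumerator built directly on
Biopython's translator.

NG86 is a counting method: it ignores transition/transversion bias when
counting sites, which under a realistic κ (here 2.0) biases ω̂ downward by
roughly 10–20% at moderate divergence. The recovery tests budget for this
known bias; an ML codon model (out of scope) would remove it.

## Synthetic genome evolution

The generator emulates the study system: clades of bacterial genomes
descending from a shared ancestral repertoire, with per-branch gene loss
and gain and codon-level divergence under selection, plus a reduced,
host-associated target genome.

*Ancestor.* `n` genes; lengths geometric with a 50-codon floor around a
mean of 120 codons — a deliberate desk-scale stand-in for the ~300-codon
bacterial average (every downstream statistic scales with length only);
codons drawn from independent nucleotide frequencies tuned to a GC target
of 0.53 (typical of the genera emulated) with stops excluded and an ATG
start; COG-like category labels drawn from a fixed weighted set.

*Sequence evolution.* Per branch, codons undergo proposal/acceptance
substitution: a position is picked uniformly, the replacement nucleotide
κ-weighted (transition:transversion 2:1 by default), and the change is
accepted with relative probability 1 if synonymous, ω if nonsynonymous,
and 0 if it creates a stop. Branch lengths are expected *accepted*
substitutions per codon; the proposal intensity is rescaled by the mean
acceptance probability over the ancestral codon composition
(uniformization), so realized divergence tracks the branch length without
per-codon rate bookkeeping (composition drift along a branch makes this an
approximation, adequate at the divergences simulated). Defaults ω = 0.2
(purifying regime), κ = 2.

*Gene content.* Each branch deletes each surviving gene independently
(default probability 0.05; the reduced target's branch uses 0.11,
mirroring a ~11% core loss) and gains Poisson-many (default mean 10) genes
simulated de novo — never copied — so gained genes can never be RBH
partners of ancestral loci and truth labels stay clean. Gains are drawn
from a random stream independent of the ancestor's even when seeds
coincide, so no spurious sequence repeats arise. The truth table records
per-leaf inventories with provenance, and clade cores defined as the
intersection of leaf inventories restricted to ancestral loci.

What the generator does *not* model: intragenic recombination,
rearrangement/synteny, pseudogenization, paralogous families, rate
heterogeneity across sites, or indels within genes. Passing recovery tests
therefore demonstrate correctness of the pipeline's bookkeeping and
estimators under a clean substitution-plus-gene-content process, not
robustness to every feature of real draft genomes (fragmented CDS, chimeric
assemblies, annotation error).

## Pipeline and problem sizes

`run_full_pipeline` chains: RBH tables → genus cores → LCA core (chained
intersection over the configured genera) → per-target loss ledgers →
pan-genome build/scan → core loci at 90% prevalence → per-locus center-star
alignments → supermatrix (pad-gaps) → NJ with bootstrap → genome-wide dN/dS
for the reference–reference and reference–target pairs. Everything is
driven by one YAML config and one seed; reruns are byte-identical, and the
run manifest records versions, thresholds, seed and outputs.

The acceptance-scale study uses a 1,500-gene ancestor, two genera of three
genomes each, one reduced target, 20 bootstrap replicates, and 300-gene
ω-recovery and saturation replicates — sizes chosen so the whole evaluation
runs on a laptop-class single core in minutes while leaving every statistic
well away from small-sample noise. Degenerate inputs are errors, not
silent drops: empty subject sets, missing ortholog tables, zero comparable
columns, untranslatable frames and over-filtered codon alignments all
raise typed exceptions, and the dN/dS scan logs each skipped pair with its
reason.

## Known limitations

- NG86 (not an ML codon model) and JC/K2P distances: adequate for the
  regime tested, biased at high divergence or strong compositional skew.
- The greedy pan-genome clustering is order-deterministic but, like all
  greedy representative methods, not invariant to the threshold geometry;
  raising thresholds only splits clusters (checked), but cluster
  representatives depend on the length ordering.
- Coverage-vs-longer is a convention; with highly fragmented draft
  annotations the `shorter` mode may match curated-database behavior more
  closely.
- The LCA construction intersects genus cores through a single
  reference-to-reference bridge; genes absent from either reference genome
  cannot appear in the LCA core even if anciently conserved elsewhere.
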