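# Methods

This note documents the models, conventions and design choices behind
`tpsfam`, in the order the pipeline applies them.

## Coordinates and sequence handling

All public interfaces use GFF3 conventions: 1-based, inclusive on both ends.
Conversion to Python's 0-based half-open slices happens in exactly one
function (`genome_io.to_slice`), which eliminates off-by-one drift between
modules. Softmasked (lowercase) input is uppercased on read with no repeat
semantics attached. Gene models are CDS-only (gene/mRNA/CDS subset of GFF3);
UTRs and alternative-splicing graphs are out of scope. The GFF3 parser is a
direct implementation of this subset rather than a generic feature-ontology
reader, because the pipeline needs hard errors on exactly two malformations
(CDS without Parent, mixed strands within a transcript) that generic readers
tolerate.

Translation uses the standard genetic code. The terminal stop codon is never
counted in protein length, so a complete ORF of 3(L+1) nt encodes L residues
(1,680 nt → 559 aa). Codons containing N translate to X, preserving
positional bookkeeping; proteins with ≥10% X are flagged degenerate.

## Architecture and classes

Intron phase is the cumulative coding length upstream of the intron, mod 3
(phase 0 between codons; 1 and 2 inside a codon). Classes are assigned from
intron count: class I for 11–14 introns, class II for 9, class III for 6,
otherwise unclassified. The class I band is wider than the textbook 12–14
because published class I gene sets include members with 12–15 predicted
exons (11–14 introns); classifying on intron count with the widened band
reconciles the rule with the data it is meant to describe.

Exon lengths in amino acids are reported as floor(nt/3) with the fractional
codon's remainder carried into the next exon, so per-gene totals are exact.

Splice consensus matrices cover 10 exonic + 10 intronic nt per boundary
(configurable). Per-column information content is `2 − (H + e_n)` bits with
the standard small-sample correction `e_n = 3/(2·ln2·n)`, floored at 0; the
correction choice is documented here because sequence-logo services rarely
state theirs. Columns are frequency-normalized excluding N.

## Protein properties

Molecular weight is the ExPasy-style theoretical average MW: sum of average
residue masses plus one water (75.07 Da for free glycine). Monoisotopic
masses are deliberately not used. X residues make MW undefined (error), and
the pipeline records NaN for degenerate proteins.

The isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14] to
0.005 tolerance (12 iterations suffice: 14/2¹² < 0.005). Net charge is the
Henderson–Hasselbalch sum over the termini and D, E, C, Y, H, K, R; it is
strictly decreasing in pH, so the root is unique and composition-only
(permutation-invariant). The default pKa table is Bjellqvist's — the set
behind ExPasy's Compute pI/MW — with EMBOSS and Sillero tables selectable,
because published pI values are only comparable within one pKa set. The
package's simple global table agrees with Biopython's positional Bjellqvist
variant to within a few tenths of a pH unit on random peptides.

The ≥400-residue functionality filter is applied before property
computation; products below it are called pseudogenes/partial genes.

Transit-peptide prediction is **not** reimplemented (the field uses trained
ML predictors). The field is either user-supplied or filled by a crude,
explicitly approximate heuristic: N-terminal 60 residues with S+T fraction
> 20% and net positive charge → "predicted". Type hints follow: transit
predicted → mono; absent and ≤600 aa → sesqui; otherwise unknown.

## Motifs

Motif notation: plain residues, `(A/B)` alternations, `X` wildcard,
`X<n>` fixed-length wildcard run; `RRX8W` is exactly R, R, eight wildcards,
W. Wildcards match the 20 standard residues only — X in a *protein* matches
nothing, the conservative reading of an unknown residue. All overlapping
hits are reported; completeness uses first occurrences. "Complete" means all
four generic motifs present (arginine motif, RDR, DDXXD, NSE/DTE); canonical
N→C ordering is reported separately but not enforced, since the literature
tabulates presence, not order. The packaged library (plain TSV, editable)
carries the generic kit plus TPS-a/b/g/c subfamily consensuses.

## Homology

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
PairwiseAligner; scoring is frozen at BLOSUM62 with gap open 10 / extend 0.5
(length-L gap costs 10 + 0.5L) and +5/−4 for nucleotides. Reference search
uses overlap alignment (terminal gaps free), the right model when truncated
pseudogene products are compared against full-length references.

Percent identity is 100 × matches / aligned columns with terminal-gap
columns excluded, rounded half-up — at the precision requested, directly
from the raw ratio (no double rounding). For equal-length substitution-only
pairs this reduces to matches/length: 1 difference in 559 aa → 99.82%.
Paralog pairs are unordered pairs above a 94% identity threshold, annotated
same-/cross-chromosome.

Candidate gating into the TPS set requires ≥40% identity over ≥50% query
coverage against the reference panel; both thresholds are configurable since
homology-search gating conventions vary.

## Phylogeny

Distances are p-distances with pairwise deletion of gap columns (Poisson
correction −ln(1−p) behind a flag). Neighbor joining minimizes the standard
Q criterion; ties break deterministically toward the lowest index pair, and
negative branch-length estimates are clamped to zero with the deficit
transferred to the sister branch (path lengths preserved). NJ is consistent
on additive matrices; the tests exploit this with exact-recovery oracles and
a brute-force least-squares topology search over all 105 six-taxon trees.

Bootstrap resamples alignment columns with replacement; support is the
percentage of replicate NJ trees containing each internal bipartition of the
reference tree, fully reproducible under a fixed seed. Newick output carries
supports as internal node labels and branch lengths to 6 decimals.

Subfamily assignment gives each query the subfamily of the smallest
bipartition side containing it and references of exactly one subfamily;
queries with no qualifying side are "ambiguous".

The progressive aligner (a deterministic stand-in for an interactive
multiple-alignment tool) builds an average-linkage guide tree on 3-mer
Jaccard distances and merges profiles by aligning their column consensuses,
projecting the resulting gap pattern into every row. Two sequences reduce
exactly to the pairwise aligner. Full-length alignments are used by default;
column trimming is left to the caller.

## Clusters

Tandem clusters chain genes per chromosome by single linkage when the
boundary gap (next start − current end − 1) is strictly below 67 kb;
"distance between genes" is read as the nearest-boundary gap, the
conservative choice when anchor points are unspecified, and the threshold is
configurable. Singletons are not clusters; strand is ignored for membership;
overlapping genes join with gap 0 and a warning. Genes on unplaced scaffolds
are excluded from chaining and counted separately; the clustered percentage
is reported over placed genes and, separately, over all genes, because both
denominators appear in the literature.

## Expression

RPKM categories interpolate the two anchor values of the heatmap convention
(white ≈ 0.1–0.5, saturated at 60): `<0.1` not_detected, `0.1–0.5` low
(closed at both anchors), `(0.5, 60)` moderate, `≥60` high. The moderate
band and the boundary closures are this package's documented choice; only
the extremes are anchored externally. Tissue specificity: exactly one tissue
above the 0.5 RPKM detection threshold. Heatmap preparation is log2(x+1),
average-linkage clustering on correlation distance, rows pre-sorted by id so
ordering is deterministic; constant rows get distance 1 with a warning.
These clustering settings are frozen for reproducibility since interactive
heatmap services rarely state theirs.

## Synthetic genomes

The generator is first-class, tested code. The default `FamilySpec` mirrors
a large citrus-type TPS family: 28/18/2/2/5 functional TPS-a/b/c/e-f/g genes
plus 40 pseudogenes (95 loci), 61 genes in 19 clusters of 2–6, 24 genes on
unplaced scaffolds, class III architecture (6 introns, phase vector fixed
per class) for a/b/g and class I (13 introns) for c/e-f. Intron lengths are
drawn 10% from 16–80 nt, 80% from 81–400 nt, 10% from 401–2,335 nt; introns
carry GT…AG cores with a pyrimidine before the terminal AG, and the exon
base before each donor is recoded synonymously to a purine when the code
allows (the R/GT context), which leaves the donor −1 purine fraction around
70–75% — an enrichment, as in real cohorts, not an invariant.

Each subfamily has one ancestor protein (556–800 aa, exon-length medians in
the 44–125 aa band) with its motif kit planted at fixed residue positions;
members are substitution-only mutants at 80–92% identity to the ancestor
with motifs preserved, so motif exon positions are conserved across the
family. References are separate 88%-identity mutants of the same ancestors.
Paralog pairs are planted at 96% (tandem) and 92% (cross-chromosome)
identity; `mutate_to_identity` hits its target within ±0.5 points by
construction. Pseudogenes arise by premature stop (product 120–340 aa) or
internal exon deletion, with a guaranteed sub-400-aa product. Expression
matrices draw baselines from a clipped log-normal (log-mean 1.6, sigma 1.0,
kept inside the moderate band so baseline genes are detected in all tissues)
and plant tissue-specific, high (≥60) and low (≤0.5 everywhere) genes.

All randomness flows from one seeded generator; identical specs produce
byte-identical files.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: subfamily ancestors are drawn independently, so
inter-subfamily identity is ~5–10% rather than the ~30–40% of real TPS
subfamilies, making subfamily recovery easier than in practice; intergenic
sequence is uniform random (no repeats or transposons); codon usage is
uniform; there are no alternative transcripts, no alleles, and no
annotation errors beyond the planted pseudogenes. Exact-recovery results on
these genomes validate the pipeline's logic, not its robustness to
real-world annotation noise.

## Pipeline and problem sizes

Stages run in a fixed order with per-stage tables written immediately, so a
failure retains earlier outputs and names its stage. Reruns under the same
seed and config are byte-identical (the config hash excludes the output
directory). Dispositions are exclusive: every gene is exactly one of
functional / pseudogene / non-TPS, with placement (chromosome vs unplaced
scaffold) tracked as an orthogonal flag — unplaced full-length genes still
count in subfamily totals, matching how unanchored scaffolds are treated in
genome papers.

Default bootstrap replicates are 1,000 in `PipelineConfig`; the analysis
drivers and the acceptance script run 200 replicates and the test suite
25–50, sizes chosen so the full default-family analysis completes in well
under a minute per run while supports on strong planted signals are already
saturated. The end-to-end tests use a reduced family (22 genes) for the
same reason; the full 95-gene family is exercised by the acceptance checks.
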