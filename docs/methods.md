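# Methods

## Representation of gene arrangements

A mitochondrial arrangement is a signed circular permutation over a closed
vocabulary of 38 tokens: 13 protein-coding genes (atp6, atp8, cob, cox1–3,
nad1–6, nad4L), 22 tRNAs (trnA … trnY, with trnL1 = tRNA-Leu(CUN),
trnL2 = tRNA-Leu(UUR), trnS1 = tRNA-Ser(AGN), trnS2 = tRNA-Ser(UCN)), two
rRNAs (rrnL, rrnS) and the control region (CR). '+' denotes the strand
carrying cox1 (the H-strand in the usual sense); records annotated on the
opposite convention are normalized by a whole-circle flip. Internally all
coordinates are 0-based half-open and circular; a feature spanning the
origin is stored with end > genome length. GenBank 1-based coordinates are
converted on read/write (Biopython handles the flat-file dialect; an
origin-spanning feature becomes a two-part compound location).

Annotation labels are mapped to the vocabulary through a shipped text
synonym table (`data/gene_synonyms.tsv`), so new spellings are data, not
code. Bare tRNA-Leu/tRNA-Ser labels are disambiguated from the anticodon
or codon-family suffix; with neither present they are rejected rather than
guessed.

Equality of orders is invariant under rotation and under reversal with
sign flip. The canonical form anchors cox1 first on '+'; CR is unstranded
and carries '+' by convention in every reading. One consequence worth
stating: the scenario search treats CR sign-blind as well, so an inversion
sweeping across CR is recognized as reaching the target even though CR
itself reports no orientation.

The published arrangements are frozen fixtures: the pancrustacean ground
pattern (identical to the *Thalassina kelanang* order), the shared derived
Gebiidea order and the shared derived Axiidea order. Two readings of the
source material were genuinely ambiguous and are resolved as follows: (a)
the derived Axiidea placement of trnL1 is taken as cox1–trnL1–trnL2 (the
alternative wording "between cox1 and tRNA-Leu(UUR) (L1)" labels the
second gene L1, evidently a slip for L2); (b) the relocated Gebiidea trnQ
keeps its ancestral '−' orientation, since only trnL1 (all four derived
genomes) and trnI/trnV (Axiidea) are described as inverted. The order
−trnQ, +trnD upstream of trnM in the Axiidea fixture follows the published
figure.

## Comparison statistics

Breakpoint distance counts adjacencies of one order absent from the other,
orientation-aware ((a,b) ≡ (−b,−a)); it is zero exactly when the circles
are equal. "Rearranged genes" is formalized as the minimum deletion set:
the smallest set of genes whose removal from both circles leaves identical
orders. The search is exact — iterative deepening on the set size over
subsets of genes incident to at least one breakpoint (a gene whose two
adjacencies survive in the other order cannot be in a minimum set) — and
deterministic: candidate subsets are enumerated lexicographically with CR
ordered last, so among co-minimal sets the one made of actual genes is
returned. This matters in practice: the Gebiidea/ground-pattern pair has
two co-minimal sets, one naming trnQ and one naming CR instead, and the
tie-break selects the trnQ reading (CR is a position marker, not a gene).
The subset-size cap defaults to 10 and failures to reconcile within it are
an explicit error.

## Event algebra and scenario inference

Five event kinds edit an order in place: transposition and reverse
transposition of a contiguous block to a target adjacency, inversion of a
block, TDRL (each gene of the duplicated region is assigned to copy 1 or
copy 2; the output is copy-1 genes then copy-2 genes, each in original
relative order), and paralog remolding, restricted to the biologically
motivated trnL1/trnL2 and trnS1/trnS2 pairs: the recipient is deleted at
its old position and a recipient-named copy appears adjacent to the donor,
on a chosen side, with the donor's sign. Every application validates its
preconditions (contiguity, target outside the block, both paralogs
present) and returns a valid order over the same gene set.

Scenario inference is iterative-deepening depth-first search over event
applications. Transpositions, reverse transpositions and remoldings touch
at most three adjacencies, inversions two, so ⌈breakpoints/3⌉ is an
admissible lower bound on the events still needed; a node is pruned when
bound exceeds remaining depth. Because the bound is admissible and the
deepening starts at it, the first depth that yields scenarios is provably
minimal — for the Gebiidea order (10 breakpoints) the depth-3 search is
refuted at the root, certifying the 4-event minimum, and for the Axiidea
order (15 breakpoints) the 5-event scenarios meet the bound exactly.
Candidate events are scored by an O(1) adjacency delta (vectorized over
all block/target combinations) and only survivors are materialized, which
keeps full searches on 38-gene circles in the tens of milliseconds.
Enumeration order is fixed (kind, block start, block length, target), the
search holds no randomness, and at most a configurable number of co-minimal
scenarios (default 10) is returned. TDRL is excluded from the default
inference vocabulary: a single TDRL can repair arbitrarily many
adjacencies, which degrades the admissible bound to 1 per event; it is
selectable for small problems, with duplicated regions capped (default 6
genes) to bound the 2^region assignment enumeration.

The narrative scenarios for the two derived orders are shipped as
regression fixtures. Unit events and mechanism phases are both reported:
the grouped-step view merges consecutive moves whose blocks are entirely
tRNA genes into one phase — the convention of rearrangement figures that
draw simultaneous tRNA translocations as a single step — giving 3 phases
for Gebiidea (tRNA transpositions of trnI and trnC+trnY; a
duplication/random-loss translocation of trnQ, encoded as a TDRL of the
CR–trnQ segment; trnL1 remolding) and 4 for Axiidea (reverse transposition
of trnI; duplication/random-loss translocation of cox3; trnD and trnV
moves; trnL1 remolding). The heuristic is exactly that — a labelling
convention for reporting, approximate for arbitrary inferred scenarios —
and does not feed back into the event algebra.

## Composition statistics

A+T content is (A+T)/length, case-folded; ambiguity codes and N count in
the denominator only. Percentages are reported to one decimal but stored
at full precision. Gene overlaps are circular interval intersections over
all gene pairs. Noncoding regions are the maximal circular intervals
covered by no PCG/tRNA/rRNA annotation — the CR annotation marks but does
not cover, so the control region surfaces as the largest gap; a tie for
largest is broken by higher A+T, then clockwise proximity to rrnS.
Overlapping spans are unioned before the gap computation, so shared
nucleotides are never double-counted and annotated + noncoding lengths sum
exactly to the genome length.

## Paralog similarity

tRNA paralogs are extracted in coding sense (reverse-complemented from '−'
annotations — the two Leu tRNAs sit on opposite strands in the ground
pattern) and globally aligned with match +1, mismatch −1, gap open −2, gap
extend −1, end gaps penalized. Identity is matches over all alignment
columns, gaps included, as a rounded percentage. Co-optimal tracebacks are
resolved deterministically, and the argument pair is put in canonical
order first so the statistic is symmetric. The scoring scheme and
denominator convention are one defensible choice among several; identities
from tools with other conventions can differ by a few points.

## Supermatrix assembly

The 13 protein-coding genes are extracted circular-safe in coding sense;
translation uses the invertebrate mitochondrial code (table 5), dropping
an incomplete final codon with a warning and a trailing stop silently.
Third-codon-position removal requires the coding span (after an explicit
frame offset) to be a whole number of codons — anything else is an error,
never a silent truncation — and keeps gaps in the surviving columns.
Genes are concatenated alphabetically (an arbitrary but recorded choice)
over a shared taxon set, with gap-padding for missing taxa behind an
explicit permissive flag; the partition table tiles the columns exactly.
Output formats are relaxed PHYLIP, FASTA and a RAxML-style partition
file. Multiple sequence alignment and tree inference are out of scope by
design: the module prepares inputs for external tools.

## Synthetic data

The generator emulates the statistical structure the analysis relies on,
not mitochondrial biology in full. Sequences are i.i.d. per position with
P(A) = P(T) = at_target/2 (default 0.70, the middle of the decapod
0.66–0.74 range); gene lengths are uniform per class — protein-coding
160–1,800 nt rounded down to whole codons, tRNA 61–73 nt, rRNA 700–1,400
nt, CR 91–1,200 nt; intergenic spacers of 1–56 nt appear at random
junctions (probability 0.3, never next to CR so the CR gap stays intact),
and the atp8/atp6 and nad4/nad4L pairs share 7 terminal nucleotides
whenever they remain adjacent on the same strand. Spacers are strictly
shorter than the minimum CR length, so the control region is always the
unique largest noncoding region. Histories sample events from a
configurable mix (default: transposition 0.5, inversion 0.2, reverse
transposition 0.2, remolding 0.1, TDRL 0 — matching the default inference
vocabulary); a remolded recipient receives the donor sequence with a
configured number of point mutations (default 5, i.e. ~92% identity on a
65-nt tRNA). One seeded generator drives everything: identical
configuration gives byte-identical output, and the replayed history is
asserted to reproduce the final order on every call.

What passing tests on this generator do **not** show: real codon
structure, strand-asymmetric substitution, selection, or annotation noise
— composition statistics on real genomes will deviate from the i.i.d.
ideal, and noncoding totals can differ by a few nucleotides depending on
how overlaps were annotated.

## Problem sizes used in the shipped checks

Oracle cross-checks run on 500 (test suite) / 200 (acceptance script)
random signed circles of 4–12 genes derived by 1–3 elementary moves;
minimality certification against brute-force breadth-first enumeration
uses circles of 5–8 genes at depth ≤ 3; parameter recovery uses 100 seeded
histories of 1–3 events on full 38-token genomes. These sizes make every
check exact (not sampled approximations of a larger claim) while the whole
suite runs in well under a minute.

## Known limitations

- Inversion distance (Hannenhalli–Pevzner) and DCJ are deliberately not
  implemented; breakpoint distance plus explicit scenario search covers
  the intended analyses.
- The minimum-deletion formalization permits CR in a deletion set; the
  tie-break merely deprioritizes it.
- Scenario counts ("all minimal scenarios") may include mechanistically
  equivalent complement-block variants of the same circular move; the
  reporting cap bounds their number.
- The GenBank reader expects one circular record with conventional
  qualifiers; EMBL/DDBJ dialects and multi-record files are out of scope.
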