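# Methods

## The observation model

The unit of observation is a Sanger-sequenced plasmid clone: one cDNA or
gDNA molecule of a gene's coding amplicon, labelled with gene, tissue and
individual. Genomic clones from the same individuals show no variation, so
the per-column majority over aligned gDNA clones serves as the invariant
genomic reference; any residual disagreement among gDNA clones is treated
as possible allelic variation, recorded as a variable position and masked
from RDD calling rather than called. An RDD is then any aligned column
where a cDNA clone differs from that consensus: a substitution, an
insertion, or a deletion. The pipeline makes no attempt to separate true
RNA editing from reverse-transcription or polymerase errors — that
distinction is not identifiable from clone sequences alone and is out of
scope; the optional uniform error channel in the simulator exists precisely
to probe how such noise would contaminate calls.

## Alignment

Clones are near-identical to one short reference (amplicons of a few
hundred bases), so each clone is aligned pairwise and globally to the
consensus with Gotoh's three-state affine-gap dynamic programme instead of
a multiple alignment; columnwise comparison against the one reference is
then equivalent and fully specified. Scoring defaults are match +2,
mismatch −2, gap open −6, gap extend −1: gaps are expensive relative to
mismatches, which suppresses spurious indels in near-identical pairs while
still allowing the real 1–12-base deletions the data contain
(a 12-base deletion costs −17, far less than 12 mismatches). All four
parameters are configurable integers with gap open ≤ gap extend ≤ 0.

Traceback ties are broken diagonal > deletion > insertion, and every gap
run is then shifted to its leftmost equivalent placement (a run moves one
step left whenever the base entering the run on the left equals the base
leaving it on the right, which preserves both the score and the multiset of
edit operations). Event positions are therefore canonical: the same edit
always produces the same 1-based coordinate. The row-wise DP is vectorised
with numpy (the within-row gap state is a running maximum, computed with a
cumulative-maximum trick), which keeps a 500-clone screen in seconds.

## Calling and nomenclature

Events are read off aligned columns in reference coordinates; insertions
anchor to the reference base they follow (terminal insertions to the
reference length). Contiguous single-base deletions merge into one
multi-base deletion event; deletions separated by unchanged bases stay
separate events, with a report-level grouping helper (window ≤ 3) for
display conventions that join near-adjacent deletions — contiguity is
well-defined, whereas the display grouping rule is not, so calling sticks
to the former. Names follow the RNA-level dialect (`r.68c>a`, `r.187a<`,
`r.115_116at<`, `r.181-192ga<`, `r.317a>`). The range-deletion form prints
only the first and last deleted bases, so it is lossy for deletions of
three or more bases; the parser reconstructs the full deleted allele when
given the reference sequence and otherwise marks the interior as unknown.

## Effect classification

Each clone's variant amplicon is re-translated from the same reading-frame
offset as the reference (`orf_offset` is an explicit per-gene input: clone
coordinate systems in this kind of table do not always start at the
initiator codon, so the offset cannot be inferred). Classification:

* protein unchanged → **silent** (this includes indels confined to the
  UTRs, whatever their length);
* net indel length not a multiple of 3 → **frameshift**, split *early*
  (variant protein shorter than native, `fs…*e`) / *late* (longer,
  `fs…*l`) by protein length rather than stop-base position, which stays
  well-defined under arbitrary indel combinations;
* in-frame net deletion with a changed protein → **motif deletion**;
* equal-length transcript whose translation stops early → **stop-gain**;
* anything else in frame → **missense**. In-frame net insertions and
  substitutions that destroy the native stop have no category of their own
  in the five-type scheme and are deliberately folded into missense; they
  are vanishingly rare under the simulator's event mix.

Frameshift names anchor at the codon containing the first cDNA-level
change, not the first changed residue: an insertion into the third base of
a proline CCN codon re-encodes proline, yet the convention still names that
proline as first affected (`fsPro90*e`). Stop-gain and missense names use
the first protein-level difference. Motif-deletion names span from the
first changed residue over the deleted codon count (`deleAsp45-Pro48`).

Reported residue counts are the number of residues before the first stop,
with one convention switch: for stop-gains the default (`stop_position`)
reports the index of the mutated residue — one more than the chain length —
because that is how such tables print it; a strict `length` convention is
selectable. Masses are average (not monoisotopic) residue masses plus one
water, reported in kDa to two decimals, matching protein-style molecular
weight figures. Variants whose translation never reaches a stop codon are
flagged `aborted` but still classified and reported, as are variants whose
first affected residue lies inside a configured signal-peptide region.

## Statistics

* **Spectrum** — counts over the 12 ordered substitution classes
  (A>C … T>G); conservation: total = number of substitution events.
* **3′-context bias** — the fraction of substitution sites whose 3′
  reference neighbour is A, tested two-sided with an exact binomial test
  against the reference's own background A frequency at internal
  positions. A binomial test (not chi-square) because this is a
  single-category enrichment with potentially small counts; it is a single
  planned test, so no multiple-testing correction is applied (the report
  notes this).
* **Gene × tissue matrix** — every event counts once; totals are emitted
  with the table and checked for consistency.
* **Synonymous split** — per-event codon comparison under the standard
  genetic code; events outside the ORF are counted in neither bin and
  logged.
* **Rates** — both events-per-clone and events-per-kb-per-clone are
  reported, the per-kb-per-clone figure as the headline, because a bare
  "rate" leaves the denominator ambiguous across genes of different
  lengths.
* **Clustering** — tissues are clustered by complete linkage on Euclidean
  distances (scipy), with heights exported and the tree written as Newick.
  The default feature space is per-site event counts per tissue (clones
  without RDDs contribute nothing and so are implicitly excluded); a
  12-class spectrum-per-tissue feature space is selectable, since the exact
  feature matrix behind this kind of tissue dendrogram is ambiguous —
  both layouts are supported and documented.

## The simulator

The generator emulates the study design, not the chemistry: random gene
models (1–3 exons, ORFs of 90–115 codons, optional decorative retroposon
annotations, either strand), mutation-free gDNA clone sets, and per-tissue
cDNA clone sets whose per-clone event counts are Poisson. Defaults are the
study conditions: five tissues (antennae, legs, head, wings, pheromone
gland) at 0.8 RDDs per clone — the scale implied by per-gene totals of
~30–90 events over ~25 clones per tissue — with the pheromone gland
multiplied by 3 ("two to three times more"); substitution classes weighted
116 : 48 : 41 : 30 : 19 for A>G, T>C, G>A, C>T, G>T (the reported top
five) and 6 for each remaining class; 5% insertions (single-base) and 5%
deletions (1–12 contiguous bases, matching observed event shapes); 10
clones per tissue and 10 gDNA clones.

Two placement rules make ground truth exact rather than approximate:
events within a clone are spaced at least 10 bases apart (removes
alignment degeneracy between neighbouring events), and indels are only
planted at left-canonical positions — a draw whose deletion or insertion
could slide one step left into an equivalent placement is redrawn. Under
these rules the left-normalising aligner recovers every planted event at
its planted coordinate, and the truth-manifest recovery tests assert
precision = recall = 1.0 exactly. There is no sequencing-error channel by
default (Sanger consensus clones are clean); a uniform substitution error
rate can be switched on for robustness experiments, and such errors are
deliberately absent from the manifest.

What the simulator does **not** model: chromatogram-level noise, PCR
recombination, reverse-transcriptase error signatures, allelic variation
in gDNA, secondary-structure-dependent editing hotspots, or realistic
retroposon sequence content. Passing recovery tests therefore demonstrates
the correctness of the computational pipeline under clean, well-separated
events — not that real clone sets are free of confounders.

## Numerical and procedural choices

* Internal coordinates are 0-based half-open; everything reported is
  1-based on the amplicon, matching the nomenclature dialect.
* Ambiguity codes are rejected, not expanded (clone consensus inputs are
  unambiguous).
* Consensus majority ties break toward the reference base; a
  majority-deletion column falls back to the reference base and is flagged
  variable.
* DP scores are exact: all quantities are integer-valued in float64.
* The alignment brute-force oracle used in tests enumerates monotone
  matchings with closed-form affine gap costs per segment — exhaustive
  over alignment classes yet tractable to length 10.
* Dendrogram heights are compared against a brute-force agglomeration
  oracle on random float matrices, where distance ties have probability
  zero; tie order between equal merges is otherwise scipy's.
* Problem sizes in the test suite (500-clone recovery, 1,000-variant
  oracle sweeps, 10,000 planted substitutions for spectrum calibration,
  100 seeded clustering runs) were chosen to give each statistical check
  at least 3-standard-error resolution while keeping the default suite
  around twenty seconds.

## Known limitations

* Alignment equivalence classes are canonicalised only for repeat-driven
  gap placement; pathological equal-score alignments mixing gaps and
  mismatches could in principle place an event differently, though the
  default scoring makes exact score ties of that kind effectively
  unreachable at the planted event spacing.
* The five-type effect scheme is per clone: multiple events in one clone
  are classified jointly from the full variant transcript, so one
  dominant category is reported even when a clone carries, say, a missense
  change upstream of a frameshift.
* Printed clone-table coordinates in this domain are not always internally
  consistent across rows (different clones can carry private indels that
  shift coordinates); the package treats the reference amplicon plus
  explicit `orf_offset` as the single coordinate authority.
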