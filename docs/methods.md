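# Methods

## The comparative model

The pipeline rests on one idea: a protein-coding gene leaves a footprint
of cross-species conservation that annotation pipelines can miss but an
all-ORF comparison cannot. Every maximal ORF ≥ 99 bp is treated as a
candidate; the intergenic ones (those sharing no genomic space with any
annotated entity) are queried against the full ORF set, and similarity —
filtered hard for significance and mutual coverage — is the only evidence
used. Because phylogenetically close genomes share intergenic sequence
through lack of divergence rather than through function, similarity
between intergenic ORFs only counts when query and subject come from
**different taxonomic families**; family, rather than species or genus,
is used because lower ranks are too inconsistently assigned in
prokaryotes to proxy for distance. No requirement is placed on
similarity to annotated genes: an intergenic ORF matching an annotated
gene anywhere is evidence of a gap in its own genome's annotation
regardless of taxonomy, which makes the missing-gene label deliberately
the most conservative of the four.

## Definitions and conventions

* **Coordinates.** Internally 0-based, half-open, forward-strand, for
  both strands; emitted files are 1-based inclusive. An ORF interval
  covers the coding sequence and *excludes* the stop codon, so the 99-bp
  length floor equals exactly 33 aa.
* **Maximality.** For each in-frame stop, the ORF anchors at the furthest
  upstream start (ATG/GTG/TTG) with no intervening in-frame stop. ORFs
  truncated by a linear sequence end have no stop and are discarded —
  they are not maximal ORFs. Circular replicons are scanned across the
  origin (each wrapping ORF reported once, coding length capped at the
  replicon length); linear is the default since most archived sequence
  lacks reliable topology metadata.
* **Context.** *Annotated* means a gene feature on the same strand shares
  the ORF's stop-codon boundary (with or without the stop codon in the
  annotated interval, since conventions differ); requiring identical
  intervals would misclassify every annotation that chose a different
  start codon. *Entity-overlapping* means ≥ 1 bp of shared genomic space
  — strand-blind, stop codon included, against features of all kinds
  (genes, RNAs, pseudogenes). A 5′-overlapping ORF gets one rescue
  attempt: re-anchoring at the 5′-most in-frame start that removes all
  overlap while keeping ≥ 99 bp. Overlap at the 3′ end is never
  rescuable because the stop, not the start, is the ORF's anchor.
* **Average percent identity I.** The mean of (identities / query
  length) and (identities / subject length), ×100. Coverage is the
  aligned span (end − start + 1) over the sequence length, computed for
  query and subject separately; both must reach 80 %.
* **α = I₁ − I₂.** I₁ is the highest I among supporting alignments, I₂
  the highest among conflicting ones; α = I₁ when no conflict exists.
  For missing genes, conflicts are alignments to annotated genes *or*
  entity-overlapping ORFs; for absent annotations, only
  entity-overlapping alignments conflict. α is reported unclamped (it
  can be negative in principle, e.g. an absent annotation whose
  entity-overlapping match outscores its gene match).

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `min_len` | 99 | bp (coding) | shortest candidate ORF; 33 aa |
| `max_evalue` | 1e-5 | — | alignment significance cutoff (inclusive) |
| `min_cov` | 80 | % | required of query *and* subject |
| `max_hits_per_query` | 1000 | hits | output cap, lowest e-values kept |
| `diff_threshold` | 20 | coverage points | gap below the top supporting hit that conflicting hits must respect for a missing call |
| `flank` | 30 | bp | ultra-conservation window on each side |
| `min_mum_len` | 19 | bp | shortest exact match counted by MUMi |

`diff_threshold` is read as 20 *absolute* percentage points of average
coverage (the quantities are already percentages); the top-scoring
supporting hit is the one with the lowest e-value, ties broken by higher
I and then subject id, so every ranking in the pipeline is total and
deterministic.

## Alignment backends

The built-in aligner is exact Smith–Waterman/Gotoh (Biopython's
`PairwiseAligner`, local mode) under BLOSUM62 with affine gaps costing
`11 + k` for a gap of length k, and Karlin–Altschul e-values
`E = K·m·n·exp(−λS)` with the standard gapped constants λ = 0.267,
K = 0.041 and n the total subject-set residue count. It exists so that
desk-scale runs and every test are self-contained and reproducible;
genome-scale runs should ingest the 12-column tabular report of a
dedicated search tool instead (`read_alignment_report`), whose e-values
are trusted as-is. Identity counts recovered from a report's percent
identity are rounded to the nearest integer. Self-hits are always
removed: the query set is a subset of the subject database, so every
query would otherwise trivially "align to an intergenic sequence".

## Stage order and precedence

Stage-1 clauses are evaluated in the order potentially-missing → absent →
artifact → unclassified. The differential-coverage rule decides missing
vs not; absent outranks artifact because the α definition for absent
annotations treats only entity-overlapping alignments as conflicts,
implying gene similarity is the stronger, overriding signal. Queries
whose only intergenic similarity is same-family fall through to
unclassified — removing those hits never changes any label, a property
the tests enforce.

Stage-2 edges connect pairs of *potentially missing* ORFs joined by a
qualifying (cross-family, screened) alignment; an alignment to any other
ORF cannot link clusters. Components are computed by single linkage
(transitive closure); clusters lacking two members from two families are
demoted to unclassified, with the near-miss reason (singleton vs
single-family) retained for triage in the classification report.

## Supporting metrics

* **GC3** — G+C fraction at third codon positions, computed on the coding
  sequence without its stop; useful because GC-rich genomes inflate both
  spurious ORF length and GC3 of real genes.
* **MUMi** — `1 − L_mum / mean(len_a, len_b)`, where `L_mum` is the total
  length of a greedy longest-first non-overlapping tiling of maximal
  exact matches ≥ 19 bp that are unique in both sequences (both strands
  of the second sequence considered). 0 for identical sequences,
  approaching 1 for unrelated ones. Matches are found by seed-and-extend
  at desk scale; no suffix-tree machinery is needed for the genome sizes
  this package targets. Group-level MUMi picks one representative
  replicon per family (lexicographically smallest id, for determinism)
  and averages over all family pairs.
* **Ultra-conservation** — a group is flagged when all members' 30-bp
  upstream flanks are mutually identical *and* likewise downstream
  (flanks read in gene orientation, truncated at sequence ends). Exact
  identity is used instead of a multiple alignment: "perfect
  conservation" and exact flank identity are the same predicate.
* Ribosome-binding-site and protein-domain evidence are accepted only as
  precomputed per-ORF tables merged into reports; the package never runs
  those predictors.

## The synthetic pan-genome

The generator's purpose is exact ground truth, not realism. Its one
structural trick is the stop cassette `TTAATTAATTAA`: stop codons in all
six frames, no G (hence no ATG/GTG/TTG), and equal to its own reverse
complement. Every planted element is assembled into a block bracketed by
cassettes, and all spacer DNA is punctuated by cassettes at most 48 nt
apart, so no reading frame can run more than a few codons across any
boundary — structurally excluding spurious ≥ 99-bp ORFs outside the
blocks. Blocks that must contain exactly one ORF (missing-gene plants,
annotated genes) are rejection-sampled until their shifted frames and
opposite strand are clean. Planted missing families share a fixed 30-bp
A/C/T flank across copies (making them ultra-conserved by construction
and keeping the scanner's start anchored); per-copy point mutations at
`mutation_rate` never touch the start or stop and never create an
in-frame stop, so truth coordinates survive mutation. Absent annotations
are verbatim unannotated copies of a gene annotated in another family's
replicon. Shadow ORFs are planted ORFs whose stop codon is overlapped by
a decoy annotation — un-rescuable by construction, since rescue can only
move the start.

Defaults (4 families × 2 replicons of 12 kb, 5 genes per replicon, 10
missing families copied into 2 families each, 5 absents, 10 shadows,
mutation rate 0) describe the smallest community in which every label,
the family filter, clustering and the group metrics are all exercised;
the noiseless setting is the regime in which recovery must be exact.
What passing tests on this generator do *not* show: robustness to indels
and rearrangements, to biased codon usage, to annotation conventions in
the wild, or to alignment sensitivity at real evolutionary distances —
the generator has none of those properties.

## Numerical and degenerate-input choices

Codons containing N never act as start or stop codons and translate to X;
initiator GTG/TTG render as M (standard prokaryotic convention, affecting
only the first aligned residue). `AlignmentHit` derives I and coverages
once at construction, so invariants cannot drift. Ties everywhere break
lexicographically (subject id, replicon id, member id) to make reruns
byte-identical; group representatives default to the smallest member id,
with an optional seed restoring randomized choice. MUMi is clamped to
[0, 1]; mean group statistics are plain arithmetic means.

## Problem sizes

The bundled tests run the full pipeline on communities of 8 replicons of
12 kb (~80 ORFs, ~2·10³ pairwise alignments), the scanner oracle on 2-kb
sequences, clustering oracles on graphs of ≤ 200 nodes, and MUMi oracles
on 1-kb instances — sizes chosen so the whole suite exercises every
stage in seconds while remaining exhaustive at the level of rules
(coverage-differential grid, boundary e-values, flank truncation).
Genome-scale searches are explicitly out of scope for the built-in
aligner and belong to an external search tool feeding
`read_alignment_report`.

## Known limitations

* The built-in aligner's e-values use fixed Karlin–Altschul constants;
  they are reproducible but not bit-compatible with any particular
  external tool.
* Whether coverage should be span-based (as here) or
  alignment-length-based is a genuine convention choice; at 80 % with
  few gaps the two rarely disagree.
* The family filter inherits every weakness of the taxonomy it is given:
  families with unusually diverse genomes are over-filtered, and
  misassigned replicons leak same-family similarity into the
  cross-family class.
* Plasmids shared across families can produce low-MUMi groups whose
  conservation reflects recent transfer rather than ancient descent; the
  MUMi column exists precisely to flag those.
* ORFs wrapping a circular origin are supported by the scanner, but the
  synthetic generator only emits linear replicons.
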