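"""Enumerate all maximal ORFs of a toy replicon on both strands.

A maximal ORF anchors at the start codon furthest upstream of its stop
without an intervening in-frame stop; only coding lengths >= 99 bp
(33 aa) are kept, matching the shortest gene size the pipeline screens.
"""

from intergene import Replicon, find_maximal_orfs

# A 102-bp gene on the forward strand and a second one embedded on the
# reverse strand, separated by stop-rich spacer.
gene_fwd = "ATG" + "GAA" * 32 + "TAA"
gene_rev = "ATG" + "TGC" * 40 + "TAG"
revcomp = gene_rev.translate(str.maketrans("ACGT", "TGCA"))[::-1]
seq = "TTAATTAATTAA" + gene_fwd + "TTAATTAATTAA" + revcomp + "TTAATTAATTAA"

replicon = Replicon("toy", seq, topology="linear")
for orf in find_maximal_orfs(replicon, min_len=99):
    print(f"{orf.orf_id:26s} strand={orf.strand} {orf.aa_len:3d} aa  {orf.aa_seq[:12]}...")
# Coordinates are 0-based half-open on the forward strand and exclude the
# stop codon, so a 99-bp interval is exactly a 33-residue protein.  Note
# the repetitive reverse-strand gene also spawns a second, overlapping ORF
# in a shifted frame — exactly the kind of shadow ORF the classification
# stage has to contend with.
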