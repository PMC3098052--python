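"""Compute the alpha uniqueness score for a hand-built query.

A query ORF supported by a cross-family intergenic alignment of average
percent identity I = 80, with one conflicting alignment to an annotated
gene of I = 60, scores alpha = I1 - I2 = 20.  alpha near 100 means the
classification rests on strong, uncontradicted similarity; alpha near 0
means the evidence is ambiguous.
"""

from intergene import AlignmentHit, Orf, alpha_score, partition_hits, stage1_label

query = Orf("FAMA_R1|+|300-450", "FAMA_R1", 300, 450, "+", "ATG" + "GCT" * 49, "M" + "A" * 49)

supporting = AlignmentHit(
    query_id=query.orf_id,
    subject_id="FAMB_R1|+|700-850",
    e_value=1e-20,
    n_identities=40,  # 40/50 on both sides -> I = 80
    q_span=50, s_span=50, q_len=50, s_len=50,
)
conflicting = AlignmentHit(
    query_id=query.orf_id,
    subject_id="FAMC_R1|+|900-1050",
    e_value=1e-12,
    n_identities=30,  # I = 60
    q_span=40, s_span=40, q_len=50, s_len=50,  # coverage 80: 20 points below
)

contexts = {supporting.subject_id: "intergenic", conflicting.subject_id: "annotated"}
families = {"FAMA_R1": "FAMA", "FAMB_R1": "FAMB", "FAMC_R1": "FAMC"}

part = partition_hits(query, [supporting, conflicting], contexts, families)
classification = stage1_label(query, part)
alpha = alpha_score("missing_gene", classification.supporting_hits, classification.conflicting_hits)

print(f"stage-1 label : {classification.label}")
print(f"I1 (support)  : {supporting.I:.1f}")
print(f"I2 (conflict) : {conflicting.I:.1f}")
print(f"alpha         : {alpha:.1f}")
# The 20-point score says the missing-gene call is supported, but an
# alignment to an annotated gene erodes a fifth of the confidence.
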