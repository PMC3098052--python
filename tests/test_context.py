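"""Genomic-context partition and the 3' start-rescue rule."""

from __future__ import annotations

import pytest

from intergene.context import FeatureIndex, assign_context, classify_orfs, rescue_start
from intergene.model import Feature, Orf, Replicon
from intergene.orfs import find_maximal_orfs

from conftest import make_orf, random_dna


def index_of(*features, length=None):
    return FeatureIndex(features, length)


class TestAssignContext:
    def test_no_features_is_intergenic(self):
        orf = make_orf(start=100, end=199)
        assert assign_context(orf, index_of()) == "intergenic"

    def test_exact_cds_match_is_annotated(self):
        orf = make_orf(start=100, end=199)
        # Annotation includes the stop codon, as CDS records usually do.
        feat = Feature("FAMQ_R1", "gene", 100, 202, "+")
        assert assign_context(orf, index_of(feat)) == "annotated"

    def test_different_start_same_stop_is_still_annotated(self):
        # Annotations often pick a different start codon; identity is the
        # shared 3' boundary on the same strand.
        orf = make_orf(start=100, end=199)
        feat = Feature("FAMQ_R1", "gene", 130, 202, "+")
        assert assign_context(orf, index_of(feat)) == "annotated"

    def test_same_interval_opposite_strand_is_overlapping(self):
        orf = make_orf(start=100, end=199)
        feat = Feature("FAMQ_R1", "gene", 100, 202, "-")
        assert assign_context(orf, index_of(feat)) == "entity_overlapping"

    def test_minus_strand_annotated_by_start_boundary(self):
        orf = make_orf(start=100, end=199, strand="-")
        feat = Feature("FAMQ_R1", "gene", 97, 199, "-")  # includes stop at [97,100)
        assert assign_context(orf, index_of(feat)) == "annotated"

    def test_rna_overlap_is_entity_overlapping(self):
        orf = make_orf(start=100, end=199)
        feat = Feature("FAMQ_R1", "rna", 190, 260, "+")
        assert assign_context(orf, index_of(feat)) == "entity_overlapping"

    def test_stop_codon_counts_in_overlap(self):
        orf = make_orf(start=100, end=199)  # stop occupies [199, 202)
        feat = Feature("FAMQ_R1", "rna", 201, 260, "+")
        assert assign_context(orf, index_of(feat)) == "entity_overlapping"
        feat_clear = Feature("FAMQ_R1", "rna", 202, 260, "+")
        assert assign_context(orf, index_of(feat_clear)) == "intergenic"

    def test_sliding_orf_against_fixed_feature_matches_interval_arithmetic(self):
        """Slide a 30-codon ORF across one fixed feature; the label must agree
        with direct interval arithmetic at every placement."""
        feat = Feature("FAMQ_R1", "rna", 300, 360, "+")
        idx = index_of(feat)
        for start in range(150, 500, 3):
            end = start + 90
            orf = make_orf(start=start, end=end)
            occupied = (start, end + 3)  # stop codon included
            expected = (
                "entity_overlapping"
                if occupied[0] < 360 and 300 < occupied[1]
                else "intergenic"
            )
            assert assign_context(orf, idx) == expected, f"placement {start}"


class TestRescueStart:
    def _orf_with_inframe_starts(self):
        # 60 codons; in-frame ATGs at codon 0, 5 and 10.
        nt = "ATG" + "AAA" * 4 + "ATG" + "AAA" * 4 + "ATG" + "AAA" * 49
        orf = Orf("r|+|0-180", "r", 0, 180, "+", nt, "M" + "K" * 4 + "M" + "K" * 4 + "M" + "K" * 49)
        return orf

    def test_five_prime_overlap_rescued_to_next_start(self):
        orf = self._orf_with_inframe_starts()
        idx = index_of(Feature("r", "gene", 0, 10, "+"))  # overlaps first 10 bp
        rescued = rescue_start(orf, idx, min_len=99)
        assert rescued.start == 15 and rescued.end == 180
        assert rescued.rescued
        assert assign_context(rescued, idx) == "intergenic"

    def test_rescue_picks_five_prime_most_qualifying_start(self):
        orf = self._orf_with_inframe_starts()
        idx = index_of(Feature("r", "gene", 0, 3, "+"))  # only the original start overlaps
        rescued = rescue_start(orf, idx, min_len=99)
        assert rescued.start == 15  # first in-frame start clearing the feature

    def test_three_prime_overlap_cannot_be_rescued(self):
        orf = self._orf_with_inframe_starts()  # stop codon at [180, 183)
        idx = index_of(Feature("r", "gene", 181, 240, "+"))
        assert rescue_start(orf, idx, min_len=99) is orf

    def test_rescue_respects_min_len(self):
        orf = self._orf_with_inframe_starts()
        # Clearing the overlap would need the start at 90, leaving 90 bp < 99.
        idx = index_of(Feature("r", "gene", 0, 88, "+"))
        assert rescue_start(orf, idx, min_len=99) is orf

    def test_rescue_is_idempotent_and_overlap_free(self):
        orf = self._orf_with_inframe_starts()
        idx = index_of(Feature("r", "gene", 0, 10, "+"))
        once = rescue_start(orf, idx, min_len=99)
        assert rescue_start(once, idx, min_len=99) is once
        lo, hi = once.start, once.end + 3
        assert not idx.overlapping(lo, hi)


class TestPartitionProperty:
    def test_every_orf_gets_exactly_one_label(self, rng):
        """Contexts partition the ORF set: label counts sum to the total."""
        for _ in range(5):
            seq = random_dna(rng, 4000)
            rep = Replicon("r", seq)
            orfs = find_maximal_orfs(rep)
            n = int(rng.integers(1, 6))
            feats = []
            for _ in range(n):
                s = int(rng.integers(0, 3800))
                feats.append(Feature("r", "gene", s, s + int(rng.integers(30, 200)), "+"))
            labeled = classify_orfs(orfs, feats)
            counts = {ctx: sum(1 for o in labeled if o.context == ctx)
                      for ctx in ("annotated", "entity_overlapping", "intergenic")}
            assert sum(counts.values()) == len(labeled) == len(orfs)
            assert all(o.context is not None for o in labeled)
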