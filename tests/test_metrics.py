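"""GC content, GC3, MUMi distance, and the flank ultra-conservation check."""

from __future__ import annotations

import pytest

from intergene.metrics import (
    gc3,
    gc_content,
    group_mumi,
    mumi,
    orf_flanks,
    ultra_conserved,
)
from intergene.model import MissingGeneGroup, Orf, Replicon, TaxonomyRecord

from conftest import random_dna
from oracles import mumi_oracle, revcomp


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
    def test_closed_forms(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_n_excluded_from_both_sides(self):
        assert gc_content("GCNN") == pytest.approx(1.0)

    def test_matches_counting_oracle(self, rng):
        seq = random_dna(rng, 1000, gc=0.6)
        expected = sum(c in "GC" for c in seq) / len(seq)
        assert gc_content(seq) == pytest.approx(expected)


class TestGc3:
    @pytest.mark.parametrize("cds,expected", [("ATGGCG", 1.0), ("ATAGCA", 0.0)])
    def test_closed_forms(self, cds, expected):
        assert gc3(cds) == pytest.approx(expected)

    def test_equals_gc_content_of_every_third_base(self, rng):
        cds = random_dna(rng, 300, gc=0.64)
        assert gc3(cds) == pytest.approx(gc_content(cds[2::3]))

    def test_partial_codons_rejected(self):
        with pytest.raises(ValueError):
            gc3("ATGGC")


class TestMumi:
    def test_identical_sequences_have_zero_distance(self, rng):
        for length in (19, 100, 1000):
            seq = random_dna(rng, length)
            assert mumi(seq, seq) == pytest.approx(0.0)

    def test_unrelated_sequences_near_one(self, rng):
        a, b = random_dna(rng, 2000), random_dna(rng, 2000)
        assert mumi(a, b) > 0.9

    def test_symmetry(self, rng):
        a = random_dna(rng, 800)
        b = a[:400] + random_dna(rng, 400)
        assert mumi(a, b) == pytest.approx(mumi(b, a), abs=1e-12)

    def test_reverse_strand_matches_count(self, rng):
        a = random_dna(rng, 500)
        assert mumi(a, revcomp(a)) == pytest.approx(0.0)

    def test_matches_brute_force_oracle_on_small_instances(self, rng):
        """Agreement with an independent run-length-DP implementation on
        1-kb instances with planted shared segments."""
        for _ in range(5):
            shared = random_dna(rng, int(rng.integers(50, 200)))
            a = random_dna(rng, 400) + shared + random_dna(rng, 400)
            b = random_dna(rng, 300) + shared + random_dna(rng, 500)
            assert mumi(a, b) == pytest.approx(mumi_oracle(a, b))
            c = random_dna(rng, 1000)
            assert mumi(a, c) == pytest.approx(mumi_oracle(a, c))

    def test_divergence_ordering_recovered(self, rng):
        """A lightly mutated copy is closer than an unrelated sequence."""
        a = random_dna(rng, 2000)
        mutated = list(a)
        for i in rng.choice(len(a), size=40, replace=False):  # 2% divergence
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        close = mumi(a, "".join(mutated))
        far = mumi(a, random_dna(rng, 2000))
        assert close < far


def _toy_group_setup(rng):
    reps = {
        "F1_R1": Replicon("F1_R1", random_dna(rng, 600)),
        "F2_R1": Replicon("F2_R1", random_dna(rng, 600)),
        "F3_R1": Replicon("F3_R1", random_dna(rng, 600)),
    }
    tax = {
        rid: TaxonomyRecord(rid, "O", rid.split("_")[0], "G") for rid in reps
    }
    group = MissingGeneGroup(
        "MG1",
        ["F1_R1|+|0-99", "F2_R1|+|0-99", "F3_R1|+|0-99"],
        {"F1", "F2", "F3"},
    )
    member_reps = {m: m.split("|")[0] for m in group.member_orf_ids}
    return group, member_reps, reps, tax


class TestGroupMumi:
    def test_three_families_average_three_pairs(self, rng):
        group, member_reps, reps, tax = _toy_group_setup(rng)
        expected = (
            mumi(reps["F1_R1"].sequence, reps["F2_R1"].sequence)
            + mumi(reps["F1_R1"].sequence, reps["F3_R1"].sequence)
            + mumi(reps["F2_R1"].sequence, reps["F3_R1"].sequence)
        ) / 3
        assert group_mumi(group, member_reps, reps, tax) == pytest.approx(expected)

    def test_two_families_is_single_pair(self, rng):
        group, member_reps, reps, tax = _toy_group_setup(rng)
        group.member_orf_ids = group.member_orf_ids[:2]
        expected = mumi(reps["F1_R1"].sequence, reps["F2_R1"].sequence)
        assert group_mumi(group, member_reps, reps, tax) == pytest.approx(expected)


class TestUltraConserved:
    def _members(self, rng, flank_up, flank_down, n=3, mismatch_at=None):
        members, reps = [], {}
        core = "ATG" + "GCA" * 32 + "TAA"
        for i in range(n):
            up, down = flank_up, flank_down
            if i == mismatch_at:
                up = "T" + up[1:]
            seq = random_dna(rng, 50) + up + core + down + random_dna(rng, 50)
            rid = f"R{i}"
            start = 50 + len(up)
            orf = Orf(f"{rid}|+|{start}-{start + 99}", rid, start, start + 99, "+",
                      core[:-3], "M" + "A" * 32)
            reps[rid] = Replicon(rid, seq)
            members.append(orf)
        return members, reps

    def test_identical_flanks_true(self, rng):
        up, down = random_dna(rng, 30), random_dna(rng, 30)
        members, reps = self._members(rng, up, down)
        assert ultra_conserved(members, reps) is True

    def test_single_mismatch_false(self, rng):
        up, down = random_dna(rng, 30), random_dna(rng, 30)
        members, reps = self._members(rng, up, down, mismatch_at=1)
        assert ultra_conserved(members, reps) is False

    def test_order_invariant(self, rng):
        up, down = random_dna(rng, 30), random_dna(rng, 30)
        members, reps = self._members(rng, up, down, n=4, mismatch_at=2)
        assert ultra_conserved(members, reps) == ultra_conserved(members[::-1], reps)

    def test_reverse_strand_flanks_in_gene_orientation(self, rng):
        """A '-' strand ORF's flanks are read on its own strand, so a plus-
        and a minus-strand copy with the same oriented context agree."""
        up, down = random_dna(rng, 30), random_dna(rng, 30)
        core = "ATG" + "GCA" * 32 + "TAA"
        plus_seq = random_dna(rng, 40) + up + core + down + random_dna(rng, 40)
        start = 40 + 30
        plus = Orf(f"P|+|{start}-{start + 99}", "P", start, start + 99, "+", core[:-3], "M" + "A" * 32)
        minus_seq = revcomp(plus_seq)
        L = len(minus_seq)
        m_start, m_end = L - (start + 99), L - start
        minus = Orf(f"M|-|{m_start}-{m_end}", "M", m_start, m_end, "-", core[:-3], "M" + "A" * 32)
        reps = {"P": Replicon("P", plus_seq), "M": Replicon("M", minus_seq)}
        assert orf_flanks(plus, reps["P"]) == orf_flanks(minus, reps["M"])
        assert ultra_conserved([plus, minus], reps) is True

    def test_flanks_truncated_at_replicon_ends(self):
        core = "ATG" + "GCA" * 32 + "TAA"
        seq = "AC" + core + "GT"
        orf = Orf("R|+|2-101", "R", 2, 101, "+", core[:-3], "M" + "A" * 32)
        up, down = orf_flanks(orf, Replicon("R", seq))
        assert (up, down) == ("AC", "GT")
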