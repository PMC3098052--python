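"""Stage-1 labeling: the family filter and the coverage-differential rule."""

from __future__ import annotations

import pytest

from intergene.model import LABEL_ABSENT, LABEL_ARTIFACT, LABEL_POTENTIAL, LABEL_UNCLASSIFIED
from intergene.stage1 import PartitionedHits, partition_hits, stage1_label

from conftest import make_hit, make_orf

FAMILIES = {"FAMQ_R1": "FAMQ", "FAMQ_R2": "FAMQ", "FAMX_R1": "FAMX"}


def subject_hit(replicon, n, **kw):
    return make_hit(subject_id=f"{replicon}|+|{n * 1000}-{n * 1000 + 99}", **kw)


class TestPartitionHits:
    def test_same_family_intergenic_hits_segregated(self):
        q = make_orf()
        h = subject_hit("FAMQ_R2", 1)
        contexts = {h.subject_id: "intergenic"}
        part = partition_hits(q, [h], contexts, FAMILIES)
        assert part.intergenic == [] and part.same_family_intergenic == [h]

    def test_gene_hits_have_no_family_requirement(self):
        q = make_orf()
        h = subject_hit("FAMQ_R1", 2)  # the query's own replicon
        part = partition_hits(q, [h], {h.subject_id: "annotated"}, FAMILIES)
        assert part.gene == [h]

    def test_partition_sizes_sum_to_input(self):
        q = make_orf()
        hits, contexts = [], {}
        for i, (rep, ctx) in enumerate(
            [("FAMX_R1", "intergenic"), ("FAMQ_R2", "intergenic"),
             ("FAMX_R1", "annotated"), ("FAMQ_R1", "entity_overlapping"),
             ("FAMX_R1", "entity_overlapping")]
        ):
            h = subject_hit(rep, i)
            hits.append(h)
            contexts[h.subject_id] = ctx
        part = partition_hits(q, hits, contexts, FAMILIES)
        total = (len(part.intergenic) + len(part.gene) + len(part.entity)
                 + len(part.same_family_intergenic))
        assert total == len(hits)
        assert len(part.intergenic) == 1 and len(part.same_family_intergenic) == 1

    def test_missing_taxonomy_is_an_error_naming_the_replicon(self):
        q = make_orf()
        h = subject_hit("GHOST_R9", 1)
        with pytest.raises(KeyError, match="GHOST_R9"):
            partition_hits(q, [h], {h.subject_id: "intergenic"}, FAMILIES)


class TestStage1Label:
    def _part(self, intergenic=(), gene=(), entity=(), samefam=()):
        return PartitionedHits(list(intergenic), list(gene), list(entity), list(samefam))

    def test_pure_cross_family_intergenic_is_potentially_missing(self):
        c = stage1_label(make_orf(), self._part(intergenic=[make_hit()]))
        assert c.label == LABEL_POTENTIAL

    def test_small_coverage_gap_demotes_to_absent(self):
        # Top intergenic avg_cov 95, gene hit avg_cov 80: gap 15 < 20.
        sup = make_hit(subject_id="i", avg_cov=95.0)
        gene = make_hit(subject_id="g", avg_cov=80.0)
        c = stage1_label(make_orf(), self._part(intergenic=[sup], gene=[gene]))
        assert c.label == LABEL_ABSENT

    def test_gap_of_exactly_20_points_keeps_potentially_missing(self):
        sup = make_hit(subject_id="i", avg_cov=100.0)
        gene = make_hit(subject_id="g", avg_cov=80.0)
        c = stage1_label(make_orf(), self._part(intergenic=[sup], gene=[gene]))
        assert c.label == LABEL_POTENTIAL

    def test_differential_rule_on_coverage_grid(self):
        """Exhaustive check of the 20-point rule over an avg_cov grid."""
        for top_cov in range(80, 101, 5):
            for conflict_cov in range(0, 101, 5):
                sup = make_hit(subject_id="i", avg_cov=float(top_cov))
                gene = make_hit(subject_id="g", avg_cov=float(conflict_cov))
                c = stage1_label(make_orf(), self._part(intergenic=[sup], gene=[gene]))
                expected = LABEL_POTENTIAL if conflict_cov <= top_cov - 20 else LABEL_ABSENT
                assert c.label == expected, (top_cov, conflict_cov)

    def test_entity_only_is_artifact_and_no_hits_unclassified(self):
        assert stage1_label(make_orf(), self._part(entity=[make_hit()])).label == LABEL_ARTIFACT
        assert stage1_label(make_orf(), self._part()).label == LABEL_UNCLASSIFIED

    def test_only_same_family_intergenic_is_unclassified(self):
        c = stage1_label(make_orf(), self._part(samefam=[make_hit()]))
        assert c.label == LABEL_UNCLASSIFIED

    def test_top_scoring_is_lowest_evalue_not_highest_coverage(self):
        # The low-coverage hit has the better e-value, so it sets the bar.
        top = make_hit(subject_id="i1", e_value=1e-20, avg_cov=85.0)
        other = make_hit(subject_id="i2", e_value=1e-8, avg_cov=100.0)
        gene = make_hit(subject_id="g", avg_cov=70.0)  # gap to top: 15 < 20
        c = stage1_label(make_orf(), self._part(intergenic=[top, other], gene=[gene]))
        assert c.label == LABEL_ABSENT

    def test_adding_gene_hits_never_promotes_absent_to_missing(self):
        """Monotonicity: extra conflicting evidence cannot create a missing call."""
        sup = make_hit(subject_id="i", avg_cov=90.0)
        close_gene = make_hit(subject_id="g1", avg_cov=85.0)
        part = self._part(intergenic=[sup], gene=[close_gene])
        assert stage1_label(make_orf(), part).label == LABEL_ABSENT
        more = self._part(intergenic=[sup], gene=[close_gene, make_hit(subject_id="g2", avg_cov=10.0)])
        assert stage1_label(make_orf(), more).label == LABEL_ABSENT

    def test_removing_same_family_hits_never_changes_the_label(self):
        for part_kw in (
            dict(intergenic=[make_hit(subject_id="i")]),
            dict(gene=[make_hit(subject_id="g")]),
            dict(entity=[make_hit(subject_id="e")]),
            dict(),
        ):
            with_sf = self._part(samefam=[make_hit(subject_id="sf")], **part_kw)
            without = self._part(**part_kw)
            assert stage1_label(make_orf(), with_sf).label == stage1_label(make_orf(), without).label

    def test_labels_partition_any_query_set(self, rng):
        """Mutual exclusivity/exhaustiveness: label counts sum to the query count."""
        labels = []
        for _ in range(300):
            part = self._part(
                intergenic=[make_hit(subject_id="i", avg_cov=float(rng.uniform(80, 100)))]
                if rng.random() < 0.5 else [],
                gene=[make_hit(subject_id="g", avg_cov=float(rng.uniform(0, 100)))]
                if rng.random() < 0.5 else [],
                entity=[make_hit(subject_id="e", avg_cov=float(rng.uniform(0, 100)))]
                if rng.random() < 0.5 else [],
            )
            labels.append(stage1_label(make_orf(), part).label)
        counts = {lab: labels.count(lab) for lab in set(labels)}
        assert sum(counts.values()) == 300
        assert set(counts) <= {LABEL_POTENTIAL, LABEL_ABSENT, LABEL_ARTIFACT, LABEL_UNCLASSIFIED}
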