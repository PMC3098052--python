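"""Stage-1 classification of intergenic query ORFs.

From its filtered hits and the taxonomy of their subjects, each query is
labeled:

* ``potentially_missing`` — at least one hit to an intergenic subject from
  a different taxonomic family, and every hit to an annotated gene or
  entity-overlapping ORF has an average coverage at least
  ``diff_threshold`` percentage points below that of the top-scoring
  intergenic hit;
* ``absent_annotation`` — otherwise, if it hits any annotated gene
  (no phylogenetic requirement);
* ``genomic_artifact`` — otherwise, if it hits any entity-overlapping ORF;
* ``unclassified`` — no qualifying hits (including queries whose only
  intergenic hits are within their own family).

Taxonomic family is a proxy for phylogenetic distance: close relatives
share intergenic sequence through lack of divergence, so same-family
intergenic similarity never supports a missing-gene call.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .align import top_hit
from .model import (
    CONTEXT_ANNOTATED,
    CONTEXT_ENTITY_OVERLAPPING,
    CONTEXT_INTERGENIC,
    LABEL_ABSENT,
    LABEL_ARTIFACT,
    LABEL_POTENTIAL,
    LABEL_UNCLASSIFIED,
    AlignmentHit,
    Classification,
    Orf,
)

DEFAULT_DIFF_THRESHOLD = 20.0  # percentage points of average coverage


@dataclass(slots=True)
class PartitionedHits:
    """A query's filtered hits split by subject context and family."""

    intergenic: list[AlignmentHit]  # cross-family intergenic subjects only
    gene: list[AlignmentHit]  # annotated subjects, any family
    entity: list[AlignmentHit]  # entity-overlapping subjects, any family
    same_family_intergenic: list[AlignmentHit]


def _replicon_of(orf_id: str) -> str:
    return orf_id.rsplit("|", 2)[0]


def partition_hits(
    query: Orf,
    hits: Sequence[AlignmentHit],
    contexts: Mapping[str, str],
    families: Mapping[str, str],
) -> PartitionedHits:
    """Split a query's hits by subject context, segregating same-family
    intergenic hits (which never support a missing-gene classification)."""
    query_family = families.get(query.replicon_id)
    if query_family is None:
        raise KeyError(f"no taxonomy for query replicon {query.replicon_id!r}")
    part = PartitionedHits([], [], [], [])
    for h in hits:
        ctx = contexts.get(h.subject_id)
        if ctx is None:
            raise KeyError(f"no context for subject {h.subject_id!r}")
        if ctx == CONTEXT_ANNOTATED:
            part.gene.append(h)
        elif ctx == CONTEXT_ENTITY_OVERLAPPING:
            part.entity.append(h)
        elif ctx == CONTEXT_INTERGENIC:
            subject_replicon = _replicon_of(h.subject_id)
            subject_family = families.get(subject_replicon)
            if subject_family is None:
                raise KeyError(f"no taxonomy for subject replicon {subject_replicon!r}")
            if subject_family != query_family:
                part.intergenic.append(h)
            else:
                part.same_family_intergenic.append(h)
        else:
            raise ValueError(f"subject {h.subject_id!r} has unknown context {ctx!r}")
    return part


def stage1_label(
    query: Orf,
    part: PartitionedHits,
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
) -> Classification:
    """Assign the Stage-1 label for one query from its partitioned hits.

    The supporting/conflicting hit lists stored on the result follow the
    uniqueness-score convention: for a potentially missing gene the
    conflicts are all gene and entity hits; for an absent annotation only
    entity hits conflict; artifacts carry their entity hits as support.
    """
    conflicts = part.gene + part.entity
    if part.intergenic:
        top = top_hit(part.intergenic)
        if all(h.avg_cov <= top.avg_cov - diff_threshold for h in conflicts):
            return Classification(
                orf_id=query.orf_id,
                label=LABEL_POTENTIAL,
                supporting_hits=list(part.intergenic),
                conflicting_hits=conflicts,
            )
    if part.gene:
        return Classification(
            orf_id=query.orf_id,
            label=LABEL_ABSENT,
            supporting_hits=list(part.gene),
            conflicting_hits=list(part.entity),
        )
    if part.entity:
        return Classification(
            orf_id=query.orf_id,
            label=LABEL_ARTIFACT,
            supporting_hits=list(part.entity),
        )
    return Classification(orf_id=query.orf_id, label=LABEL_UNCLASSIFIED)


def classify_queries(
    queries: Sequence[Orf],
    hits_by_query: Mapping[str, Sequence[AlignmentHit]],
    contexts: Mapping[str, str],
    families: Mapping[str, str],
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD,
) -> dict[str, Classification]:
    """Stage-1 labels for a whole query set."""
    out: dict[str, Classification] = {}
    for q in queries:
        part = partition_hits(q, hits_by_query.get(q.orf_id, ()), contexts, families)
        out[q.orf_id] = stage1_label(q, part, diff_threshold)
    return out
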