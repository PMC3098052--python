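"""Genomic-context partition of ORFs against the annotation.

Every ORF receives exactly one of three labels:

* ``annotated`` — a gene feature on the same strand shares the ORF's
  stop-codon boundary (annotations frequently differ in their chosen start
  codon, so coinciding 3' ends, not identical intervals, define identity);
* ``entity_overlapping`` — any feature of any kind shares at least one bp
  of genomic space with the ORF (stop codon included), strand-blind;
* ``intergenic`` — neither of the above.

A 5'-overlapping ORF may be rescued by re-anchoring its start codon closer
to the 3' end, which undoes false overlaps created by always choosing the
most upstream start.
"""

from __future__ import annotations

from collections.abc import Iterable

from intervaltree import IntervalTree

from .model import (
    CONTEXT_ANNOTATED,
    CONTEXT_ENTITY_OVERLAPPING,
    CONTEXT_INTERGENIC,
    Feature,
    Orf,
    orf_id_for,
)
from .orfs import START_CODONS


class FeatureIndex:
    """Interval index over the features of one replicon."""

    def __init__(self, features: Iterable[Feature], replicon_length: int | None = None):
        self.tree = IntervalTree()
        self.features = list(features)
        self.replicon_length = replicon_length
        for f in self.features:
            self.tree[f.start : f.end] = f

    def _segments(self, start: int, end: int) -> list[tuple[int, int]]:
        """Split an interval that may wrap a circular origin into linear pieces."""
        L = self.replicon_length
        if L is None:
            return [(max(start, 0), end)]
        segs = []
        if start < 0:  # stop codon of a '-' ORF wrapping leftwards
            segs.append((start % L, L))
            start = 0
        if end > L:
            segs.append((0, end % L if end % L else L))
            end = L
        segs.append((start, end))
        return [(a, b) for a, b in segs if a < b]

    def overlapping(self, start: int, end: int) -> list[Feature]:
        found = []
        for a, b in self._segments(start, end):
            found.extend(iv.data for iv in self.tree.overlap(a, b))
        return found


def _occupied_interval(orf: Orf) -> tuple[int, int]:
    """Forward-strand interval of the ORF including its stop codon."""
    if orf.strand == "+":
        return orf.start, orf.end + 3
    return orf.start - 3, orf.end


def assign_context(orf: Orf, index: FeatureIndex) -> str:
    """Classify one ORF as annotated / entity_overlapping / intergenic."""
    lo, hi = _occupied_interval(orf)
    L = index.replicon_length
    for f in index.overlapping(lo, hi):
        if f.kind != "gene" or f.strand != orf.strand:
            continue
        # Same 3' boundary, with or without the stop codon in the annotation.
        if orf.strand == "+":
            boundaries = {orf.end, orf.end + 3}
            if L is not None:
                boundaries |= {(b - 1) % L + 1 for b in boundaries}
            if f.end in boundaries:
                return CONTEXT_ANNOTATED
        else:
            boundaries = {orf.start, orf.start - 3}
            if L is not None:
                boundaries |= {b % L for b in boundaries}
            if f.start in boundaries:
                return CONTEXT_ANNOTATED
    if index.overlapping(lo, hi):
        return CONTEXT_ENTITY_OVERLAPPING
    return CONTEXT_INTERGENIC


def rescue_start(orf: Orf, index: FeatureIndex, min_len: int) -> Orf:
    """Re-anchor an entity-overlapping ORF at a later start codon if that
    removes all feature overlap while keeping coding length >= ``min_len``.

    The 5'-most qualifying start is chosen, preserving maximality among the
    overlap-free choices.  If no start qualifies (including when the overlap
    involves the 3' end) the ORF is returned unchanged.
    """
    length = orf.end - orf.start
    for trim in range(0, length - min_len + 1, 3):
        codon = orf.nt_seq[trim : trim + 3]
        if codon not in START_CODONS:
            continue
        if trim == 0:  # already overlap-free: nothing to rescue (idempotence)
            lo, hi = _occupied_interval(orf)
            if not index.overlapping(lo, hi):
                return orf
            continue
        if orf.strand == "+":
            new_start, new_end = orf.start + trim, orf.end
        else:
            new_start, new_end = orf.start, orf.end - trim
        candidate = Orf(
            orf_id=orf_id_for(orf.replicon_id, orf.strand, new_start, new_end),
            replicon_id=orf.replicon_id,
            start=new_start,
            end=new_end,
            strand=orf.strand,
            nt_seq=orf.nt_seq[trim:],
            aa_seq="M" + orf.aa_seq[trim // 3 + 1 :] if trim // 3 < len(orf.aa_seq) else "",
            rescued=True,
        )
        lo, hi = _occupied_interval(candidate)
        if not index.overlapping(lo, hi):
            return candidate
    return orf


def classify_orfs(
    orfs: Iterable[Orf],
    features: Iterable[Feature],
    replicon_length: int | None = None,
    min_len: int = 99,
) -> list[Orf]:
    """Assign contexts to all ORFs of one replicon, applying start rescue.

    Entity-overlapping ORFs are given one rescue attempt and re-classified.
    Returns the (possibly re-anchored) ORFs with ``context`` set.
    """
    index = FeatureIndex(features, replicon_length)
    out: list[Orf] = []
    for orf in orfs:
        ctx = assign_context(orf, index)
        if ctx == CONTEXT_ENTITY_OVERLAPPING:
            rescued = rescue_start(orf, index, min_len)
            if rescued is not orf:
                orf = rescued
                ctx = assign_context(orf, index)
        orf.context = ctx
        out.append(orf)
    return out
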