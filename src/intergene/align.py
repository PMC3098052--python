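"""All-vs-all protein alignment: a built-in exact local aligner plus hit filtering.

The built-in backend is an exact Smith-Waterman/Gotoh local aligner
(BLOSUM62, affine gaps costing ``open + k * extend`` for a gap of length
k) with Karlin-Altschul e-values, suitable for desk-scale runs and tests.
Genome-scale runs ingest the tabular report of an external search tool
instead (:func:`intergene.io.read_alignment_report`); both paths feed the
same filtered-hit contract.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .model import AlignmentHit, Orf

# Karlin-Altschul gapped constants for BLOSUM62 with gap penalties 11/1.
LAMBDA = 0.267
K = 0.041

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(str(_BLOSUM62.alphabet))


def _make_aligner(gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    # Biopython charges open_gap_score for the first gapped position, so a
    # gap of length k costs open + k * extend under the convention here.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def e_value(score: float, query_len: int, db_size_aa: int) -> float:
    """Karlin-Altschul expectation: E = K * m * n * exp(-lambda * S)."""
    return K * query_len * db_size_aa * math.exp(-LAMBDA * score)


def local_align(
    query_aa: str,
    subject_aa: str,
    db_size_aa: int,
    query_id: str = "query",
    subject_id: str = "subject",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentHit | None:
    """Best local alignment of two protein sequences, or None if none scores > 0.

    Identities, aligned spans and the e-value (with ``db_size_aa`` as the
    database size) are derived from the optimal alignment.
    """
    if not query_aa or not subject_aa:
        raise ValueError("empty protein sequence")
    for seq, name in ((query_aa, query_id), (subject_aa, subject_id)):
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"{name}: non-amino-acid symbols {sorted(bad)}")
    aligner = _make_aligner(gap_open, gap_extend)
    if aligner.score(query_aa, subject_aa) <= 0:
        return None
    alignment = next(iter(aligner.align(query_aa, subject_aa)))
    counts = alignment.counts()
    q_blocks, s_blocks = alignment.aligned
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    s_span = int(s_blocks[-1][1] - s_blocks[0][0])
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        e_value=e_value(alignment.score, len(query_aa), db_size_aa),
        n_identities=int(counts.identities),
        q_span=q_span,
        s_span=s_span,
        q_len=len(query_aa),
        s_len=len(subject_aa),
    )


def align_all(
    queries: Sequence[Orf],
    subjects: Sequence[Orf],
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> list[AlignmentHit]:
    """Align every query against every subject (self-pairs skipped).

    The effective database size is the total residue count of the subject
    set, mirroring how search tools scale their e-values.
    """
    db_size_aa = sum(len(s.aa_seq) for s in subjects)
    hits: list[AlignmentHit] = []
    for q in queries:
        for s in subjects:
            if q.orf_id == s.orf_id:
                continue
            hit = local_align(
                q.aa_seq,
                s.aa_seq,
                db_size_aa,
                query_id=q.orf_id,
                subject_id=s.orf_id,
                gap_open=gap_open,
                gap_extend=gap_extend,
            )
            if hit is not None:
                hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    max_evalue: float = 1e-5,
    min_cov: float = 80.0,
    max_hits_per_query: int = 1000,
) -> list[AlignmentHit]:
    """Screen alignments: e-value <= cutoff, both coverages >= min_cov,
    self-hits removed, and at most ``max_hits_per_query`` hits per query
    ranked by ascending e-value (ties: descending I, then subject id)."""
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.e_value <= max_evalue and h.cov_q >= min_cov and h.cov_s >= min_cov:
            by_query[h.query_id].append(h)
    kept: list[AlignmentHit] = []
    for query_id in sorted(by_query):
        ranked = sorted(by_query[query_id], key=lambda h: (h.e_value, -h.I, h.subject_id))
        kept.extend(ranked[:max_hits_per_query])
    return kept


def top_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Top-scoring hit: lowest e-value, ties broken by highest I, then subject id."""
    if not hits:
        raise ValueError("empty hit list")
    return min(hits, key=lambda h: (h.e_value, -h.I, h.subject_id))
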