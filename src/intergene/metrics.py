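"""Supporting sequence metrics: GC content, GC3, the MUMi genome distance,
and the flank ultra-conservation check for missing-gene groups.

MUMi summarises how much of two genomes is covered by maximal exact
matches that are unique in both (MUMs): identical genomes score 0,
unrelated genomes approach 1.  It correlates well with average nucleotide
identity and serves here as a sanity check that the families represented
in a missing-gene group are genuinely diverged.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

from Bio.Seq import reverse_complement

from .model import MissingGeneGroup, Orf, Replicon, TaxonomyRecord

DEFAULT_MIN_MUM_LEN = 19
DEFAULT_FLANK = 30


def gc_content(seq: str) -> float:
    """Fraction of G+C among unambiguous bases (N excluded from both sides)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    denom = len(seq) - seq.count("N")
    if denom == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / denom


def gc3(cds: str) -> float:
    """Fraction of codons whose third base is G or C (pass coding sequence
    without the stop codon)."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"coding sequence length {len(cds)} not divisible by 3")
    if not cds:
        raise ValueError("empty sequence")
    third = cds[2::3]
    return (third.count("G") + third.count("C")) / len(third)


def _count_occurrences(haystack: str, needle: str) -> int:
    """Occurrences including overlapping ones."""
    count = 0
    i = haystack.find(needle)
    while i != -1:
        count += 1
        i = haystack.find(needle, i + 1)
    return count


def _maximal_matches(a: str, b: str, min_len: int) -> set[tuple[int, int, int]]:
    """All maximal exact matches >= min_len between a and b as (ia, ib, length).

    Seed-and-extend over ``min_len``-mers; each match is extended to
    maximality and recorded once.
    """
    if len(a) < min_len or len(b) < min_len:
        return set()
    index: dict[str, list[int]] = {}
    for i in range(len(a) - min_len + 1):
        index.setdefault(a[i : i + min_len], []).append(i)
    matches: set[tuple[int, int, int]] = set()
    seen: set[tuple[int, int]] = set()  # (diagonal, ia) of an already-extended seed
    for j in range(len(b) - min_len + 1):
        for i in index.get(b[j : j + min_len], ()):
            key = (i - j, i)
            if key in seen:
                continue
            lo_i, lo_j = i, j
            while lo_i > 0 and lo_j > 0 and a[lo_i - 1] == b[lo_j - 1]:
                lo_i -= 1
                lo_j -= 1
            hi_i, hi_j = i + min_len, j + min_len
            while hi_i < len(a) and hi_j < len(b) and a[hi_i] == b[hi_j]:
                hi_i += 1
                hi_j += 1
            for k in range(lo_i, hi_i - min_len + 1):
                seen.add((i - j, k))
            matches.add((lo_i, lo_j, hi_i - lo_i))
    return matches


def mumi(seq_a: str, seq_b: str, min_mum_len: int = DEFAULT_MIN_MUM_LEN) -> float:
    """MUM-index distance in [0, 1] between two nucleotide sequences.

    Maximal exact matches (both strands of ``seq_b`` considered) that are
    unique in both sequences and >= ``min_mum_len`` are tiled greedily,
    longest first, without overlap; the distance is
    ``1 - L_mum / mean(len_a, len_b)``, clamped to [0, 1].
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a, b = seq_a.upper(), seq_b.upper()
    b_rc = reverse_complement(b)

    candidates: list[tuple[int, int, int, str]] = []
    for strand, bseq in (("+", b), ("-", b_rc)):
        for ia, ib, length in _maximal_matches(a, bseq, min_mum_len):
            candidates.append((ia, ib, length, strand))

    # Uniqueness in both genomes: the matched string occurs exactly once in
    # a, and exactly once in b counting both strands.
    mums: list[tuple[int, int, int, str]] = []
    for ia, ib, length, strand in candidates:
        s = a[ia : ia + length] if strand == "+" else b_rc[ib : ib + length]
        if _count_occurrences(a, s) != 1:
            continue
        if _count_occurrences(b, s) + _count_occurrences(b_rc, s) != 1:
            continue
        mums.append((ia, ib, length, strand))

    # Greedy non-overlapping tiling, longest first (deterministic ties).
    mums.sort(key=lambda m: (-m[2], m[0], m[1], m[3]))
    used_a: list[tuple[int, int]] = []
    used_b: list[tuple[int, int]] = []
    l_mum = 0
    for ia, ib, length, strand in mums:
        a_iv = (ia, ia + length)
        if strand == "+":
            b_iv = (ib, ib + length)
        else:  # map reverse-strand coordinates back onto b
            b_iv = (len(b) - ib - length, len(b) - ib)
        if any(a_iv[0] < e and s < a_iv[1] for s, e in used_a):
            continue
        if any(b_iv[0] < e and s < b_iv[1] for s, e in used_b):
            continue
        used_a.append(a_iv)
        used_b.append(b_iv)
        l_mum += length

    dist = 1.0 - l_mum / ((len(a) + len(b)) / 2.0)
    return min(1.0, max(0.0, dist))


def group_mumi(
    group: MissingGeneGroup,
    member_replicons: Mapping[str, str],
    replicons: Mapping[str, Replicon],
    taxonomy: Mapping[str, TaxonomyRecord],
    min_mum_len: int = DEFAULT_MIN_MUM_LEN,
) -> float:
    """Average MUMi across one representative replicon per family in a group.

    The representative of each family is the lexicographically smallest
    replicon id among the group's members of that family; the mean is over
    all unordered family pairs.
    """
    by_family: dict[str, str] = {}
    for orf_id in group.member_orf_ids:
        rid = member_replicons[orf_id]
        fam = taxonomy[rid].family
        if fam not in by_family or rid < by_family[fam]:
            by_family[fam] = rid
    reps = sorted(by_family.values())
    if len(reps) < 2:
        raise ValueError(f"group {group.group_id}: needs representatives from >= 2 families")
    dists = [
        mumi(replicons[ra].sequence, replicons[rb].sequence, min_mum_len)
        for i, ra in enumerate(reps)
        for rb in reps[i + 1 :]
    ]
    return sum(dists) / len(dists)


def orf_flanks(orf: Orf, replicon: Replicon, flank: int = DEFAULT_FLANK) -> tuple[str, str]:
    """Upstream and downstream flanking sequence of an ORF, in gene
    orientation, truncated at linear replicon ends.

    Upstream precedes the start codon; downstream follows the stop codon.
    """
    seq = replicon.sequence
    L = len(seq)
    if orf.strand == "+":
        up = seq[max(0, orf.start - flank) : orf.start]
        down = seq[orf.end + 3 : min(L, orf.end + 3 + flank)]
    else:
        up = reverse_complement(seq[orf.end : min(L, orf.end + flank)])
        down = reverse_complement(seq[max(0, orf.start - 3 - flank) : orf.start - 3])
    return up, down


def ultra_conserved(
    member_orfs: Sequence[Orf],
    replicons: Mapping[str, Replicon],
    flank: int = DEFAULT_FLANK,
) -> bool:
    """True iff all members share identical upstream flanks and identical
    downstream flanks (each taken in gene orientation)."""
    if not member_orfs:
        raise ValueError("empty group")
    flanks = [orf_flanks(o, replicons[o.replicon_id], flank) for o in member_orfs]
    ups = {u for u, _ in flanks}
    downs = {d for _, d in flanks}
    return len(ups) == 1 and len(downs) == 1
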