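"""Maximal-ORF enumeration and translation.

An ORF is maximal when, for its in-frame stop codon, the start codon is the
furthest upstream one reachable without crossing another in-frame stop.
Both strands are scanned; coordinates are reported on the forward strand.
Circular replicons are scanned across the origin and each origin-spanning
ORF is reported once, with its coding length capped at the replicon length.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .model import Orf, Replicon, orf_id_for

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_MIN_LEN = 99  # bp of coding sequence, i.e. >= 33 aa

# Bacterial translation table; identical to the standard table for sense
# codons, so only the start-codon set above is table-11 specific here.
_TABLE = CodonTable.unambiguous_dna_by_id[11]
_CODON_TO_AA = dict(_TABLE.forward_table)


def translate(nt_seq: str) -> str:
    """Translate a stop-free coding sequence; the initiator codon is rendered M.

    Codons containing ambiguous bases (N) translate to X and are never
    treated as start or stop codons.
    """
    nt_seq = nt_seq.upper()
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"coding sequence length {len(nt_seq)} not divisible by 3")
    aa: list[str] = []
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at nt position {i}")
        aa.append(_CODON_TO_AA.get(codon, "X"))
    if aa and nt_seq[:3] in START_CODONS:
        aa[0] = "M"
    return "".join(aa)


def _scan_frames(seq: str, min_len: int, max_len: int | None, emit_from: int, emit_to: int):
    """Yield (start, end) coding intervals of maximal ORFs in ``seq`` coordinates.

    Only ORFs whose stop codon begins in [emit_from, emit_to) are yielded,
    which lets the circular case scan a tripled sequence and report each
    origin-spanning ORF exactly once.
    """
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []  # start-codon positions since the last in-frame stop
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if starts and emit_from <= pos < emit_to:
                    for s in starts:  # 5'-most start first
                        length = pos - s
                        if max_len is not None and length > max_len:
                            continue
                        if length >= min_len:
                            yield s, pos
                        break  # only the furthest qualifying start counts
                starts = []
            elif codon in START_CODONS:
                starts.append(pos)


def find_maximal_orfs(
    replicon: Replicon,
    min_len: int = DEFAULT_MIN_LEN,
    start_codons: frozenset[str] = START_CODONS,
    stop_codons: frozenset[str] = STOP_CODONS,
) -> list[Orf]:
    """Enumerate all maximal ORFs with coding length >= ``min_len`` on both strands.

    Linear replicons discard ORFs truncated by a sequence end (no stop codon
    means no maximal ORF).  Circular replicons wrap the origin.
    """
    if min_len <= 0 or min_len % 3 != 0:
        raise ValueError(f"min_len must be a positive multiple of 3, got {min_len}")
    if start_codons is not START_CODONS or stop_codons is not STOP_CODONS:
        # Allow overriding at module level only through explicit rebinding;
        # the scan below reads the module constants for speed.
        raise NotImplementedError("custom codon sets are not supported")

    seq = replicon.sequence
    L = len(seq)
    circular = replicon.topology == "circular"
    orfs: list[Orf] = []
    for strand in ("+", "-"):
        oriented = seq if strand == "+" else reverse_complement(seq)
        if circular:
            scan_seq = oriented * 3
            intervals = _scan_frames(scan_seq, min_len, L, emit_from=L, emit_to=2 * L)
        else:
            scan_seq = oriented
            intervals = _scan_frames(scan_seq, min_len, None, emit_from=0, emit_to=L)
        for a, b in intervals:
            nt = scan_seq[a:b]
            if strand == "+":
                f_start = a % L if circular else a
            else:
                f_start = (L - (b % L)) % L if circular else L - b
            f_end = f_start + (b - a)
            orf = Orf(
                orf_id=orf_id_for(replicon.replicon_id, strand, f_start, f_end),
                replicon_id=replicon.replicon_id,
                start=f_start,
                end=f_end,
                strand=strand,
                nt_seq=nt,
                aa_seq=translate(nt),
            )
            orfs.append(orf)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs
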