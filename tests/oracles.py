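"""Independent reference implementations used only to check the package.

Each oracle is written from the definition of the quantity, using a
different algorithmic route than the implementation under test: six-frame
pair enumeration for ORFs, a hand-written codon table, quadratic Gotoh
dynamic programming for local alignment, breadth-first search for
connected components, and a run-length DP for maximal exact matches.
"""

from __future__ import annotations

from collections import deque

_COMP = str.maketrans("ACGTN", "TGCAN")

STARTS = {"ATG", "GTG", "TTG"}
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_orfs(seq: str, min_len: int, circular: bool = False):
    """All maximal ORFs >= min_len as a set of (start, end, strand) forward
    coordinates (end may exceed the length for origin-wrapping ORFs).

    For every in-frame stop, every upstream start codon is enumerated and
    the furthest one without an intervening in-frame stop is kept.  On
    circular sequences the upstream walk wraps the origin and is capped at
    one full sequence length.
    """
    L = len(seq)
    found = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)

        def codon(p: int) -> str:
            if circular:
                return "".join(s[(p + k) % L] for k in range(3))
            return s[p : p + 3]

        stop_positions = []
        if circular:
            stop_positions = [p for p in range(L) if codon(p) in STOPS]
        else:
            stop_positions = [p for p in range(L - 2) if codon(p) in STOPS]
        for p in stop_positions:
            best = None
            k = 1
            while 3 * k <= L:
                q = (p - 3 * k) % L if circular else p - 3 * k
                if not circular and q < 0:
                    break
                c = codon(q)
                if c in STOPS:
                    break
                if c in STARTS:
                    best = (q, 3 * k)
                k += 1
            if best is None:
                continue
            start, length = best
            if length < min_len:
                continue
            if strand == "+":
                f_start = start
            else:
                f_start = (L - (start + length) % L) % L if circular else L - (start + length)
            found.add((f_start, f_start + length, strand))
    return found


# Hand-written standard codon table (bacterial sense codons are identical).
_ORACLE_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(nt: str) -> str:
    aa = []
    for i in range(0, len(nt), 3):
        c = nt[i : i + 3]
        aa.append(_ORACLE_TABLE.get(c, "X"))
    if nt[:3] in STARTS:
        aa[0] = "M"
    return "".join(aa)


def gotoh_local_score(a: str, b: str, matrix, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Textbook affine-gap local alignment score; a gap of length k costs
    open + k * extend."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion from a)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            sub = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def bfs_components(nodes, edges):
    """Connected components by breadth-first search, as sorted tuples."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    components = []
    for n in sorted(adj):
        if n in seen:
            continue
        comp = []
        queue = deque([n])
        seen.add(n)
        while queue:
            u = queue.popleft()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    queue.append(v)
        components.append(tuple(sorted(comp)))
    return sorted(components)


def _runlength_matches(a: str, b: str, min_len: int):
    """Maximal exact matches via the match-run DP table (quadratic)."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    matches = set()
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
        for j in range(1, m + 1):
            run = cur[j]
            if run < min_len:
                continue
            ended = i == n or j == m or a[i] != b[j]
            if ended:
                matches.add((i - run, j - run, run))
        prev = cur
    return matches


def _count_overlapping(hay: str, needle: str) -> int:
    c, i = 0, hay.find(needle)
    while i != -1:
        c += 1
        i = hay.find(needle, i + 1)
    return c


def mumi_oracle(a: str, b: str, min_len: int = 19) -> float:
    """MUM-index distance recomputed from the definition with DP matching."""
    b_rc = revcomp(b)
    cands = []
    for strand, bs in (("+", b), ("-", b_rc)):
        for ia, ib, length in _runlength_matches(a, bs, min_len):
            s = a[ia : ia + length]
            if _count_overlapping(a, s) != 1:
                continue
            if _count_overlapping(b, s) + _count_overlapping(b_rc, s) != 1:
                continue
            cands.append((ia, ib, length, strand))
    cands.sort(key=lambda m: (-m[2], m[0], m[1], m[3]))
    used_a, used_b, total = [], [], 0
    for ia, ib, length, strand in cands:
        aiv = (ia, ia + length)
        biv = (ib, ib + length) if strand == "+" else (len(b) - ib - length, len(b) - ib)
        if any(aiv[0] < e and s < aiv[1] for s, e in used_a):
            continue
        if any(biv[0] < e and s < biv[1] for s, e in used_b):
            continue
        used_a.append(aiv)
        used_b.append(biv)
        total += length
    return min(1.0, max(0.0, 1.0 - total / ((len(a) + len(b)) / 2)))
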