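"""Shared domain types and coordinate conventions.

All internal coordinates are 0-based, half-open, on the forward strand,
for features and ORFs on either strand.  Emitted files use the standard
1-based inclusive convention of GFF3 and friends.

An :class:`Orf` interval covers the coding sequence only — the stop codon
sits immediately 3' of the interval.  A minimum coding length of 99 bp
therefore corresponds exactly to proteins of >= 33 aa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# Genomic-context labels for an ORF relative to the annotation.
CONTEXT_ANNOTATED = "annotated"
CONTEXT_ENTITY_OVERLAPPING = "entity_overlapping"
CONTEXT_INTERGENIC = "intergenic"
CONTEXTS = (CONTEXT_ANNOTATED, CONTEXT_ENTITY_OVERLAPPING, CONTEXT_INTERGENIC)

# Classification labels for intergenic query ORFs.
LABEL_MISSING = "missing_gene"
LABEL_ABSENT = "absent_annotation"
LABEL_ARTIFACT = "genomic_artifact"
LABEL_POTENTIAL = "potentially_missing"
LABEL_UNCLASSIFIED = "unclassified"
FINAL_LABELS = (LABEL_MISSING, LABEL_ABSENT, LABEL_ARTIFACT, LABEL_UNCLASSIFIED)

FEATURE_KINDS = ("gene", "rna", "pseudogene", "other")


@dataclass(slots=True)
class Replicon:
    """One independently replicating unit: a chromosome or a plasmid."""

    replicon_id: str
    sequence: str
    topology: str = "linear"  # "linear" or "circular"
    genome_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.replicon_id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"replicon {self.replicon_id!r}: bad topology {self.topology!r}")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class TaxonomyRecord:
    """Taxonomic placement of a replicon; family is the unit of the phylogenetic filter."""

    replicon_id: str
    order: str
    family: str
    genus: str

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError(f"replicon {self.replicon_id!r}: empty family")


@dataclass(slots=True)
class Feature:
    """An annotated entity (gene, RNA, pseudogene, ...) on a replicon."""

    replicon_id: str
    kind: str  # gene | rna | pseudogene | other
    start: int  # 0-based half-open
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"bad feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature on {self.replicon_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(slots=True)
class Orf:
    """A maximal open reading frame.

    ``start``/``end`` delimit the coding interval on forward-strand
    coordinates, excluding the stop codon.  On circular replicons an ORF
    spanning the origin has ``end > len(replicon)``; positions are taken
    modulo the replicon length.
    """

    orf_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str
    context: str | None = None
    rescued: bool = False

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"ORF {self.orf_id}: length not a multiple of 3")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.orf_id}: bad strand {self.strand!r}")

    @property
    def aa_len(self) -> int:
        return (self.end - self.start) // 3

    def stop_interval(self) -> tuple[int, int]:
        """Forward-strand interval of the stop codon (may exceed replicon length on wrap)."""
        if self.strand == "+":
            return self.end, self.end + 3
        return self.start - 3, self.start


def orf_id_for(replicon_id: str, strand: str, start: int, end: int) -> str:
    """Deterministic ORF identifier: ``replicon|strand|start-end`` (internal coordinates)."""
    return f"{replicon_id}|{strand}|{start}-{end}"


@dataclass(slots=True)
class AlignmentHit:
    """One pairwise protein alignment after derivation of I and coverages.

    ``I`` is the average percent identity: the mean of the percent identity
    computed with respect to the query length and with respect to the
    subject length.  Coverages are aligned-span fractions of each sequence.
    """

    query_id: str
    subject_id: str
    e_value: float
    n_identities: int
    q_span: int
    s_span: int
    q_len: int
    s_len: int
    I: float = field(init=False)
    cov_q: float = field(init=False)
    cov_s: float = field(init=False)
    avg_cov: float = field(init=False)

    def __post_init__(self) -> None:
        if self.q_len <= 0 or self.s_len <= 0:
            raise ValueError("alignment hit with non-positive sequence length")
        self.I = (
            100.0 * self.n_identities / self.q_len + 100.0 * self.n_identities / self.s_len
        ) / 2.0
        self.cov_q = 100.0 * self.q_span / self.q_len
        self.cov_s = 100.0 * self.s_span / self.s_len
        self.avg_cov = (self.cov_q + self.cov_s) / 2.0


@dataclass(slots=True)
class Classification:
    """Stage-1/Stage-2 outcome for one intergenic query ORF."""

    orf_id: str
    label: str
    alpha: float | None = None
    supporting_hits: list[AlignmentHit] = field(default_factory=list)
    conflicting_hits: list[AlignmentHit] = field(default_factory=list)
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.alpha is not None and self.label not in (LABEL_MISSING, LABEL_ABSENT):
            raise ValueError(f"{self.orf_id}: alpha defined for label {self.label!r}")


@dataclass(slots=True)
class MissingGeneGroup:
    """A promoted single-linkage cluster of missing genes."""

    group_id: str
    member_orf_ids: list[str]
    families: set[str]
    avg_alpha: float = float("nan")
    avg_length_aa: float = float("nan")
    avg_identity: float = float("nan")
    avg_mumi: float | None = None
    ultra_conserved: bool | None = None

    def __post_init__(self) -> None:
        if len(self.member_orf_ids) < 2:
            raise ValueError(f"group {self.group_id}: needs >= 2 members")
        if len(self.families) < 2:
            raise ValueError(f"group {self.group_id}: needs >= 2 families")
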