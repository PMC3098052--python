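"""Readers and writers for sequences, annotations, taxonomy and alignment reports.

GFF3 uses 1-based inclusive coordinates; everything internal is 0-based
half-open on the forward strand (see :mod:`intergene.model`).  The tabular
alignment dialect accepted here is the common 12-column tab-separated
format (query, subject, pident, length, mismatch, gapopen, qstart, qend,
sstart, send, evalue, bitscore), as emitted by ``blastp -outfmt 6`` or
``diamond``.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import AlignmentHit, Feature, Orf, Replicon, TaxonomyRecord

# GFF3/GenBank feature-type -> internal kind
_KIND_MAP = {
    "cds": "gene",
    "gene": "gene",
    "trna": "rna",
    "rrna": "rna",
    "ncrna": "rna",
    "tmrna": "rna",
    "rna": "rna",
    "misc_rna": "rna",
    "pseudogene": "pseudogene",
}


def _map_kind(feature_type: str) -> str:
    return _KIND_MAP.get(feature_type.lower(), "other")


def read_replicons(path: str | os.PathLike, format: str = "fasta") -> list[Replicon]:
    """Read replicon sequences from a FASTA or GenBank file.

    Topology is taken from record metadata when present (GenBank), else
    linear.  Duplicate replicon ids are an error.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported sequence format {format!r}")
    replicons: list[Replicon] = []
    seen: set[str] = set()
    for record in SeqIO.parse(os.fspath(path), format):
        if record.id in seen:
            raise ValueError(f"duplicate replicon id {record.id!r} in {path}")
        seen.add(record.id)
        topology = record.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        # A ``[topology=circular]`` tag in a FASTA description is honoured.
        if format == "fasta" and "[topology=circular]" in (record.description or ""):
            topology = "circular"
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"replicon {record.id!r} in {path} has an empty sequence")
        replicons.append(Replicon(record.id, seq, topology=topology, genome_id=record.id))
    return replicons


def read_features(
    path: str | os.PathLike,
    format: str = "gff3",
    replicon_lengths: Mapping[str, int] | None = None,
) -> list[Feature]:
    """Read annotated features from GFF3 or a GenBank feature table.

    GFF3 1-based inclusive intervals are converted to 0-based half-open.
    When ``replicon_lengths`` is given, features referencing unknown
    replicons or exceeding the replicon length are an error.
    """
    features: list[Feature] = []
    if format == "gff3":
        db = gffutils.create_db(
            os.fspath(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
        for f in db.all_features():
            start = f.start - 1  # 1-based inclusive -> 0-based half-open
            end = f.end
            if start >= end:
                raise ValueError(f"feature on {f.seqid}: start > end after conversion")
            features.append(
                Feature(
                    replicon_id=f.seqid,
                    kind=_map_kind(f.featuretype),
                    start=start,
                    end=end,
                    strand=f.strand if f.strand in ("+", "-") else "+",
                )
            )
    elif format == "genbank":
        for record in SeqIO.parse(os.fspath(path), "genbank"):
            for f in record.features:
                if f.type.lower() == "source":
                    continue
                features.append(
                    Feature(
                        replicon_id=record.id,
                        kind=_map_kind(f.type),
                        start=int(f.location.start),
                        end=int(f.location.end),
                        strand="-" if f.location.strand == -1 else "+",
                    )
                )
    else:
        raise ValueError(f"unsupported annotation format {format!r}")

    if replicon_lengths is not None:
        for f in features:
            if f.replicon_id not in replicon_lengths:
                raise ValueError(f"feature references unknown replicon {f.replicon_id!r}")
            if f.end > replicon_lengths[f.replicon_id]:
                raise ValueError(
                    f"feature [{f.start}, {f.end}) exceeds length of replicon {f.replicon_id!r}"
                )
    return features


def write_features_gff3(features: Iterable[Feature], path: str | os.PathLike) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    type_for = {"gene": "CDS", "rna": "ncRNA", "pseudogene": "pseudogene", "other": "region"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            fh.write(
                "\t".join(
                    [
                        f.replicon_id,
                        "intergene",
                        type_for[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        "0" if f.kind == "gene" else ".",
                        f"ID=feat{i:05d}",
                    ]
                )
                + "\n"
            )


def read_taxonomy(path: str | os.PathLike) -> dict[str, TaxonomyRecord]:
    """Read the replicon taxonomy TSV (columns replicon_id, order, family, genus)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"replicon_id", "order", "family", "genus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy file missing columns: {sorted(missing)}")
    records: dict[str, TaxonomyRecord] = {}
    for row in df.itertuples(index=False):
        if row.replicon_id in records:
            raise ValueError(f"duplicate taxonomy entry for {row.replicon_id!r}")
        records[row.replicon_id] = TaxonomyRecord(
            row.replicon_id, row.order, row.family, row.genus
        )
    return records


_TAB6_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_alignment_report(
    path: str | os.PathLike,
    q_lens: Mapping[str, int],
    s_lens: Mapping[str, int],
) -> list[AlignmentHit]:
    """Ingest a 12-column tabular all-vs-all protein alignment report.

    The identity count is recovered as ``round(pident * length / 100)`` and
    aligned spans as ``qend - qstart + 1`` / ``send - sstart + 1``; the
    average percent identity I and the coverages follow from those.
    """
    df = pd.read_csv(path, sep="\t", names=_TAB6_COLUMNS, comment="#", dtype=str)
    hits: list[AlignmentHit] = []
    for row in df.itertuples(index=False):
        try:
            pident = float(row.pident)
            length = int(row.length)
            qstart, qend = int(row.qstart), int(row.qend)
            sstart, send = int(row.sstart), int(row.send)
            evalue = float(row.evalue)
        except ValueError as exc:
            raise ValueError(f"non-numeric field in alignment row {row!r}") from exc
        if row.query not in q_lens:
            raise ValueError(f"unknown query id {row.query!r} in alignment report")
        if row.subject not in s_lens:
            raise ValueError(f"unknown subject id {row.subject!r} in alignment report")
        hits.append(
            AlignmentHit(
                query_id=row.query,
                subject_id=row.subject,
                e_value=evalue,
                n_identities=round(pident * length / 100.0),
                q_span=qend - qstart + 1,
                s_span=abs(send - sstart) + 1,
                q_len=q_lens[row.query],
                s_len=s_lens[row.subject],
            )
        )
    return hits


def write_fasta_aa(orfs: Iterable[Orf], path: str | os.PathLike) -> None:
    """Write ORF protein sequences as FASTA."""
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id}\n{orf.aa_seq}\n")


def write_fasta_nt(orfs: Iterable[Orf], path: str | os.PathLike) -> None:
    """Write ORF nucleotide (coding) sequences as FASTA."""
    with open(path, "w") as fh:
        for orf in orfs:
            fh.write(f">{orf.orf_id}\n{orf.nt_seq}\n")
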