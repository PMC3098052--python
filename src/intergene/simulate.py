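"""Seeded synthetic pan-genome generator with exact ground truth.

The generator emulates a small set of prokaryotic replicons spread over
several taxonomic families, carrying annotated genes, planted conserved
intergenic ORFs ("missing genes", copied across families), planted absent
annotations (unannotated copies of a gene annotated elsewhere), shadow
ORFs overlapping annotated entities, and neutral spacer DNA.

Ground truth is exact by construction rather than by post-hoc screening of
random sequence: every planted element is assembled into a *block*
bracketed by a stop cassette — a 12-nt sequence containing stop codons in
all six reading frames, free of G (hence of start codons), and equal to
its own reverse complement.  Cassettes also punctuate all spacer DNA at
most 48 nt apart.  No open reading frame can therefore extend more than a
few codons across any block or spacer boundary, and no spurious ORF of
>= 99 bp can arise outside the planted blocks.  Blocks that must contain
exactly one ORF (missing-gene plants and annotated genes) are additionally
rejection-sampled until their alternative frames and opposite strand are
ORF-free.

This emulates the *logic* of real pan-genomes (conservation across
families, annotation gaps, shadow ORFs) but none of their compositional
realism: no indels or rearrangements, uniform codon usage, and abstract
family labels.
"""

from __future__ import annotations

import itertools
import os
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import write_features_gff3
from .model import (
    CONTEXT_ANNOTATED,
    CONTEXT_ENTITY_OVERLAPPING,
    LABEL_ABSENT,
    LABEL_MISSING,
    LABEL_UNCLASSIFIED,
    Feature,
    Replicon,
    TaxonomyRecord,
)
from .orfs import STOP_CODONS, find_maximal_orfs

# Stops in all six frames, no G (so no start codons), self-reverse-complementary.
STOP_CASSETTE = "TTAATTAATTAA"

_SENSE_CODONS = sorted(
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)


@dataclass(slots=True)
class SimulationConfig:
    """Study conditions for the synthetic pan-genome.

    Defaults describe a small four-family, eight-replicon community with
    ten planted missing-gene families (each copied into two replicons of
    different families), five absent annotations and ten shadow ORFs.
    """

    n_families: int = 4
    replicons_per_family: int = 2
    replicon_len: int = 12000
    n_annotated_genes: int = 5  # per replicon
    n_planted_missing_families: int = 10
    n_planted_absent: int = 5
    n_shadow_orfs: int = 10
    n_planted_samefam_families: int = 0  # conserved plants confined to one family
    mutation_rate: float = 0.0  # per-site, per planted missing-gene copy
    gc_bias: float = 0.5  # spacer G+C fraction
    seed: int = 0
    max_block_retries: int = 500


@dataclass(slots=True)
class SyntheticDataset:
    replicons: list[Replicon]
    features: list[Feature]
    taxonomy: dict[str, TaxonomyRecord]
    truth: pd.DataFrame  # element_id, replicon_id, start, end, strand, intended_label, family_set


@dataclass(slots=True)
class _Block:
    """One planted element: oriented sequence plus the ORF inside it."""

    seq: str  # block sequence in gene orientation (starts/ends with cassette)
    orf_start: int  # coding interval within seq, stop codon excluded
    orf_end: int
    element_id: str
    intended_label: str
    family_set: tuple[str, ...]
    strand: str = "+"
    decoy_feature: bool = False  # shadow blocks carry an overlapping annotation
    annotate: bool = False  # annotated genes get a CDS feature


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA (stop included)."""
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _random_chunk(rng: np.random.Generator, length: int, gc_bias: float) -> str:
    p_gc = gc_bias / 2.0
    p_at = (1.0 - gc_bias) / 2.0
    return "".join(rng.choice(["A", "C", "G", "T"], size=length, p=[p_at, p_gc, p_gc, p_at]))


def _acgt_flank(rng: np.random.Generator, length: int) -> str:
    """Flank over {A, C, T}: no G means no start codons in any frame."""
    return "".join(rng.choice(["A", "C", "T"], size=length))


def _orf_free_except(block: str, start: int, end: int, min_len: int = 99) -> bool:
    """True iff the only maximal ORF >= min_len in ``block`` is [start, end) on '+'."""
    probe = Replicon("probe", block)
    found = {(o.start, o.end, o.strand) for o in find_maximal_orfs(probe, min_len)}
    return found == {(start, end, "+")}


def _single_orf_block(
    rng: np.random.Generator,
    n_codons: int,
    element_id: str,
    label: str,
    family_set: tuple[str, ...],
    max_retries: int,
    flank: str | None = None,
    require_clean: bool = True,
    annotate: bool = False,
) -> _Block:
    """Build a cassette-bracketed block containing exactly one ORF.

    ``flank`` (shared across copies of a planted family) surrounds the ORF
    inside the cassettes; when None, bare cassettes abut the ORF.
    """
    up = down = flank if flank is not None else ""
    for _ in range(max_retries):
        orf = _random_orf(rng, n_codons)
        seq = STOP_CASSETTE + up + orf + down + STOP_CASSETTE
        start = len(STOP_CASSETTE) + len(up)
        end = start + len(orf) - 3
        if not require_clean or _orf_free_except(seq, start, end):
            return _Block(seq, start, end, element_id, label, family_set, annotate=annotate)
    raise RuntimeError(
        f"could not draw an ORF-clean block for {element_id} after {max_retries} tries"
    )


def _mutate_copy(rng: np.random.Generator, orf_block: _Block, rate: float) -> _Block:
    """Point-mutate the coding interior of a planted copy.

    The start codon, the stop codon, and any change that would create an
    in-frame stop are left untouched, so the planted ORF's coordinates are
    preserved exactly.
    """
    if rate <= 0:
        return orf_block
    seq = list(orf_block.seq)
    s, e = orf_block.orf_start, orf_block.orf_end
    bases = "ACGT"
    for pos in range(s + 3, e):  # interior codons only
        if rng.random() >= rate:
            continue
        old = seq[pos]
        new = rng.choice([b for b in bases if b != old])
        codon_start = s + ((pos - s) // 3) * 3
        trial = seq[codon_start:pos] + [new] + seq[pos + 1 : codon_start + 3]
        if "".join(trial) in STOP_CODONS:
            continue
        seq[pos] = new
    return _Block(
        "".join(seq),
        orf_block.orf_start,
        orf_block.orf_end,
        orf_block.element_id,
        orf_block.intended_label,
        orf_block.family_set,
    )


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate(config: SimulationConfig) -> SyntheticDataset:
    """Generate one synthetic pan-genome; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    families = [f"FAM{i + 1:02d}" for i in range(cfg.n_families)]
    replicon_ids: list[str] = []
    taxonomy: dict[str, TaxonomyRecord] = {}
    for fi, fam in enumerate(families):
        for ri in range(cfg.replicons_per_family):
            rid = f"{fam}_R{ri + 1}"
            replicon_ids.append(rid)
            taxonomy[rid] = TaxonomyRecord(
                rid,
                order=f"ORD{fi // 2 + 1:02d}",
                family=fam,
                genus=f"GEN{fi + 1:02d}",
            )
    family_of = {rid: taxonomy[rid].family for rid in replicon_ids}
    by_family: dict[str, list[str]] = {}
    for rid in replicon_ids:
        by_family.setdefault(family_of[rid], []).append(rid)

    blocks: dict[str, list[_Block]] = {rid: [] for rid in replicon_ids}

    # --- annotated genes -------------------------------------------------
    for rid in replicon_ids:
        for gi in range(cfg.n_annotated_genes):
            n_codons = int(rng.integers(40, 81))
            block = _single_orf_block(
                rng,
                n_codons,
                element_id=f"GENE_{rid}_{gi + 1}",
                label=CONTEXT_ANNOTATED,
                family_set=(family_of[rid],),
                max_retries=cfg.max_block_retries,
                annotate=True,
            )
            block.strand = "+" if rng.random() < 0.5 else "-"
            blocks[rid].append(block)

    # --- planted missing-gene families (cross-family conservation) -------
    def plant_conserved(n_plants: int, same_family: bool, tag: str, label: str) -> None:
        for pi in range(n_plants):
            if same_family:
                fam = families[pi % len(families)]
                host_replicons = by_family[fam][:2]
                if len(host_replicons) < 2:
                    raise ValueError("same-family plants need >= 2 replicons per family")
            else:
                fa = families[pi % len(families)]
                fb = families[(pi + 1) % len(families)]
                host_replicons = [
                    by_family[fa][pi % len(by_family[fa])],
                    by_family[fb][pi % len(by_family[fb])],
                ]
            fam_set = tuple(sorted({family_of[r] for r in host_replicons}))
            n_codons = int(rng.integers(35, 61))
            flank = _acgt_flank(rng, 30)
            master = _single_orf_block(
                rng,
                n_codons,
                element_id=f"{tag}{pi + 1:02d}",
                label=label,
                family_set=fam_set,
                max_retries=cfg.max_block_retries,
                flank=flank,
            )
            strand = "+" if rng.random() < 0.5 else "-"
            for ci, rid in enumerate(host_replicons):
                copy = _mutate_copy(rng, master, cfg.mutation_rate)
                copy = _Block(
                    copy.seq,
                    copy.orf_start,
                    copy.orf_end,
                    f"{master.element_id}_C{ci + 1}",
                    label,
                    fam_set,
                    strand=strand,
                )
                blocks[rid].append(copy)

    plant_conserved(cfg.n_planted_missing_families, False, "MISS", LABEL_MISSING)
    plant_conserved(cfg.n_planted_samefam_families, True, "SAMEFAM", LABEL_UNCLASSIFIED)

    # --- absent annotations: unannotated copies of an annotated gene -----
    for ai in range(cfg.n_planted_absent):
        src_rid = replicon_ids[ai % len(replicon_ids)]
        host_choices = [r for r in replicon_ids if family_of[r] != family_of[src_rid]]
        host_rid = host_choices[ai % len(host_choices)]
        source_gene = blocks[src_rid][ai % cfg.n_annotated_genes]  # an annotated gene block
        copy = _Block(
            source_gene.seq,
            source_gene.orf_start,
            source_gene.orf_end,
            f"ABSENT{ai + 1:02d}",
            LABEL_ABSENT,
            tuple(sorted({family_of[src_rid], family_of[host_rid]})),
            strand="+" if rng.random() < 0.5 else "-",
        )
        blocks[host_rid].append(copy)

    # --- shadow ORFs: planted ORFs overlapped by a decoy annotation ------
    for si in range(cfg.n_shadow_orfs):
        rid = replicon_ids[si % len(replicon_ids)]
        n_codons = int(rng.integers(35, 61))
        block = _single_orf_block(
            rng,
            n_codons,
            element_id=f"SHADOW{si + 1:02d}",
            label=CONTEXT_ENTITY_OVERLAPPING,
            family_set=(family_of[rid],),
            max_retries=cfg.max_block_retries,
            require_clean=False,
        )
        block.decoy_feature = True
        blocks[rid].append(block)

    # --- assemble replicons ----------------------------------------------
    def spacer(min_len: int = 0) -> str:
        parts = [STOP_CASSETTE]
        while sum(map(len, parts)) < max(min_len, 40):
            parts.append(_random_chunk(rng, int(rng.integers(20, 49)), cfg.gc_bias))
            parts.append(STOP_CASSETTE)
        return "".join(parts)

    replicons: list[Replicon] = []
    features: list[Feature] = []
    truth_rows: list[dict] = []
    for rid in replicon_ids:
        order = rng.permutation(len(blocks[rid]))
        parts: list[str] = [spacer()]
        pos = len(parts[0])
        for bi in order:
            block = blocks[rid][bi]
            oriented = block.seq if block.strand == "+" else _revcomp(block.seq)
            if block.strand == "+":
                orf_start = pos + block.orf_start
                orf_end = pos + block.orf_end
            else:
                orf_start = pos + len(block.seq) - block.orf_end
                orf_end = pos + len(block.seq) - block.orf_start
            if block.annotate:
                # CDS annotated with its stop codon, as in standard practice.
                if block.strand == "+":
                    features.append(Feature(rid, "gene", orf_start, orf_end + 3, "+"))
                else:
                    features.append(Feature(rid, "gene", orf_start - 3, orf_end, "-"))
            if block.decoy_feature:
                # Overlap the last 2 bp of the shadow ORF's stop codon.
                if block.strand == "+":
                    features.append(Feature(rid, "rna", orf_end + 1, orf_end + 41, "+"))
                else:
                    features.append(Feature(rid, "rna", max(0, orf_start - 41), orf_start - 1, "-"))
            truth_rows.append(
                {
                    "element_id": block.element_id,
                    "replicon_id": rid,
                    "start": orf_start,
                    "end": orf_end,
                    "strand": block.strand,
                    "intended_label": block.intended_label,
                    "family_set": ";".join(block.family_set),
                }
            )
            parts.append(oriented)
            pos += len(oriented)
            gap = spacer()
            parts.append(gap)
            pos += len(gap)
        if pos > cfg.replicon_len:
            raise ValueError(
                f"replicon_len={cfg.replicon_len} too small: {rid} needs {pos} bp"
            )
        pad = spacer(cfg.replicon_len - pos)[: cfg.replicon_len - pos]
        parts.append(pad)
        replicons.append(Replicon(rid, "".join(parts), topology="linear", genome_id=rid))

    truth = pd.DataFrame(truth_rows).sort_values(["replicon_id", "start"]).reset_index(drop=True)
    features.sort(key=lambda f: (f.replicon_id, f.start, f.end, f.strand))
    return SyntheticDataset(replicons, features, taxonomy, truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | os.PathLike) -> dict[str, str]:
    """Write FASTA + GFF3 + taxonomy TSV + truth TSV; returns the file paths.

    Truth coordinates are emitted 1-based inclusive, like all other output.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "replicons.fasta"),
        "gff3": os.path.join(outdir, "features.gff3"),
        "taxonomy": os.path.join(outdir, "taxonomy.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        for rep in dataset.replicons:
            fh.write(f">{rep.replicon_id}\n")
            for i in range(0, len(rep.sequence), 80):
                fh.write(rep.sequence[i : i + 80] + "\n")
    write_features_gff3(dataset.features, paths["gff3"])
    with open(paths["taxonomy"], "w") as fh:
        fh.write("replicon_id\torder\tfamily\tgenus\n")
        for rid in sorted(dataset.taxonomy):
            t = dataset.taxonomy[rid]
            fh.write(f"{t.replicon_id}\t{t.order}\t{t.family}\t{t.genus}\n")
    out = dataset.truth.copy()
    out["start"] = out["start"] + 1  # 1-based inclusive on disk
    out.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def score_against_truth(
    truth: pd.DataFrame,
    orf_contexts: Mapping[tuple[str, int, int, str], str],
    final_labels: Mapping[tuple[str, int, int, str], str],
) -> dict[str, dict[str, float]]:
    """Per-label recall and precision of the pipeline against planted intent.

    Keys of the two mappings are ``(replicon_id, start, end, strand)`` in
    internal coordinates.  Context-type intents (annotated,
    entity_overlapping) are scored against contexts; query labels
    (missing_gene, absent_annotation, unclassified) against final labels.
    """
    context_intents = {CONTEXT_ANNOTATED, CONTEXT_ENTITY_OVERLAPPING}
    scores: dict[str, dict[str, float]] = {}
    for label, sub in truth.groupby("intended_label"):
        lookup = orf_contexts if label in context_intents else final_labels
        hits = 0
        for row in sub.itertuples(index=False):
            key = (row.replicon_id, int(row.start), int(row.end), row.strand)
            if lookup.get(key) == label:
                hits += 1
        n_called = sum(1 for v in lookup.values() if v == label)
        truth_keys = {
            (r.replicon_id, int(r.start), int(r.end), r.strand)
            for r in sub.itertuples(index=False)
        }
        true_calls = sum(
            1 for k, v in lookup.items() if v == label and k in truth_keys
        )
        scores[label] = {
            "recall": hits / len(sub) if len(sub) else float("nan"),
            "precision": true_calls / n_called if n_called else float("nan"),
            "n_truth": float(len(sub)),
            "n_called": float(n_called),
        }
    return scores
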