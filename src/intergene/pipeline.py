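"""End-to-end orchestration: scan -> context -> align -> classify -> cluster -> score.

The query set is the intergenic ORFs; the subject database is all ORFs of
all three context groups.  Alignments come either from the built-in local
aligner or from an ingested tabular report of an external search tool.
"""

from __future__ import annotations

import json
import os
from collections import defaultdict
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from . import align as _align
from . import metrics as _metrics
from .context import classify_orfs
from .io import (
    read_alignment_report,
    write_fasta_aa,
    write_fasta_nt,
)
from .model import (
    CONTEXT_ANNOTATED,
    CONTEXT_ENTITY_OVERLAPPING,
    CONTEXT_INTERGENIC,
    LABEL_ABSENT,
    LABEL_ARTIFACT,
    LABEL_MISSING,
    LABEL_POTENTIAL,
    LABEL_UNCLASSIFIED,
    AlignmentHit,
    Classification,
    Feature,
    MissingGeneGroup,
    Orf,
    Replicon,
    TaxonomyRecord,
)
from .orfs import DEFAULT_MIN_LEN, find_maximal_orfs
from .scoring import alpha_score, group_alpha
from .stage1 import DEFAULT_DIFF_THRESHOLD, classify_queries
from .stage2 import build_clusters, finalize_missing


@dataclass(slots=True)
class PipelineConfig:
    """All tunable thresholds of the discovery pipeline."""

    min_len: int = DEFAULT_MIN_LEN  # bp of coding sequence
    max_evalue: float = 1e-5
    min_cov: float = 80.0  # percent, required of query AND subject
    max_hits_per_query: int = 1000
    diff_threshold: float = DEFAULT_DIFF_THRESHOLD  # percentage points of avg coverage
    flank: int = 30  # bp for the ultra-conservation check
    min_mum_len: int = 19  # bp for MUMi
    compute_group_metrics: bool = True


@dataclass(slots=True)
class PipelineResult:
    replicons: dict[str, Replicon]
    features: list[Feature]
    taxonomy: dict[str, TaxonomyRecord]
    orfs: list[Orf]  # all ORFs, contexts assigned
    queries: list[Orf]  # the intergenic subset
    hits: list[AlignmentHit]  # filtered hits
    classifications: dict[str, Classification]  # per query, final labels
    groups: list[MissingGeneGroup]
    demotions: dict[str, str]  # demoted orf_id -> near-miss reason
    summary: dict = field(default_factory=dict)


def run_pipeline(
    replicons: Sequence[Replicon],
    features: Sequence[Feature],
    taxonomy: Mapping[str, TaxonomyRecord],
    config: PipelineConfig | None = None,
    alignment_report: str | os.PathLike | None = None,
) -> PipelineResult:
    """Run the full missing-gene discovery pipeline.

    With ``alignment_report`` set, hits are ingested from that 12-column
    tabular file instead of running the built-in aligner (its e-values are
    trusted as-is).  Every replicon must have a taxonomy record: the
    family filter is mandatory.
    """
    cfg = config or PipelineConfig()
    for rep in replicons:
        if rep.replicon_id not in taxonomy:
            raise ValueError(f"no taxonomy record for replicon {rep.replicon_id!r}")
    rep_by_id = {r.replicon_id: r for r in replicons}
    feats_by_rep: dict[str, list[Feature]] = defaultdict(list)
    for f in features:
        if f.replicon_id not in rep_by_id:
            raise ValueError(f"feature references unknown replicon {f.replicon_id!r}")
        feats_by_rep[f.replicon_id].append(f)

    # 1-2. ORF scan and genomic-context partition (with start rescue).
    all_orfs: list[Orf] = []
    for rep in replicons:
        orfs = find_maximal_orfs(rep, cfg.min_len)
        length = len(rep) if rep.topology == "circular" else None
        all_orfs.extend(
            classify_orfs(orfs, feats_by_rep[rep.replicon_id], length, cfg.min_len)
        )
    queries = [o for o in all_orfs if o.context == CONTEXT_INTERGENIC]

    # 3. All-vs-all alignment and screening.
    if alignment_report is not None:
        lens = {o.orf_id: o.aa_len for o in all_orfs}
        raw_hits = read_alignment_report(alignment_report, lens, lens)
    else:
        raw_hits = _align.align_all(queries, all_orfs)
    hits = _align.filter_hits(
        raw_hits, cfg.max_evalue, cfg.min_cov, cfg.max_hits_per_query
    )
    hits_by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        hits_by_query[h.query_id].append(h)

    # 4. Stage-1 labels.
    contexts = {o.orf_id: o.context for o in all_orfs}
    families = {rid: taxonomy[rid].family for rid in taxonomy}
    classifications = classify_queries(
        queries, hits_by_query, contexts, families, cfg.diff_threshold
    )

    # 5. Stage-2 single-linkage clustering of the potentially-missing set.
    orf_by_id = {o.orf_id: o for o in all_orfs}
    candidates = {
        oid for oid, c in classifications.items() if c.label == LABEL_POTENTIAL
    }
    edges = [
        (oid, h.subject_id)
        for oid in sorted(candidates)
        for h in classifications[oid].supporting_hits
        if h.subject_id in candidates
    ]
    clusters = build_clusters(candidates, edges)
    families_by_orf = {
        oid: families[orf_by_id[oid].replicon_id] for oid in candidates
    }
    groups, demoted = finalize_missing(clusters, families_by_orf)

    demotions: dict[str, str] = {}
    for members in clusters:
        fams = {families_by_orf[m] for m in members}
        if len(members) >= 2 and len(fams) >= 2:
            continue
        reason = "singleton_cluster" if len(members) < 2 else "single_family_cluster"
        for m in members:
            demotions[m] = reason

    # 6. Final labels and alpha scores.
    member_to_group = {
        oid: g.group_id for g in groups for oid in g.member_orf_ids
    }
    for oid, c in classifications.items():
        if c.label == LABEL_POTENTIAL:
            if oid in member_to_group:
                c.label = LABEL_MISSING
                c.cluster_id = member_to_group[oid]
                c.alpha = alpha_score(LABEL_MISSING, c.supporting_hits, c.conflicting_hits)
            else:
                c.label = LABEL_UNCLASSIFIED
                c.supporting_hits = []
                c.conflicting_hits = []
        elif c.label == LABEL_ABSENT:
            c.alpha = alpha_score(LABEL_ABSENT, c.supporting_hits, c.conflicting_hits)

    # 7. Group-level statistics.
    for g in groups:
        alphas = [classifications[m].alpha for m in g.member_orf_ids]
        g.avg_alpha = group_alpha(alphas)
        g.avg_length_aa = float(
            np.mean([orf_by_id[m].aa_len for m in g.member_orf_ids])
        )
        g.avg_identity = float(
            np.mean(
                [
                    max(h.I for h in classifications[m].supporting_hits)
                    for m in g.member_orf_ids
                ]
            )
        )
        if cfg.compute_group_metrics:
            member_replicons = {m: orf_by_id[m].replicon_id for m in g.member_orf_ids}
            g.avg_mumi = _metrics.group_mumi(
                g, member_replicons, rep_by_id, taxonomy, cfg.min_mum_len
            )
            g.ultra_conserved = _metrics.ultra_conserved(
                [orf_by_id[m] for m in g.member_orf_ids], rep_by_id, cfg.flank
            )

    # 8. Summary with the partition identities.
    context_counts = {
        ctx: sum(1 for o in all_orfs if o.context == ctx)
        for ctx in (CONTEXT_ANNOTATED, CONTEXT_ENTITY_OVERLAPPING, CONTEXT_INTERGENIC)
    }
    label_counts = {
        label: sum(1 for c in classifications.values() if c.label == label)
        for label in (LABEL_MISSING, LABEL_ABSENT, LABEL_ARTIFACT, LABEL_UNCLASSIFIED)
    }
    summary = {
        "n_replicons": len(replicons),
        "n_orfs": len(all_orfs),
        "contexts": context_counts,
        "n_queries": len(queries),
        "labels": label_counts,
        "n_groups": len(groups),
        "n_filtered_hits": len(hits),
    }
    return PipelineResult(
        replicons=rep_by_id,
        features=list(features),
        taxonomy=dict(taxonomy),
        orfs=all_orfs,
        queries=queries,
        hits=hits,
        classifications=classifications,
        groups=groups,
        demotions=demotions,
        summary=summary,
    )


def _is_plasmid(replicon_id: str) -> bool:
    return "plasmid" in replicon_id.lower() or replicon_id.lower().startswith("p")


def write_report(
    result: PipelineResult,
    outdir: str | os.PathLike,
    representative_seed: int | None = None,
) -> dict[str, str]:
    """Write the report bundle: per-ORF contexts, per-query classifications,
    missing-gene gene/group tables, FASTA of missing-gene proteins and one
    representative nucleotide sequence per group, and a JSON summary.

    Group representatives are the smallest member orf_id unless a seed is
    given, which restores a randomized choice.  Coordinates on disk are
    1-based inclusive.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    orf_by_id = {o.orf_id: o for o in result.orfs}
    paths = {name: os.path.join(outdir, fn) for name, fn in [
        ("orfs", "orf_contexts.tsv"),
        ("classifications", "classifications.tsv"),
        ("genes", "missing_genes.tsv"),
        ("groups", "missing_groups.tsv"),
        ("aa_fasta", "missing_genes_aa.fasta"),
        ("nt_fasta", "missing_groups_representative_nt.fasta"),
        ("summary", "summary.json"),
    ]}

    with open(paths["orfs"], "w") as fh:
        fh.write("orf_id\treplicon_id\tstart\tend\tstrand\tcontext\trescued\n")
        for o in result.orfs:
            fh.write(
                f"{o.orf_id}\t{o.replicon_id}\t{o.start + 1}\t{o.end}\t"
                f"{o.strand}\t{o.context}\t{str(o.rescued).lower()}\n"
            )

    with open(paths["classifications"], "w") as fh:
        fh.write(
            "orf_id\tlabel\talpha\tn_supporting\tn_conflicting\t"
            "top_supporting_subject\tcluster_id\tdemotion_reason\n"
        )
        for oid in sorted(result.classifications):
            c = result.classifications[oid]
            top = (
                _align.top_hit(c.supporting_hits).subject_id
                if c.supporting_hits
                else ""
            )
            alpha = f"{c.alpha:.4f}" if c.alpha is not None else ""
            fh.write(
                f"{oid}\t{c.label}\t{alpha}\t{len(c.supporting_hits)}\t"
                f"{len(c.conflicting_hits)}\t{top}\t{c.cluster_id or ''}\t"
                f"{result.demotions.get(oid, '')}\n"
            )

    with open(paths["genes"], "w") as fh:
        fh.write(
            "replicon_id\tgene_id\tstart\tstop\tlength_aa\talpha\tcluster_id\t"
            "order\tfamily\tgenus\n"
        )
        for g in result.groups:
            for oid in g.member_orf_ids:
                o = orf_by_id[oid]
                t = result.taxonomy[o.replicon_id]
                c = result.classifications[oid]
                fh.write(
                    f"{o.replicon_id}\t{oid}\t{o.start + 1}\t{o.end}\t{o.aa_len}\t"
                    f"{c.alpha:.4f}\t{g.group_id}\t{t.order}\t{t.family}\t{t.genus}\n"
                )

    with open(paths["groups"], "w") as fh:
        fh.write(
            "group_id\tn_members\tfamilies\tavg_alpha\tavg_length_aa\t"
            "avg_identity\tn_replicons\tn_chromosomes\tn_plasmids\t"
            "avg_mumi\tultra_conserved\n"
        )
        for g in result.groups:
            reps = {orf_by_id[m].replicon_id for m in g.member_orf_ids}
            n_plasmid = sum(1 for r in reps if _is_plasmid(r))
            mumi = f"{g.avg_mumi:.4f}" if g.avg_mumi is not None else ""
            ultra = "" if g.ultra_conserved is None else str(g.ultra_conserved).lower()
            fh.write(
                f"{g.group_id}\t{len(g.member_orf_ids)}\t{';'.join(sorted(g.families))}\t"
                f"{g.avg_alpha:.4f}\t{g.avg_length_aa:.2f}\t{g.avg_identity:.4f}\t"
                f"{len(reps)}\t{len(reps) - n_plasmid}\t{n_plasmid}\t{mumi}\t{ultra}\n"
            )

    missing_orfs = [
        orf_by_id[oid]
        for oid in sorted(result.classifications)
        if result.classifications[oid].label == LABEL_MISSING
    ]
    write_fasta_aa(missing_orfs, paths["aa_fasta"])
    rng = np.random.default_rng(representative_seed) if representative_seed is not None else None
    representatives = []
    for g in result.groups:
        members = sorted(g.member_orf_ids)
        pick = members[int(rng.integers(len(members)))] if rng is not None else members[0]
        representatives.append(orf_by_id[pick])
    write_fasta_nt(representatives, paths["nt_fasta"])

    with open(paths["summary"], "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
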