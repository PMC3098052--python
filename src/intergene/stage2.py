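"""Stage-2 single-linkage clustering of potentially missing ORFs.

Two candidates are connected if a qualifying alignment (a cross-family
intergenic hit whose both endpoints are themselves potentially missing)
links them; connectivity is transitive.  Clusters with at least two ORFs
spanning at least two taxonomic families are promoted to missing-gene
groups; the members of all other clusters are demoted to unclassified.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import networkx as nx

from .model import MissingGeneGroup


def build_clusters(
    candidates: Iterable[str],
    qualifying_edges: Iterable[tuple[str, str]],
) -> list[list[str]]:
    """Connected components over (candidates, edges); singletons included.

    Clusters are ordered (and their members sorted) by smallest member id,
    so the output is invariant to edge order.
    """
    graph = nx.Graph()
    candidate_set = set(candidates)
    graph.add_nodes_from(candidate_set)
    for a, b in qualifying_edges:
        if a not in candidate_set or b not in candidate_set:
            raise ValueError(f"edge endpoint not a candidate: ({a!r}, {b!r})")
        graph.add_edge(a, b)
    clusters = [sorted(component) for component in nx.connected_components(graph)]
    clusters.sort(key=lambda members: members[0])
    return clusters


def finalize_missing(
    clusters: Sequence[Sequence[str]],
    families_by_orf: Mapping[str, str],
) -> tuple[list[MissingGeneGroup], list[str]]:
    """Promote family-diverse clusters to missing-gene groups.

    Returns the groups (group ids MG00001... in cluster order) and the flat
    list of demoted ORF ids (members of clusters with < 2 members or < 2
    families).
    """
    groups: list[MissingGeneGroup] = []
    demoted: list[str] = []
    n = 0
    for members in clusters:
        fams = {families_by_orf[m] for m in members}
        if len(members) >= 2 and len(fams) >= 2:
            n += 1
            groups.append(
                MissingGeneGroup(
                    group_id=f"MG{n:05d}",
                    member_orf_ids=sorted(members),
                    families=fams,
                )
            )
        else:
            demoted.extend(members)
    return groups, sorted(demoted)
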