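"""Co-annotation graph construction and transport-cluster extraction.

Protein families are nodes; every unordered pair of candidate families that
co-occur on the same reviewed cross-reference entry (emulating reviewed
UniProt records) or in the same operon defines an edge, with the supporting
record ids kept as provenance. Generic families (e.g. the ubiquitous ABC
ATP-binding domain) accumulate many co-annotation partners and would glue
unrelated transporters together, so nodes whose distinct-neighbour degree
exceeds a cutoff (default 6) are removed in a single pass on the input
degrees. Transport clusters are the connected components of the pruned
graph, plus a singleton cluster for every remaining candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx
import pandas as pd


@dataclass(frozen=True)
class XrefEntry:
    """One cross-reference record: a protein entry annotated with families."""

    entry_id: str
    family_accessions: frozenset[str]
    reviewed: bool = True

    def __post_init__(self) -> None:
        if not self.family_accessions:
            raise ValueError(f"xref {self.entry_id}: empty accession set")
        object.__setattr__(self, "family_accessions", frozenset(self.family_accessions))


@dataclass(frozen=True)
class OperonEntry:
    """One operon: families encoded in the same operon."""

    operon_id: str
    family_accessions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.family_accessions:
            raise ValueError(f"operon {self.operon_id}: empty accession set")
        object.__setattr__(self, "family_accessions", frozenset(self.family_accessions))


def build_coannotation_graph(
    candidates: set[str],
    xrefs: Iterable[XrefEntry] = (),
    operons: Iterable[OperonEntry] = (),
    known_families: set[str] | None = None,
) -> nx.Graph:
    """Build the family co-annotation graph over the candidate set.

    Only reviewed cross-reference entries contribute edges; operons always
    do. Families on a record that are not candidates are ignored; families
    absent from ``known_families`` (when given) are skipped with a warning.
    Each edge carries a ``provenance`` list of supporting record ids.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    graph = nx.Graph()
    graph.add_nodes_from(candidates)

    def add_record(record_id: str, accessions: frozenset[str]) -> None:
        if known_families is not None:
            unknown = accessions - known_families
            if unknown:
                warnings.warn(
                    f"record {record_id}: unknown accessions skipped: {sorted(unknown)}"
                )
                accessions = accessions & known_families
        members = sorted(accessions & candidates)
        for a, b in combinations(members, 2):
            if graph.has_edge(a, b):
                graph.edges[a, b]["provenance"].append(record_id)
            else:
                graph.add_edge(a, b, provenance=[record_id])

    for x in xrefs:
        if x.reviewed:
            add_record(x.entry_id, x.family_accessions)
    for op in operons:
        add_record(op.operon_id, op.family_accessions)
    return graph


def prune_hubs(graph: nx.Graph, max_degree: int = 6) -> tuple[nx.Graph, set[str]]:
    """Remove hub nodes whose input-graph degree exceeds ``max_degree``.

    A single pass on the input degrees: all nodes over the cutoff are
    removed together with their incident edges, with no cascading
    re-evaluation (removing one hub never rescues another). Nodes at exactly
    ``max_degree`` survive.
    """
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    removed = {n for n, d in graph.degree() if d > max_degree}
    pruned = graph.copy()
    pruned.remove_nodes_from(removed)
    return pruned, removed


def cluster_families(graph: nx.Graph, candidates: set[str]) -> pd.DataFrame:
    """Emit transport clusters as connected components plus singletons.

    Every candidate present in the (pruned) graph lands in exactly one
    component; candidates missing from the graph become singleton clusters.
    Cluster ids are assigned deterministically in order of the smallest
    member accession (``TC0001``, ``TC0002``, ...).

    Returns a table with columns cluster_id, members (frozenset),
    n_members, n_evidence (number of supporting records, summed over
    member edges).
    """
    components = [set(c) for c in nx.connected_components(graph)]
    leftovers = candidates - set(graph.nodes)
    components.extend({c} for c in leftovers)
    components.sort(key=lambda c: min(c))
    rows = []
    for i, members in enumerate(components, start=1):
        sub = graph.subgraph(members) if members <= set(graph.nodes) else None
        n_evidence = (
            sum(len(d["provenance"]) for _, _, d in sub.edges(data=True)) if sub else 0
        )
        rows.append({
            "cluster_id": f"TC{i:04d}",
            "members": frozenset(members),
            "n_members": len(members),
            "n_evidence": n_evidence,
        })
    return pd.DataFrame(rows, columns=["cluster_id", "members", "n_members", "n_evidence"])


def partition_of(clusters: pd.DataFrame) -> set[frozenset[str]]:
    """The label-free partition a cluster table represents (for comparisons)."""
    return set(clusters["members"])
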