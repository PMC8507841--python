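"""End-to-end pipeline driver: screen → cluster → annotate → quantify → profile.

Convenience layer used by the CLI, the recovery tests and the acceptance
script; every step is an ordinary call into the per-stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import cluster_builder, ecology, family_screen, quantify, taxonomy
from .quantify import ClusterAbundance
from .substrate_annotator import AnnotationSource, annotate_clusters
from .synthetic_data import CommunityData, ReferenceData


@dataclass
class PipelineResult:
    """All intermediate and final tables of one pipeline run."""

    candidates: set[str]
    screen_counts: dict[str, int]
    removed_hubs: set[str]
    clusters: pd.DataFrame            # annotated cluster table
    tpm_mg: pd.DataFrame
    tpm_mt: pd.DataFrame
    orf_to_cluster: pd.Series
    abundance_mg: ClusterAbundance
    abundance_mt: ClusterAbundance
    abundant: set[str]                # union over MG and MT
    tensor_mg: pd.DataFrame           # taxon × category × sample (rank order)
    tensor_mt: pd.DataFrame
    orf_paths: dict[str, tuple[str, ...]]

    def cluster_category(self) -> dict[str, str]:
        return dict(zip(self.clusters["cluster_id"], self.clusters["category"]))

    def importer_clusters(self) -> set[str]:
        mask = self.clusters["transport_class"] == "importer"
        return set(self.clusters.loc[mask, "cluster_id"])


def build_clusters(
    reference: ReferenceData,
    terms=family_screen.DEFAULT_TERMS,
    max_degree: int = 6,
    sources: AnnotationSource | None = None,
) -> tuple[set[str], dict[str, int], set[str], pd.DataFrame]:
    """Reference half: screen families, build/prune the co-annotation
    graph, emit annotated clusters."""
    candidates, counts = family_screen.screen_families(reference.families, terms)
    graph = cluster_builder.build_coannotation_graph(
        candidates, reference.xrefs, reference.operons,
        known_families=set(reference.families["accession"]),
    )
    pruned, removed = cluster_builder.prune_hubs(graph, max_degree=max_degree)
    clusters = cluster_builder.cluster_families(pruned, candidates - removed)
    annotated = annotate_clusters(
        clusters, reference.families, sources or reference.sources
    )
    return candidates, counts, removed, annotated


def run_pipeline(
    reference: ReferenceData,
    community: CommunityData,
    terms=family_screen.DEFAULT_TERMS,
    max_degree: int = 6,
    abundance_threshold: float = 0.005,
    rank: str = "order",
) -> PipelineResult:
    """Run the whole analysis on simulated (or externally loaded) inputs."""
    candidates, counts, removed, annotated = build_clusters(
        reference, terms=terms, max_degree=max_degree
    )

    lengths = community.orfs.set_index("orf_id")["length"]
    tpm_mg = quantify.tpm_normalize(community.counts_mg, lengths)
    tpm_mt = quantify.tpm_normalize(community.counts_mt, lengths)

    mapping = quantify.map_orfs_to_clusters(community.orfs, annotated)
    ab_mg = quantify.cluster_abundance(tpm_mg, mapping, abundance_threshold)
    ab_mt = quantify.cluster_abundance(tpm_mt, mapping, abundance_threshold)
    abundant = quantify.abundant_clusters(ab_mg, ab_mt)

    contig_paths = taxonomy.vote_all_contigs(community.orfs)
    orf_paths = taxonomy.propagate_taxonomy(community.orfs, contig_paths)

    categories = dict(zip(annotated["cluster_id"], annotated["category"]))
    tensor_mg = taxonomy.aggregate_by_taxon(tpm_mg, mapping, categories, orf_paths, rank=rank)
    tensor_mt = taxonomy.aggregate_by_taxon(tpm_mt, mapping, categories, orf_paths, rank=rank)

    return PipelineResult(
        candidates=candidates,
        screen_counts=counts,
        removed_hubs=removed,
        clusters=annotated,
        tpm_mg=tpm_mg,
        tpm_mt=tpm_mt,
        orf_to_cluster=mapping,
        abundance_mg=ab_mg,
        abundance_mt=ab_mt,
        abundant=abundant,
        tensor_mg=tensor_mg,
        tensor_mt=tensor_mt,
        orf_paths=orf_paths,
    )


def env_screen_from_result(
    result: PipelineResult,
    env: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Spearman environment screen on the MG relative cluster abundances."""
    return ecology.spearman_env_screen(result.abundance_mg.relative, env, **kwargs)
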