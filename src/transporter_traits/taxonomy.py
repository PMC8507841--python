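"""Contig taxonomy voting, propagation, and taxon-level trait aggregation.

ORF-level taxonomic assignments are noisy, so a contig is assigned the
deepest lineage supported by a strict majority of its classified ORFs,
descending rank by rank (lowest-common-ancestor voting); the voted contig
path is then propagated back to every ORF on the contig, overriding the
individual hits. Transporter abundances are aggregated into a
taxon × substrate-category × sample tensor at a chosen rank (default
order), optionally under a domain grouping that reports Cyanobacteria
separately and subtracts them from Bacteria.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

UNCLASSIFIED = "Unclassified"

DOMAIN_GROUPS = (
    "Archaea", "Bacteria", "Cyanobacteria", "Picoeukaryota", "Viruses", UNCLASSIFIED,
)

TaxPath = tuple[str, ...]


def parse_path(text: str) -> TaxPath:
    """Parse a semicolon-delimited lineage; empty string → unclassified."""
    if not text or (isinstance(text, float) and np.isnan(text)):
        return ()
    return tuple(p.strip() for p in str(text).split(";") if p.strip())


def format_path(path: TaxPath) -> str:
    return ";".join(path)


def vote_contig_taxonomy(
    orf_paths: Sequence[TaxPath],
    majority_fraction: float = 0.5,
) -> TaxPath:
    """Lowest-common-ancestor vote over the ORF paths of one contig.

    Descends rank by rank. At each rank the label supported by a fraction
    strictly greater than ``majority_fraction`` of the ORFs classified at
    that rank (among ORFs consistent with the path chosen so far) is kept;
    the vote stops at the first rank without such a label. All-empty input
    yields the empty (unclassified) path.
    """
    if not 0.5 <= majority_fraction < 1:
        raise ValueError("majority_fraction must be in [0.5, 1)")
    consistent = list(orf_paths)
    chosen: list[str] = []
    for r in range(max((len(p) for p in consistent), default=0)):
        voters = [p[r] for p in consistent if len(p) > r]
        if not voters:
            break
        counts = Counter(voters)
        label = min(counts, key=lambda c: (-counts[c], c))
        if counts[label] / len(voters) <= majority_fraction:
            break
        chosen.append(label)
        consistent = [p for p in consistent if len(p) <= r or p[r] == label]
    return tuple(chosen)


def vote_all_contigs(
    orfs: pd.DataFrame,
    majority_fraction: float = 0.5,
) -> dict[str, TaxPath]:
    """Vote a taxonomy for every contig in an ORF table.

    ``orfs`` needs columns contig_id and taxonomy_hit (a path tuple).
    """
    out: dict[str, TaxPath] = {}
    for contig, group in orfs.groupby("contig_id"):
        out[str(contig)] = vote_contig_taxonomy(
            list(group["taxonomy_hit"]), majority_fraction
        )
    return out


def propagate_taxonomy(
    orfs: pd.DataFrame,
    contig_paths: Mapping[str, TaxPath],
) -> dict[str, TaxPath]:
    """Propagate voted contig paths to ORFs, overriding individual hits."""
    missing = set(orfs["contig_id"]) - set(contig_paths)
    if missing:
        raise ValueError(f"contigs without a voted path: {sorted(missing)[:5]}")
    return {
        orf: contig_paths[contig]
        for orf, contig in zip(orfs["orf_id"], orfs["contig_id"])
    }


def domain_group(path: TaxPath) -> str:
    """Map a lineage to a reporting group: Archaea, Bacteria (excluding
    Cyanobacteria), Cyanobacteria, Picoeukaryota, Viruses, Unclassified.

    Picoeukaryota is the Eukaryota domain in this size fraction;
    Cyanobacteria are identified by phylum label.
    """
    if not path:
        return UNCLASSIFIED
    domain = path[0]
    if domain == "Bacteria":
        return "Cyanobacteria" if len(path) > 1 and path[1] == "Cyanobacteria" else "Bacteria"
    if domain == "Eukaryota":
        return "Picoeukaryota"
    if domain in ("Archaea", "Viruses"):
        return domain
    return UNCLASSIFIED


def taxon_label(path: TaxPath, rank: str) -> str:
    ri = RANKS.index(rank)
    return path[ri] if len(path) > ri else UNCLASSIFIED


def aggregate_by_taxon(
    tpm: pd.DataFrame,
    orf_to_cluster: pd.Series,
    cluster_category: Mapping[str, str],
    orf_paths: Mapping[str, TaxPath],
    rank: str = "order",
    grouping: bool = False,
) -> pd.DataFrame:
    """Aggregate transporter TPM into a taxon × category × sample tensor.

    Each mapped ORF contributes its TPM to the cell
    (taxon at ``rank`` of its propagated path, category of its cluster).
    Unclassified abundance is retained in a dedicated bucket so that the
    per-category totals are conserved exactly. With ``grouping=True`` the
    taxon axis is the domain grouping (Cyanobacteria reported separately,
    i.e. subtracted from Bacteria).

    Returns a DataFrame with a (taxon, category) MultiIndex and sample
    columns.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    orf_ids = tpm.index.intersection(orf_to_cluster.index)
    labels = []
    for orf in orf_ids:
        path = orf_paths.get(orf, ())
        taxon = domain_group(path) if grouping else taxon_label(path, rank)
        labels.append((taxon, cluster_category[orf_to_cluster[orf]]))
    idx = pd.MultiIndex.from_tuples(labels, names=["taxon", "category"])
    tensor = tpm.loc[orf_ids].groupby(idx).sum()
    tensor.index = pd.MultiIndex.from_tuples(tensor.index, names=["taxon", "category"])
    return tensor.sort_index()


def composition(tensor: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon substrate composition: each taxon's categories normalized
    to fractions per sample (0/0 → 0)."""
    totals = tensor.groupby(level="taxon").transform("sum")
    return tensor.div(totals.mask(totals == 0, 1.0))


def pooled_composition(tensor: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon substrate composition pooled over samples.

    TPM is summed across samples before normalizing, so each sample
    contributes in proportion to the taxon's abundance there; for a taxon
    with a season-constant profile this is the minimum-variance estimate
    of that profile. Returns taxon × category fractions.
    """
    pooled = tensor.sum(axis=1).unstack("category", fill_value=0.0)
    totals = pooled.sum(axis=1)
    return pooled.div(totals.mask(totals == 0, 1.0), axis=0)


def taxon_richness_per_category(
    tensor: pd.DataFrame,
    min_abundance: float = 0.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Number of distinct taxa per substrate category, per sample.

    A taxon counts for a category in a sample iff its abundance exceeds
    ``min_abundance`` (strict). Returns (category × sample counts, period
    mean per category).
    """
    present = tensor > min_abundance
    counts = present.groupby(level="category").sum().astype(int)
    return counts, counts.mean(axis=1)


def importer_richness_per_taxon(
    tpm: pd.DataFrame,
    orf_to_cluster: pd.Series,
    importer_clusters: set[str],
    orf_paths: Mapping[str, TaxPath],
    raw_counts: pd.DataFrame,
    abundant_set: Iterable[str],
    rank: str = "order",
    quantile: float = 0.9,
    min_reads: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Importer-cluster richness per taxon and sample, with visibility mask.

    The count is the number of distinct importer clusters with abundance
    > 0 for the taxon in the sample. A taxon/sample cell is *visible* only
    when (a) the taxon's total transporter abundance is at or above the
    across-taxa ``quantile`` (linear-interpolation sample quantile) in that
    sample, and (b) strictly more than ``min_reads`` raw reads from that
    taxon map to the abundant transporter set.

    Returns (counts, visible) DataFrames indexed by taxon.
    """
    abundant_set = set(abundant_set)
    orf_ids = tpm.index.intersection(orf_to_cluster.index)
    taxa = pd.Series(
        [taxon_label(orf_paths.get(o, ()), rank) for o in orf_ids], index=orf_ids
    )
    clusters = orf_to_cluster.loc[orf_ids]

    imp_mask = clusters.isin(importer_clusters)
    per_cluster = tpm.loc[orf_ids[imp_mask]].copy()
    per_cluster.index = pd.MultiIndex.from_arrays(
        [taxa[imp_mask], clusters[imp_mask]], names=["taxon", "cluster"]
    )
    per_cluster = per_cluster.groupby(level=["taxon", "cluster"]).sum()
    counts = (per_cluster > 0).groupby(level="taxon").sum().astype(int)

    totals = tpm.loc[orf_ids].groupby(taxa.values).sum()
    thresholds = totals.quantile(quantile, axis=0, interpolation="linear")
    vis_quantile = totals.ge(thresholds, axis=1)

    ab_mask = clusters.isin(abundant_set)
    raw = raw_counts.reindex(index=orf_ids[ab_mask], columns=tpm.columns, fill_value=0)
    reads = raw.groupby(taxa[ab_mask].values).sum()
    vis_reads = reads.reindex(totals.index, fill_value=0) > min_reads

    visible = (vis_quantile & vis_reads).reindex(counts.index, fill_value=False)
    return counts, visible
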