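"""TPM normalization, ORF→cluster mapping, and cluster abundance.

TPM (transcripts per million) length-normalizes raw ORF read counts:

    tpm(i, s) = 1e6 * (c(i,s) / L(i)) / sum_j (c(j,s) / L(j))

so every sample column with any reads sums to one million. Cluster
abundances are TPM sums over the ORFs mapped to each non-excluded transport
cluster; relative abundance divides by the per-sample total over all
transporter clusters. A cluster is "abundant" when its relative abundance
exceeds a threshold (default 0.5%, strict) in at least one sample of either
the metagenome (MG) or the metatranscriptome (MT) dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: ORF assignment priority when hits fall in several clusters.
SOURCE_PRIORITY = {"TIGRFAM": 0, "COG": 1, "PFAM": 2}


def accession_source(accession: str) -> str:
    """Infer the source database from the accession prefix."""
    if accession.startswith("TIGR"):
        return "TIGRFAM"
    if accession.startswith("COG"):
        return "COG"
    if accession.startswith("PF"):
        return "PFAM"
    raise ValueError(f"cannot infer source database of accession {accession!r}")


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """TPM-normalize an ORF × sample count matrix given ORF lengths (bp).

    Columns with zero depth stay all-zero (with a warning). Scaling all
    counts in a sample by a constant leaves its TPM column unchanged.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing lengths for ORFs: {list(missing[:5])}...")
    L = lengths.loc[counts.index].astype(float)
    if (L <= 0).any():
        raise ValueError("ORF lengths must be positive")
    rates = counts.div(L, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"zero-depth samples left all-zero: {list(totals.index[zero])}")
        totals = totals.mask(zero, 1.0)
    return rates.div(totals, axis=1) * 1e6


def map_orfs_to_clusters(
    orfs: pd.DataFrame,
    annotated_clusters: pd.DataFrame,
) -> pd.Series:
    """Map each ORF to at most one non-excluded transport cluster.

    An ORF maps iff at least one of its family hits belongs to a
    non-excluded cluster. When hits span several clusters the cluster of
    the highest-priority hit wins (TIGRFAM > COG > PFAM, then lexicographic
    accession), so no ORF is double counted.

    Returns a Series orf_id → cluster_id covering mapped ORFs only.
    """
    fam_to_cluster: dict[str, str] = {}
    for rec in annotated_clusters.to_dict("records"):
        if rec.get("excluded", False):
            continue
        for acc in rec["members"]:
            fam_to_cluster[acc] = rec["cluster_id"]
    assigned = {}
    for orf_id, hits in zip(orfs["orf_id"], orfs["family_hits"]):
        mapped = [h for h in hits if h in fam_to_cluster]
        if not mapped:
            continue
        best = min(mapped, key=lambda a: (SOURCE_PRIORITY[accession_source(a)], a))
        assigned[orf_id] = fam_to_cluster[best]
    return pd.Series(assigned, name="cluster_id", dtype=object)


@dataclass
class ClusterAbundance:
    """Per-cluster TPM sums and relative abundances for one dataset."""

    entries: pd.DataFrame        # cluster × sample TPM sums
    relative: pd.DataFrame       # cluster × sample fractions of transporter TPM
    abundant_set: set[str]       # clusters > threshold in >=1 sample (this dataset)
    threshold: float


def cluster_abundance(
    tpm: pd.DataFrame,
    mapping: pd.Series,
    threshold: float = 0.005,
) -> ClusterAbundance:
    """Sum TPM per cluster and compute relative abundances.

    Samples where no transporter ORF has any signal get an all-zero
    relative column (with a warning). The abundance filter is a strict
    inequality: relative > threshold in at least one sample.
    """
    if mapping.empty:
        raise ValueError("orf→cluster mapping is empty")
    mapped = tpm.loc[tpm.index.intersection(mapping.index)]
    entries = mapped.groupby(mapping.loc[mapped.index]).sum()
    entries.index.name = "cluster_id"
    totals = entries.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero transporter signal reported as zeros: {list(totals.index[zero])}"
        )
    relative = entries.div(totals.mask(zero, 1.0), axis=1)
    abundant = set(entries.index[(relative > threshold).any(axis=1)])
    return ClusterAbundance(entries, relative, abundant, threshold)


def abundant_clusters(*abundances: ClusterAbundance) -> set[str]:
    """Union-over-datasets abundance filter (abundant in MG *or* MT)."""
    out: set[str] = set()
    for ab in abundances:
        out |= ab.abundant_set
    return out


def mass_partition_gap(tpm: pd.DataFrame, mapping: pd.Series, abundance: ClusterAbundance) -> float:
    """Largest absolute gap between cluster sums and mapped-ORF TPM totals
    (diagnostic for the each-ORF-counted-once invariant)."""
    mapped = tpm.loc[tpm.index.intersection(mapping.index)]
    return float(np.abs(abundance.entries.sum(axis=0) - mapped.sum(axis=0)).max())
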