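"""Plain-TSV serialization of all pipeline tables.

Set-valued columns (family accessions) are comma-joined; taxonomy paths are
semicolon-joined; count matrices keep the ORF id as the row key with one
column per sample.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .cluster_builder import OperonEntry, XrefEntry
from .taxonomy import format_path, parse_path


def write_families(families: pd.DataFrame, path: str | Path) -> None:
    families.to_csv(path, sep="\t", index=False)


def read_families(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str).fillna("")


def write_xrefs(xrefs: Iterable[XrefEntry], path: str | Path) -> None:
    rows = [
        {"entry_id": x.entry_id, "reviewed": int(x.reviewed),
         "accessions": ",".join(sorted(x.family_accessions))}
        for x in xrefs
    ]
    pd.DataFrame(rows, columns=["entry_id", "reviewed", "accessions"]).to_csv(
        path, sep="\t", index=False
    )


def read_xrefs(path: str | Path) -> list[XrefEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"entry_id": str, "accessions": str})
    return [
        XrefEntry(r.entry_id, frozenset(r.accessions.split(",")), bool(int(r.reviewed)))
        for r in df.itertuples()
    ]


def write_operons(operons: Iterable[OperonEntry], path: str | Path) -> None:
    rows = [
        {"operon_id": op.operon_id, "accessions": ",".join(sorted(op.family_accessions))}
        for op in operons
    ]
    pd.DataFrame(rows, columns=["operon_id", "accessions"]).to_csv(path, sep="\t", index=False)


def read_operons(path: str | Path) -> list[OperonEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [OperonEntry(r.operon_id, frozenset(r.accessions.split(","))) for r in df.itertuples()]


def write_orfs(orfs: pd.DataFrame, path: str | Path) -> None:
    out = orfs.copy()
    out["family_hits"] = out["family_hits"].map(lambda s: ",".join(sorted(s)))
    out["taxonomy_hit"] = out["taxonomy_hit"].map(format_path)
    out.to_csv(path, sep="\t", index=False)


def read_orfs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"orf_id": str, "contig_id": str, "family_hits": str, "taxonomy_hit": str},
    )
    df["family_hits"] = df["family_hits"].fillna("").map(
        lambda s: frozenset(a for a in s.split(",") if a)
    )
    df["taxonomy_hit"] = df["taxonomy_hit"].fillna("").map(parse_path)
    df["length"] = df["length"].astype(int)
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="orf_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="orf_id")


def write_clusters(clusters: pd.DataFrame, path: str | Path) -> None:
    out = clusters.copy()
    out["members"] = out["members"].map(lambda s: ",".join(sorted(s)))
    out.to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["members"] = df["members"].map(lambda s: frozenset(str(s).split(",")))
    return df


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "dataset": str})
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_env(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t", index_label="sample_id")


def read_env(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_tensor(tensor: pd.DataFrame, path: str | Path) -> None:
    """Taxon × category × sample tensor as a long-format TSV."""
    long = tensor.stack().rename("abundance").reset_index()
    long.columns = ["taxon", "category", "sample_id", "abundance"]
    long.to_csv(path, sep="\t", index=False)


def read_tensor(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    return long.pivot_table(
        index=["taxon", "category"], columns="sample_id", values="abundance", fill_value=0.0
    )
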