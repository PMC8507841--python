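"""Substrate and transport-direction annotation of transport clusters.

A transport cluster (a set of protein families jointly representing one
membrane transporter) is assigned:

* a **substrate category** — one of nine putative substrate groups used for
  importer trait profiling (amino acids/peptides + ammonium, carbohydrates,
  nucleosides, anions, cations, nitrate, urea, phosphate, phosphonate), or
  ``unannotated`` when no evidence links the cluster to any category;
* a **transport class** — importer, utility exporter, toxin exporter, metal
  transporter (kept separate because metal-ion transport is frequently
  bidirectional), or other;
* optionally a **secretion type** (Type I/II/III/V/VI) when the cluster is a
  toxin exporter, and a **TCDB mechanism class** when curated.

Category evidence comes from TIGRFAM-role hints, Gene Ontology hints, and a
machine-readable curated override table; TIGRFAM roles take precedence over
GO, and overrides beat both. Unannotated clusters are flagged ``excluded``
and must not enter any downstream abundance table.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The nine substrate categories used for importer trait profiling.
SUBSTRATE_CATEGORIES: tuple[str, ...] = (
    "amino_acids_peptides_ammonium",
    "carbohydrate",
    "nucleoside",
    "anion",
    "cation",
    "nitrate",
    "urea",
    "phosphate",
    "phosphonate",
)

UNANNOTATED = "unannotated"

TRANSPORT_CLASSES: tuple[str, ...] = (
    "importer",
    "exporter_utility",
    "exporter_toxin",
    "metal",
    "other",
)

SECRETION_TYPES: tuple[str, ...] = ("T1", "T2", "T3", "T5", "T6", "other")

TCDB_CLASSES: tuple[str, ...] = (
    "1A", "1B", "2A", "2C", "3A", "3D", "4A", "4B", "9A",
)


@dataclass(frozen=True)
class Override:
    """One curated override record (replaces the manual literature curation)."""

    category: str | None = None
    transport_class: str | None = None
    secretion_type: str | None = None
    tcdb: str | None = None
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in SUBSTRATE_CATEGORIES:
            raise ValueError(f"unknown substrate category: {self.category!r}")
        if self.transport_class is not None and self.transport_class not in TRANSPORT_CLASSES:
            raise ValueError(f"unknown transport class: {self.transport_class!r}")
        if self.secretion_type is not None and self.secretion_type not in SECRETION_TYPES:
            raise ValueError(f"unknown secretion type: {self.secretion_type!r}")
        if self.tcdb is not None and self.tcdb not in TCDB_CLASSES:
            raise ValueError(f"unknown TCDB class: {self.tcdb!r}")


@dataclass
class AnnotationSource:
    """Category/class evidence tables.

    tigr_roles / go_map map family accessions to substrate-category hints;
    overrides map a family accession or a cluster id to an :class:`Override`.
    """

    tigr_roles: Mapping[str, str] = field(default_factory=dict)
    go_map: Mapping[str, str] = field(default_factory=dict)
    overrides: Mapping[str, Override] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, hints in (("tigr_roles", self.tigr_roles), ("go_map", self.go_map)):
            bad = {c for c in hints.values() if c not in SUBSTRATE_CATEGORIES}
            if bad:
                raise ValueError(f"{name} contains unknown categories: {sorted(bad)}")


# Ordered keyword rules for the importer/exporter split. Metal is ranked
# first (bidirectional metal-ion transporters are kept out of both groups),
# then toxin secretion, then utility export; anything left that looks like
# uptake is an importer, and the fall-through is "other".
DEFAULT_CLASS_RULES: tuple[tuple[tuple[str, ...], str], ...] = (
    (("metal ion", "cobalt", "zinc", "cadmium", "nickel", "manganese",
      "copper", "magnesium"), "metal"),
    (("secretion", "hemolysin", "toxin", "autotransporter", "cytolysin"),
     "exporter_toxin"),
    (("efflux", "export", "excretion", "translocase"), "exporter_utility"),
    (("uptake", "import", "symport", "antiport", "permease",
      "substrate-binding"), "importer"),
)

_SECRETION_PATTERNS: tuple[tuple[str, str], ...] = (
    ("type vi secretion", "T6"),
    ("type iii secretion", "T3"),
    ("type ii secretion", "T2"),
    ("type v secretion", "T5"),
    ("type i secretion", "T1"),
    ("autotransporter", "T5"),
    ("hemolysin", "T1"),
)


def _majority(hints: Sequence[str]) -> tuple[str | None, bool]:
    """Majority vote over category hints; ties go to the lexicographically
    smallest category and are flagged."""
    if not hints:
        return None, False
    counts = Counter(hints)
    top = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == top)
    return winners[0], len(winners) > 1


def annotate_cluster(
    members: Iterable[str],
    sources: AnnotationSource,
    cluster_id: str | None = None,
) -> tuple[str, bool, bool]:
    """Resolve the substrate category of one cluster.

    Resolution order: curated override (cluster id, then any member family,
    smallest accession first) → majority vote over member TIGRFAM-role hints
    → majority vote over member GO hints → ``unannotated``.

    Returns ``(category, tie_flag, excluded)``.
    """
    members = sorted(members)
    if not members:
        raise ValueError("cluster has no members")
    for key in ([cluster_id] if cluster_id is not None else []) + members:
        ov = sources.overrides.get(key)
        if ov is not None and ov.category is not None:
            return ov.category, False, False
    tigr_hints = [sources.tigr_roles[m] for m in members if m in sources.tigr_roles]
    category, tie = _majority(tigr_hints)
    if category is None:
        go_hints = [sources.go_map[m] for m in members if m in sources.go_map]
        category, tie = _majority(go_hints)
    if category is None:
        return UNANNOTATED, False, True
    return category, tie, False


def classify_transport_class(
    members: Iterable[str],
    descriptions: Mapping[str, str],
    sources: AnnotationSource,
    cluster_id: str | None = None,
    keyword_rules: Sequence[tuple[Sequence[str], str]] = DEFAULT_CLASS_RULES,
) -> tuple[str, str | None, str | None]:
    """Assign the transport class (and secretion type for toxin exporters).

    The override wins; otherwise the first keyword rule whose terms match any
    member description (case-insensitive substring) assigns the class; no
    match falls through to ``other``. Returns
    ``(transport_class, secretion_type, tcdb_class)``.
    """
    if not keyword_rules:
        raise ValueError("keyword_rules must be non-empty")
    members = sorted(members)
    texts = [descriptions.get(m, "").lower() for m in members]
    tcdb = None
    for key in ([cluster_id] if cluster_id is not None else []) + members:
        ov = sources.overrides.get(key)
        if ov is None:
            continue
        if tcdb is None and ov.tcdb is not None:
            tcdb = ov.tcdb
        if ov.transport_class is not None:
            sec = ov.secretion_type
            if ov.transport_class == "exporter_toxin" and sec is None:
                sec = _detect_secretion_type(texts)
            return ov.transport_class, sec, tcdb
    for terms, klass in keyword_rules:
        if any(t.lower() in text for text in texts for t in terms):
            sec = _detect_secretion_type(texts) if klass == "exporter_toxin" else None
            return klass, sec, tcdb
    return "other", None, tcdb


def _detect_secretion_type(texts: Sequence[str]) -> str:
    joined = " ".join(texts)
    for pattern, sec in _SECRETION_PATTERNS:
        # word-boundary after "type i/ii/..." so "type ii" does not also hit "type i"
        if re.search(re.escape(pattern) + r"\b" if pattern.startswith("type") else re.escape(pattern), joined):
            return sec
    return "other"


def annotate_clusters(
    clusters: pd.DataFrame,
    families: pd.DataFrame,
    sources: AnnotationSource,
    keyword_rules: Sequence[tuple[Sequence[str], str]] = DEFAULT_CLASS_RULES,
) -> pd.DataFrame:
    """Annotate a cluster table (as produced by ``cluster_families``).

    Adds ``category``, ``transport_class``, ``secretion_type``, ``tcdb``,
    ``excluded`` and ``tie_flag`` columns. ``families`` supplies the member
    descriptions searched by the keyword rules.
    """
    descriptions = dict(zip(families["accession"], families["description"]))
    rows = []
    for rec in clusters.to_dict("records"):
        members = sorted(rec["members"])
        category, tie, excluded = annotate_cluster(members, sources, rec["cluster_id"])
        klass, sec, tcdb = classify_transport_class(
            members, descriptions, sources, rec["cluster_id"], keyword_rules
        )
        rows.append({
            **rec,
            "category": category,
            "transport_class": klass,
            "secretion_type": sec,
            "tcdb": tcdb,
            "excluded": excluded,
            "tie_flag": tie,
        })
    return pd.DataFrame(rows)
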