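"""Text screen for transporter-related protein families.

Candidate transporter families are found by case-insensitive text search over
the name and description fields of PFAM/TIGRFAM/COG family metadata. The
default term list (transport, efflux, uptake, symport, antiport) is the
printed example set and is deliberately configurable: a production screen of
real database releases will want a richer pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

#: Default screen terms.
DEFAULT_TERMS: tuple[str, ...] = (
    "transport", "efflux", "uptake", "symport", "antiport",
)

REQUIRED_FAMILY_COLUMNS = ("accession", "source_db", "name", "description")
SOURCE_DBS = ("PFAM", "TIGRFAM", "COG")


@dataclass(frozen=True)
class ScreenPattern:
    """An ordered list of case-insensitive match terms.

    mode="substring" matches anywhere ("symport" hits "symporter");
    mode="word" requires word boundaries for a stricter screen.
    """

    terms: tuple[str, ...] = field(default=DEFAULT_TERMS)
    mode: str = "substring"

    def __post_init__(self) -> None:
        if not self.terms or any(not t for t in self.terms):
            raise ValueError("pattern terms must be non-empty")
        if self.mode not in ("substring", "word"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        object.__setattr__(self, "terms", tuple(self.terms))

    def matches(self, text: str) -> bool:
        low = text.lower()
        if self.mode == "substring":
            return any(t.lower() in low for t in self.terms)
        return any(
            re.search(r"\b" + re.escape(t.lower()) + r"\b", low) for t in self.terms
        )


def screen_families(
    families: pd.DataFrame,
    pattern: ScreenPattern | Iterable[str] = DEFAULT_TERMS,
) -> tuple[set[str], dict[str, int]]:
    """Screen a family table for transporter candidates.

    Parameters
    ----------
    families
        Table with columns accession, source_db, name, description.
    pattern
        A :class:`ScreenPattern` or a bare term iterable (substring mode).

    Returns
    -------
    (candidates, per_source_counts)
        The candidate accession set and the number of candidates per
        source database.
    """
    if not isinstance(pattern, ScreenPattern):
        pattern = ScreenPattern(tuple(pattern))
    missing = [c for c in REQUIRED_FAMILY_COLUMNS if c not in families.columns]
    if missing:
        raise ValueError(f"family table lacks columns: {missing}")
    if families.empty:
        raise ValueError("family table is empty")
    if families["accession"].duplicated().any():
        dups = families.loc[families["accession"].duplicated(), "accession"]
        raise ValueError(f"duplicate accessions: {sorted(set(dups))}")

    hit = [
        pattern.matches(f"{name} {desc}")
        for name, desc in zip(families["name"].fillna(""), families["description"].fillna(""))
    ]
    cand = families.loc[hit]
    candidates = set(cand["accession"])
    counts = {db: int((cand["source_db"] == db).sum()) for db in SOURCE_DBS}
    return candidates, counts
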