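"""Published summary counts from the Baltic Sea picoplankton transporter
survey this pipeline re-implements, with the arithmetic that ties them
together.

These numbers describe the original full-scale analysis (a Baltic Sea
reference co-assembly annotated against March-2018 database snapshots);
they are inputs for consistency arithmetic, not something the desk-scale
synthetic pipeline reproduces.
"""

from __future__ import annotations

#: ORFs in the reference co-assembly, and those identified as transporters.
TOTAL_ORFS = 6_757_106
TRANSPORTER_ORFS = 66_029

#: Transport clusters overall, and the subset linked to TIGRFAM families.
TOTAL_CLUSTERS = 1_149
TIGR_LINKED_CLUSTERS = 338

#: Published total of "abundant" clusters (>0.5% relative abundance in at
#: least one MG or MT sample) and its breakdown by transport class.
ABUNDANT_TOTAL = 124
ABUNDANT_BREAKDOWN = {
    "importer": 59,
    "exporter_utility": 25,
    "exporter_toxin": 21,
    "other": 10,
    "metal": 9,
}

#: Toxin-secretion exporter clusters by secretion type, with published total.
SECRETION_TOTAL = 74
SECRETION_BREAKDOWN = {"T1": 13, "T2": 20, "T3": 2, "T5": 8, "T6": 27, "other": 4}

#: TCDB mechanism-class shares of the importers (percent). The two major
#: classes are printed exactly; the minor classes are printed rounded.
TCDB_MAJOR_SHARES = {"2A": 43, "3A": 42}
TCDB_MINOR_SHARES = {"1A": 5, "1B": 2, "2C": 1, "3D": 4, "4A": 2, "4B": 2, "9A": 1}


def abundant_breakdown_total(breakdown: dict[str, int] = ABUNDANT_BREAKDOWN) -> int:
    """Sum of the per-class abundant-cluster counts."""
    return sum(breakdown.values())


def secretion_breakdown_total(breakdown: dict[str, int] = SECRETION_BREAKDOWN) -> int:
    """Sum of the per-secretion-type cluster counts."""
    return sum(breakdown.values())


def tcdb_residual_share(major: dict[str, int] = TCDB_MAJOR_SHARES) -> int:
    """Importer share (percent) outside the two dominant TCDB classes."""
    return 100 - sum(major.values())


def transporter_orf_percentage(
    transporter_orfs: int = TRANSPORTER_ORFS,
    total_orfs: int = TOTAL_ORFS,
) -> float:
    """Transporter ORFs as a percentage of all assembly ORFs."""
    return 100.0 * transporter_orfs / total_orfs
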