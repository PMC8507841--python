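"""Synthetic pipeline inputs with planted ground truth.

Two generators cover the whole pipeline surface:

* :func:`simulate_reference` builds the *reference side*: protein-family
  metadata for the three source databases, reviewed cross-reference entries
  and operons that connect each planted transport cluster into one
  co-annotation component (and nothing else), optional hub families with
  many partners across clusters (emulating generic domains such as the ABC
  ATP-binding domain), decoy (non-transporter) families, and the
  TIGRFAM-role / GO hint tables that drive substrate annotation.

* :func:`simulate_community` builds the *sample side*: a taxon-structured
  ORF catalogue on contigs, metagenome (MG) and metatranscriptome (MT)
  count matrices drawn multinomially from Gaussian seasonal taxon peaks
  split across substrate categories by per-taxon profiles, plus sample
  metadata and environmental covariates optionally linked to taxon
  trajectories.

Everything planted is recorded in a :class:`GroundTruth` object so that
recovery by the analysis pipeline can be tested exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_builder import OperonEntry, XrefEntry
from .substrate_annotator import (
    SECRETION_TYPES,
    SUBSTRATE_CATEGORIES,
    TRANSPORT_CLASSES,
    AnnotationSource,
)

# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class ClusterSpec:
    """One planted transport cluster."""

    cluster_id: str
    n_families: int
    substrate_category: str
    transport_class: str
    secretion_type: str | None = None

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError(f"{self.cluster_id}: n_families must be >= 1")
        if self.substrate_category not in SUBSTRATE_CATEGORIES:
            raise ValueError(f"{self.cluster_id}: unknown category {self.substrate_category!r}")
        if self.transport_class not in TRANSPORT_CLASSES:
            raise ValueError(f"{self.cluster_id}: unknown class {self.transport_class!r}")
        if self.secretion_type is not None and self.secretion_type not in SECRETION_TYPES:
            raise ValueError(f"{self.cluster_id}: unknown secretion type {self.secretion_type!r}")


@dataclass(frozen=True)
class TaxonSpec:
    """One planted taxon: a Gaussian seasonal peak and a substrate profile.

    peak_day is the day of year of maximum abundance, peak_width the
    Gaussian s.d. in days, amplitude the relative peak height, and
    substrate_profile the fixed split of the taxon's transporter abundance
    over the nine substrate categories (sums to 1).
    """

    taxon_path: tuple[str, ...]
    peak_day: float
    peak_width: float
    amplitude: float
    substrate_profile: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        prof = dict(self.substrate_profile)
        if any(v < 0 for v in prof.values()):
            raise ValueError("substrate_profile entries must be >= 0")
        unknown = set(prof) - set(SUBSTRATE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in profile: {sorted(unknown)}")
        if abs(sum(prof.values()) - 1.0) > 1e-9:
            raise ValueError("substrate_profile must sum to 1")
        object.__setattr__(self, "taxon_path", tuple(self.taxon_path))
        object.__setattr__(self, "substrate_profile", prof)

    @property
    def label(self) -> str:
        """The deepest rank label (used as the taxon name at rank order)."""
        return self.taxon_path[-1]

    def weight(self, day_of_year: float) -> float:
        d = day_of_year - self.peak_day
        return self.amplitude * math.exp(-(d * d) / (2 * self.peak_width**2))


@dataclass
class CommunitySpec:
    """Sampling design for the synthetic community.

    ``decoy_fraction`` is the fraction of the ORF *catalogue* made of
    non-transporter decoys. Decoy ORFs jointly carry a season-constant
    read mass of ``background_weight`` times the peak transporter mass,
    emulating the stable non-transporter bulk of a real metagenome (in
    which transporter genes are a small, seasonally varying slice); with
    the default of 9, transporters take ≈10% of reads at the seasonal peak
    and less off-peak, and transporter TPM tracks each taxon's absolute
    trajectory instead of being renormalized against the other taxa.
    """

    taxa: list[TaxonSpec]
    n_samples_mg: int = 33
    n_samples_mt: int = 25
    sample_dates_mg: Sequence[pd.Timestamp] | None = None
    sample_dates_mt: Sequence[pd.Timestamp] | None = None
    depth: int = 100_000
    orfs_per_cluster_per_taxon: int = 3
    orf_length_range: tuple[int, int] = (300, 3000)
    decoy_fraction: float = 0.2
    background_weight: float = 9.0
    env_link: Mapping[str, tuple[str, int]] = field(default_factory=dict)
    mt_expression: Mapping[str, float] = field(default_factory=dict)
    contig_size: int = 5

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("taxa list must be non-empty")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if self.background_weight < 0:
            raise ValueError("background_weight must be >= 0")
        lo, hi = self.orf_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid orf_length_range")


@dataclass
class GroundTruth:
    """Everything planted, for exact recovery tests."""

    true_clusters: dict[str, frozenset[str]]
    hub_families: frozenset[str]
    true_candidates: frozenset[str]
    cluster_specs: list[ClusterSpec]
    decoy_families: frozenset[str]
    orf_to_cluster: dict[str, str] = field(default_factory=dict)
    orf_to_taxon: dict[str, str] = field(default_factory=dict)
    expected_composition: pd.DataFrame | None = None

    def partition(self) -> set[frozenset[str]]:
        return set(self.true_clusters.values())

    def to_json(self) -> str:
        payload = {
            "true_clusters": {k: sorted(v) for k, v in self.true_clusters.items()},
            "hub_families": sorted(self.hub_families),
            "true_candidates": sorted(self.true_candidates),
            "decoy_families": sorted(self.decoy_families),
            "cluster_specs": [
                {
                    "cluster_id": s.cluster_id,
                    "n_families": s.n_families,
                    "substrate_category": s.substrate_category,
                    "transport_class": s.transport_class,
                    "secretion_type": s.secretion_type,
                }
                for s in self.cluster_specs
            ],
            "orf_to_cluster": self.orf_to_cluster,
            "orf_to_taxon": self.orf_to_taxon,
        }
        if self.expected_composition is not None:
            tensor = self.expected_composition
            payload["expected_composition"] = {
                f"{t}|{c}": {s: float(v) for s, v in row.items()}
                for (t, c), row in tensor.iterrows()
            }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        tensor = None
        if "expected_composition" in d:
            rows = {
                tuple(k.split("|")): v for k, v in d["expected_composition"].items()
            }
            tensor = pd.DataFrame.from_dict(rows, orient="index")
            tensor.index = pd.MultiIndex.from_tuples(tensor.index, names=["taxon", "category"])
        return cls(
            true_clusters={k: frozenset(v) for k, v in d["true_clusters"].items()},
            hub_families=frozenset(d["hub_families"]),
            true_candidates=frozenset(d["true_candidates"]),
            cluster_specs=[ClusterSpec(**s) for s in d["cluster_specs"]],
            decoy_families=frozenset(d["decoy_families"]),
            orf_to_cluster=dict(d["orf_to_cluster"]),
            orf_to_taxon=dict(d["orf_to_taxon"]),
            expected_composition=tensor,
        )


@dataclass
class ReferenceData:
    """Output bundle of :func:`simulate_reference`."""

    families: pd.DataFrame
    xrefs: list[XrefEntry]
    operons: list[OperonEntry]
    sources: AnnotationSource
    truth: GroundTruth


@dataclass
class CommunityData:
    """Output bundle of :func:`simulate_community`."""

    orfs: pd.DataFrame
    counts_mg: pd.DataFrame
    counts_mt: pd.DataFrame
    samples: pd.DataFrame
    env: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# reference-side generation

_CATEGORY_WORDS = {
    "amino_acids_peptides_ammonium": "amino acid/peptide/ammonium",
    "carbohydrate": "carbohydrate",
    "nucleoside": "nucleoside",
    "anion": "sulfate/molybdate anion",
    "cation": "siderophore/organic cation",
    "nitrate": "nitrate",
    "urea": "urea",
    "phosphate": "phosphate",
    "phosphonate": "phosphonate",
}

_SECRETION_WORDS = {
    "T1": "type i secretion",
    "T2": "type ii secretion",
    "T3": "type iii secretion",
    "T5": "type v secretion",
    "T6": "type vi secretion",
    "other": "toxin secretion",
}

# Decoy text must not contain any default screen term.
_DECOY_DESCRIPTIONS = (
    "ribosomal protein subunit",
    "transcription initiation factor",
    "DNA polymerase III subunit",
    "cell division protein FtsZ homolog",
    "chaperonin GroEL-like protein",
    "two-component sensor histidine kinase",
    "tRNA modification GTPase",
    "peptidoglycan synthesis enzyme",
)


def _class_description(spec: ClusterSpec, part: int) -> str:
    word = _CATEGORY_WORDS[spec.substrate_category]
    if spec.transport_class == "importer":
        return f"{word} uptake transporter, subunit {part}"
    if spec.transport_class == "exporter_utility":
        return f"{word} efflux system membrane component {part}"
    if spec.transport_class == "exporter_toxin":
        sec = _SECRETION_WORDS[spec.secretion_type or "T2"]
        return f"{sec} system transport protein {part}"
    if spec.transport_class == "metal":
        return f"cobalt-zinc-cadmium metal ion efflux transporter {part}"
    return f"membrane transport protein of unresolved direction, subunit {part}"


class _AccessionFactory:
    def __init__(self) -> None:
        self.counters = {"TIGRFAM": 0, "PFAM": 0, "COG": 0}

    def next(self, source: str) -> str:
        self.counters[source] += 1
        n = self.counters[source]
        return {"TIGRFAM": f"TIGR{n:05d}", "PFAM": f"PF{n:05d}", "COG": f"COG{n:04d}"}[source]


def simulate_reference(
    cluster_specs: Sequence[ClusterSpec],
    n_decoy_families: int = 0,
    hub_spec: tuple[int, int] = (0, 7),
    seed: int = 0,
    n_unreviewed_noise: int = 0,
) -> ReferenceData:
    """Generate the reference-side inputs with planted cluster structure.

    Every multi-family cluster is connected by a chain of reviewed
    cross-reference / operon co-annotations among its own members only.
    Hubs (``hub_spec = (n_hubs, hub_degree)``, degree must be >= 7 so they
    exceed the degree-6 pruning cutoff) are extra candidate families
    co-annotated with ``hub_degree`` partners drawn across clusters. Decoy
    families carry no screen keyword. ``n_unreviewed_noise`` adds
    unreviewed cross-cluster entries that a correct graph builder must
    ignore.
    """
    if n_decoy_families < 0:
        raise ValueError("n_decoy_families must be >= 0")
    n_hubs, hub_degree = hub_spec
    if n_hubs < 0:
        raise ValueError("n_hubs must be >= 0")
    if n_hubs > 0 and hub_degree < 7:
        raise ValueError("hub_degree must be >= 7 so hubs exceed the pruning cutoff")
    ids = [s.cluster_id for s in cluster_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cluster ids in specs")

    rng = np.random.default_rng(seed)
    acc = _AccessionFactory()
    fam_rows: list[dict] = []
    tigr_roles: dict[str, str] = {}
    go_map: dict[str, str] = {}
    true_clusters: dict[str, frozenset[str]] = {}
    xrefs: list[XrefEntry] = []
    operons: list[OperonEntry] = []
    xref_n = operon_n = 0

    source_cycle = ("TIGRFAM", "PFAM", "COG")
    for spec in cluster_specs:
        members = []
        for j in range(spec.n_families):
            source = source_cycle[j % 3]
            a = acc.next(source)
            members.append(a)
            fam_rows.append({
                "accession": a,
                "source_db": source,
                "name": f"{spec.cluster_id}_{j}",
                "description": _class_description(spec, j),
            })
            if source == "TIGRFAM":
                tigr_roles[a] = spec.substrate_category
            go_map[a] = spec.substrate_category
        true_clusters[spec.cluster_id] = frozenset(members)
        # connect the cluster: a 3-way entry when possible, then a pair chain
        start = 0
        if len(members) >= 3:
            xref_n += 1
            xrefs.append(XrefEntry(f"X{xref_n:05d}", frozenset(members[:3]), reviewed=True))
            start = 2
        for j in range(start, len(members) - 1):
            pair = frozenset(members[j: j + 2])
            if j % 2 == 0:
                xref_n += 1
                xrefs.append(XrefEntry(f"X{xref_n:05d}", pair, reviewed=True))
            else:
                operon_n += 1
                operons.append(OperonEntry(f"OP{operon_n:05d}", pair))

    all_members = [m for s in cluster_specs for m in sorted(true_clusters[s.cluster_id])]
    hubs: list[str] = []
    if n_hubs > 0:
        if len(all_members) < hub_degree:
            raise ValueError("not enough planted families to satisfy hub_degree")
        # interleave members across clusters so hub partners span clusters
        by_cluster = [sorted(true_clusters[s.cluster_id]) for s in cluster_specs]
        interleaved: list[str] = []
        depth_i = 0
        while len(interleaved) < len(all_members):
            for group in by_cluster:
                if depth_i < len(group):
                    interleaved.append(group[depth_i])
            depth_i += 1
        for h in range(n_hubs):
            a = acc.next("PFAM")
            hubs.append(a)
            fam_rows.append({
                "accession": a,
                "source_db": "PFAM",
                "name": f"hub_{h}",
                "description": "ABC transporter ATP-binding domain protein",
            })
            offset = (h * hub_degree) % len(interleaved)
            partners = [interleaved[(offset + i) % len(interleaved)] for i in range(hub_degree)]
            for p in dict.fromkeys(partners):
                xref_n += 1
                xrefs.append(XrefEntry(f"X{xref_n:05d}", frozenset({a, p}), reviewed=True))

    decoys: list[str] = []
    for d in range(n_decoy_families):
        source = source_cycle[d % 3]
        a = acc.next(source)
        decoys.append(a)
        fam_rows.append({
            "accession": a,
            "source_db": source,
            "name": f"decoy_{d}",
            "description": _DECOY_DESCRIPTIONS[d % len(_DECOY_DESCRIPTIONS)],
        })

    if n_unreviewed_noise > 0 and len(cluster_specs) >= 2:
        for _ in range(n_unreviewed_noise):
            i, j = rng.choice(len(cluster_specs), size=2, replace=False)
            a = sorted(true_clusters[cluster_specs[i].cluster_id])[0]
            b = sorted(true_clusters[cluster_specs[j].cluster_id])[0]
            xref_n += 1
            xrefs.append(XrefEntry(f"X{xref_n:05d}", frozenset({a, b}), reviewed=False))

    families = pd.DataFrame(fam_rows, columns=["accession", "source_db", "name", "description"])
    if families["accession"].duplicated().any():
        raise RuntimeError("generated duplicate accessions")

    truth = GroundTruth(
        true_clusters=true_clusters,
        hub_families=frozenset(hubs),
        true_candidates=frozenset(m for v in true_clusters.values() for m in v) | frozenset(hubs),
        cluster_specs=list(cluster_specs),
        decoy_families=frozenset(decoys),
    )
    sources = AnnotationSource(tigr_roles=tigr_roles, go_map=go_map, overrides={})
    return ReferenceData(families, xrefs, operons, sources, truth)


def random_cluster_specs(n: int, seed: int = 0, max_families: int = 5) -> list[ClusterSpec]:
    """Random cluster specs with field-plausible class frequencies."""
    rng = np.random.default_rng(seed)
    classes = ("importer", "exporter_utility", "exporter_toxin", "metal", "other")
    weights = (0.5, 0.2, 0.15, 0.08, 0.07)
    specs = []
    for i in range(n):
        klass = classes[rng.choice(len(classes), p=weights)]
        sec = str(rng.choice(SECRETION_TYPES)) if klass == "exporter_toxin" else None
        specs.append(ClusterSpec(
            cluster_id=f"PC{i:04d}",
            n_families=int(rng.integers(1, max_families + 1)),
            substrate_category=str(rng.choice(SUBSTRATE_CATEGORIES)),
            transport_class=klass,
            secretion_type=sec,
        ))
    return specs


# ---------------------------------------------------------------------------
# community-side generation

ENV_BASELINES = {
    "temperature": 10.0,   # °C
    "salinity": 7.0,       # PSU
    "chla": 2.0,           # µg L⁻¹
    "doc": 350.0,          # µmol C L⁻¹
    "nh4": 0.5,            # µmol L⁻¹
    "no3": 2.0,            # µmol L⁻¹
    "po4": 0.3,            # µmol L⁻¹
    "sio4": 10.0,          # µmol L⁻¹
    "totn": 20.0,          # µmol L⁻¹
}


def _default_dates(spec: CommunitySpec) -> tuple[list[pd.Timestamp], list[pd.Timestamp]]:
    if spec.sample_dates_mg is not None:
        mg = [pd.Timestamp(d) for d in spec.sample_dates_mg]
    else:
        mg = list(pd.date_range("2012-03-15", periods=spec.n_samples_mg, freq="9D"))
    if spec.sample_dates_mt is not None:
        mt = [pd.Timestamp(d) for d in spec.sample_dates_mt]
    else:
        # four dates sampled in both datasets (mid-May, mid-June,
        # mid-August, late December), the rest monthly in later years
        matched = [mg[i] for i in (7, 10, 17, 31) if i < len(mg)]
        mt = matched[: spec.n_samples_mt]
        extra = spec.n_samples_mt - len(mt)
        if extra > 0:
            mt += list(pd.date_range("2013-01-15", periods=extra, freq="30D"))
        mt.sort()
    return mg, mt


def simulate_community(
    spec: CommunitySpec,
    truth: GroundTruth,
    seed: int = 0,
) -> CommunityData:
    """Generate the ORF catalogue, MG/MT counts, samples and environment.

    Expected per-sample relative abundance of taxon t is proportional to
    ``amplitude_t * exp(-(day - peak_day_t)^2 / (2 * peak_width_t^2))``
    (day of year); within a taxon it is split across substrate categories
    by the taxon's profile and evenly across the clusters of each
    category. Counts are multinomial draws of size ``depth`` with ORF
    inclusion probability proportional to abundance x ORF length (so TPM,
    not raw proportions, recovers the planted composition). Decoy ORFs
    jointly carry a season-constant read mass (see
    :class:`CommunitySpec`). MT counts come from the same composition
    (optionally scaled per taxon by ``mt_expression``) with independent
    sampling noise.

    The planted ORF assignments and the expected MG composition tensor are
    recorded on ``truth``.
    """
    rng = np.random.default_rng(seed)
    by_category: dict[str, list[ClusterSpec]] = {}
    for cs in truth.cluster_specs:
        by_category.setdefault(cs.substrate_category, []).append(cs)

    lo, hi = spec.orf_length_range
    orf_rows: list[dict] = []
    orf_taxon_idx: list[int] = []
    orf_base: list[float] = []     # time-independent within-taxon weight
    orf_counter = 0
    contig_counter = 0
    orf_to_cluster: dict[str, str] = {}
    orf_to_taxon: dict[str, str] = {}

    for ti, taxon in enumerate(spec.taxa):
        taxon_orfs: list[dict] = []
        for category in SUBSTRATE_CATEGORIES:
            p_cat = taxon.substrate_profile.get(category, 0.0)
            if p_cat <= 0:
                continue
            clusters = by_category.get(category)
            if not clusters:
                raise ValueError(
                    f"profile of {taxon.label} needs category {category!r} "
                    "but no planted cluster carries it"
                )
            for cs in clusters:
                members = sorted(truth.true_clusters[cs.cluster_id])
                m = spec.orfs_per_cluster_per_taxon
                base = p_cat / (len(clusters) * m)
                for _ in range(m):
                    orf_counter += 1
                    orf_id = f"orf{orf_counter:06d}"
                    taxon_orfs.append({
                        "orf_id": orf_id,
                        "length": int(rng.integers(lo, hi + 1)),
                        "family_hits": frozenset({members[int(rng.integers(len(members)))]}),
                        "taxonomy_hit": taxon.taxon_path,
                    })
                    orf_taxon_idx.append(ti)
                    orf_base.append(base)
                    orf_to_cluster[orf_id] = cs.cluster_id
                    orf_to_taxon[orf_id] = taxon.label
        # chunk the taxon's ORFs onto contigs
        for c0 in range(0, len(taxon_orfs), spec.contig_size):
            contig_counter += 1
            for row in taxon_orfs[c0: c0 + spec.contig_size]:
                row["contig_id"] = f"ctg{contig_counter:05d}"
        orf_rows.extend(taxon_orfs)

    n_trans = len(orf_rows)
    n_decoy = 0
    if spec.decoy_fraction > 0:
        if not truth.decoy_families:
            raise ValueError("decoy_fraction > 0 but the reference has no decoy families")
        n_decoy = max(1, round(spec.decoy_fraction / (1 - spec.decoy_fraction) * n_trans))
        decoy_fams = sorted(truth.decoy_families)
        for d in range(n_decoy):
            orf_counter += 1
            taxon = spec.taxa[d % len(spec.taxa)]
            if d % spec.contig_size == 0:
                contig_counter += 1
            orf_rows.append({
                "orf_id": f"orf{orf_counter:06d}",
                "contig_id": f"ctg{contig_counter:05d}",
                "length": int(rng.integers(lo, hi + 1)),
                "family_hits": frozenset({decoy_fams[int(rng.integers(len(decoy_fams)))]}),
                "taxonomy_hit": taxon.taxon_path,
            })

    orfs = pd.DataFrame(orf_rows, columns=[
        "orf_id", "contig_id", "length", "family_hits", "taxonomy_hit",
    ])
    lengths = orfs["length"].to_numpy(dtype=float)
    taxon_idx = np.array(orf_taxon_idx)
    base = np.array(orf_base)

    mg_dates, mt_dates = _default_dates(spec)
    mg_ids = [f"MG{i + 1:02d}" for i in range(len(mg_dates))]
    mt_ids = [f"MT{i + 1:02d}" for i in range(len(mt_dates))]

    def draw_counts(dates: list[pd.Timestamp], ids: list[str],
                    taxon_scale: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
        weights = np.zeros((len(spec.taxa), len(dates)))
        abund = np.zeros((len(orfs), len(dates)))
        for si, date in enumerate(dates):
            doy = date.dayofyear
            w = np.array([t.weight(doy) for t in spec.taxa]) * taxon_scale
            weights[:, si] = w
            abund[:n_trans, si] = w[taxon_idx] * base
        if n_decoy:
            # season-constant background tied to the peak transporter mass
            peak_mass = abund[:n_trans].sum(axis=0).max()
            abund[n_trans:, :] = spec.background_weight * peak_mass / n_decoy
        cols = {}
        for si, sid in enumerate(ids):
            p = abund[:, si] * lengths
            p /= p.sum()
            cols[sid] = rng.multinomial(spec.depth, p)
        counts = pd.DataFrame(cols, index=orfs["orf_id"])
        return counts, weights

    ones = np.ones(len(spec.taxa))
    counts_mg, w_mg = draw_counts(mg_dates, mg_ids, ones)
    mt_scale = np.array([spec.mt_expression.get(t.label, 1.0) for t in spec.taxa])
    counts_mt, _ = draw_counts(mt_dates, mt_ids, mt_scale)

    samples = pd.DataFrame(
        [{"sample_id": s, "date": d, "dataset": "MG"} for s, d in zip(mg_ids, mg_dates)]
        + [{"sample_id": s, "date": d, "dataset": "MT"} for s, d in zip(mt_ids, mt_dates)]
    )

    # expected MG composition tensor (transporter mass only, normalized per sample)
    rows = {}
    w_totals = w_mg.sum(axis=0)
    for ti, taxon in enumerate(spec.taxa):
        for category in SUBSTRATE_CATEGORIES:
            p_cat = taxon.substrate_profile.get(category, 0.0)
            if p_cat <= 0:
                continue
            rows[(taxon.label, category)] = w_mg[ti] * p_cat / w_totals
    expected = pd.DataFrame.from_dict(rows, orient="index", columns=mg_ids)
    expected.index = pd.MultiIndex.from_tuples(expected.index, names=["taxon", "category"])
    expected = expected.sort_index()

    # environment table (MG dates)
    env_cols = {}
    label_to_idx = {t.label: i for i, t in enumerate(spec.taxa)}
    for var, baseline in ENV_BASELINES.items():
        if var in spec.env_link:
            taxon_label, sign = spec.env_link[var]
            w = w_mg[label_to_idx[taxon_label]]
            wnorm = w / w.max() if w.max() > 0 else w
            values = baseline * (1 + sign * 0.8 * wnorm) \
                + rng.normal(0, 0.02 * baseline, len(mg_ids))
        else:
            values = baseline * (1 + rng.normal(0, 0.05, len(mg_ids)))
        env_cols[var] = values
    env = pd.DataFrame(env_cols, index=pd.Index(mg_ids, name="sample_id"))

    truth.orf_to_cluster = orf_to_cluster
    truth.orf_to_taxon = orf_to_taxon
    truth.expected_composition = expected
    return CommunityData(orfs, counts_mg, counts_mt, samples, env, truth)


# ---------------------------------------------------------------------------
# default study design

def default_reference_specs() -> list[ClusterSpec]:
    """Planted reference: two importer clusters per substrate category plus
    a small complement of exporter/metal/other clusters."""
    specs = []
    i = 0
    for category in SUBSTRATE_CATEGORIES:
        for size in (2, 3):
            i += 1
            specs.append(ClusterSpec(f"PC{i:04d}", size, category, "importer"))
    for category in ("anion", "cation", "carbohydrate"):
        i += 1
        specs.append(ClusterSpec(f"PC{i:04d}", 2, category, "exporter_utility"))
    for sec in ("T2", "T5"):
        i += 1
        specs.append(ClusterSpec(f"PC{i:04d}", 2, "anion", "exporter_toxin", secretion_type=sec))
    i += 1
    specs.append(ClusterSpec(f"PC{i:04d}", 2, "cation", "metal"))
    i += 1
    specs.append(ClusterSpec(f"PC{i:04d}", 1, "anion", "other"))
    return specs


_P = "amino_acids_peptides_ammonium"

#: Seven-order community: Gaussian peaks tracing the observed spring→autumn
#: succession and per-order substrate profiles matching the reported means
#: (e.g. Flavobacteriales 50% cations / 27% AA-peptides).
DEFAULT_TAXA: tuple[TaxonSpec, ...] = (
    TaxonSpec(("Bacteria", "Bacteroidetes", "Flavobacteriia", "Flavobacteriales"),
              100, 20, 1.0,
              {_P: .27, "carbohydrate": .08, "nucleoside": .03, "anion": .04,
               "cation": .50, "nitrate": .01, "urea": .01, "phosphate": .04,
               "phosphonate": .02}),
    TaxonSpec(("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhodobacterales"),
              120, 25, 0.8,
              {_P: .19, "carbohydrate": .36, "nucleoside": .02, "anion": .02,
               "cation": .18, "nitrate": .01, "urea": .01, "phosphate": .02,
               "phosphonate": .19}),
    TaxonSpec(("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Cellvibrionales"),
              160, 25, 0.7,
              {_P: .27, "carbohydrate": .15, "nucleoside": .04, "anion": .26,
               "cation": .15, "nitrate": .02, "urea": .01, "phosphate": .07,
               "phosphonate": .03}),
    TaxonSpec(("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales"),
              180, 25, 0.65,
              {_P: .08, "carbohydrate": .39, "nucleoside": .04, "anion": .08,
               "cation": .18, "nitrate": .04, "urea": .03, "phosphate": .07,
               "phosphonate": .09}),
    TaxonSpec(("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Pelagibacterales"),
              205, 55, 0.6,
              {_P: .25, "carbohydrate": .10, "nucleoside": .03, "anion": .05,
               "cation": .10, "nitrate": .23, "urea": .02, "phosphate": .15,
               "phosphonate": .07}),
    TaxonSpec(("Bacteria", "Bacteroidetes", "Sphingobacteriia", "Sphingobacteriales"),
              225, 20, 0.9,
              {_P: .12, "carbohydrate": .06, "nucleoside": .03, "anion": .04,
               "cation": .70, "nitrate": .01, "urea": .005, "phosphate": .03,
               "phosphonate": .005}),
    TaxonSpec(("Eukaryota", "Chlorophyta", "Mamiellophyceae", "Mamiellales"),
              290, 30, 0.5,
              {_P: .15, "carbohydrate": .15, "nucleoside": .03, "anion": .25,
               "cation": .20, "nitrate": .07, "urea": .04, "phosphate": .08,
               "phosphonate": .03}),
)

#: Environmental covariates tied to taxon trajectories: the spring bloom
#: (chlorophyll) tracks Flavobacteriales, late-summer temperature tracks
#: Sphingobacteriales, and phosphate is drawn down against it.
DEFAULT_ENV_LINK: dict[str, tuple[str, int]] = {
    "chla": ("Flavobacteriales", +1),
    "temperature": ("Sphingobacteriales", +1),
    "po4": ("Sphingobacteriales", -1),
}


def default_community(**overrides) -> CommunitySpec:
    """The default study design: 33 biweekly MG samples and 25 MT samples
    over seven orders with succession peaks and fixed substrate profiles."""
    kwargs = dict(
        taxa=list(DEFAULT_TAXA),
        env_link=dict(DEFAULT_ENV_LINK),
    )
    kwargs.update(overrides)
    return CommunitySpec(**kwargs)
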