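# Methods

This note records the models, conventions and open design choices behind
the package, at the level of detail a maintainer needs to change them
safely. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

The unit of biology is the **transport cluster**: the set of protein
families (PFAM/TIGRFAM/COG) that jointly make up one functional membrane
transporter, including all subunits. Clusters are derived from
co-annotation evidence — two candidate families are linked when a reviewed
protein cross-reference entry or an operon is annotated with both — on the
argument that subunits of one transporter are encoded and annotated
together. Connected components of this graph, after hub pruning, are the
clusters.

**Hub pruning.** Generic domains (ATP-binding cassettes and the like)
annotate many unrelated proteins and would fuse unrelated transporters
into one component. A family whose distinct-neighbour degree exceeds 6 is
removed. Three conventions matter:

* Degree counts *distinct neighbours*, not supporting records: an edge
  backed by fifty entries still counts once, because the graph's semantics
  is "unique pairwise combination".
* Pruning is a **single pass on input degrees** — a filter, not a fixed
  point. Removing one hub never rescues another whose degree only dropped
  because the first was removed. This makes the operation order-free and
  idempotent.
* Cross-reference and operon evidence are pooled into one graph before
  pruning; only reviewed cross-reference entries contribute.

Candidates with no surviving edges become singleton clusters: downstream
quantification requires every non-pruned candidate to map somewhere, and
the plausible cluster count in real data (over a thousand) can only be
reached if singletons count.

**Substrate annotation** resolves per cluster in a fixed order: curated
override → majority vote over member TIGRFAM-role hints → majority vote
over member GO hints → `unannotated` (excluded from every abundance
table). TIGRFAM precedence is the domain convention; the majority rule and
its tie-break (lexicographically smallest category, recorded with a
`tie_flag` so curators can audit) are this package's choices — the
upstream methodology resolved within-cluster conflicts by hand. Transport
classes come from ordered keyword rules over member descriptions:
metal → toxin-secretion → utility-export → importer → other. Metal ranks
first because metal-ion transporters are frequently bidirectional and are
kept out of both the importer and exporter groups; secretion outranks
generic efflux so that toxin machinery is not absorbed into utility
export. TCDB mechanism classes are taken from the override table only;
inferring them from text would be false precision.

**Quantification.** TPM with plain ORF nucleotide lengths (no
effective-length correction — counting is per-ORF on an assembly, not
isoform quantification). Columns with any reads sum to 10⁶ exactly;
zero-depth columns stay zero with a warning. An ORF with hits in several
clusters is assigned to exactly one — the cluster of its
highest-priority hit (TIGRFAM > COG > PFAM, then lexicographic
accession) — so cluster abundances partition the mapped TPM mass exactly.
The "abundant" filter is a strict `> 0.5%` of the per-dataset transporter
total in at least one sample, unioned over MG and MT; per-dataset
denominators because the two datasets are profiled separately.

**Taxonomy.** Contig LCA voting descends rank by rank and keeps the label
supported by a fraction strictly greater than `majority_fraction`
(default 0.5) of the ORFs classified at that rank, restricted to ORFs
consistent with the path so far; the first rank without such a label ends
the path. The upstream alignment-weighted voting details are out of scope;
this strict-majority stand-in is deliberately simple and configurable. A
consequence worth knowing: a 6-ORF contig with independent 20% order-level
mislabels is recovered exactly when ≥ 4 of 6 ORFs carry the true order,
i.e. with probability P(Bin(6, 0.8) ≥ 4) ≈ 0.901 — the strict rule cannot
do better, and the test suite pins the rate at that binomial value.
Unclassified abundance is kept in a dedicated bucket so that aggregation
is exactly conservative. In the domain grouping, Picoeukaryota is the
Eukaryota domain (this size fraction contains no larger eukaryotes) and
Cyanobacteria are split out of Bacteria by phylum label.

**Seasonal statistics.** Composition stability is the per-category s.d.
of a taxon's composition over samples, computed only in samples where the
taxon's total abundance exceeds a floor (avoids 0/0 compositions in
off-peak samples); the stability score is the worst category. MG–MT
coupling defaults to Pearson on per-sample relative abundances across the
dates present in both datasets (the correlation type is not fixed by the
source methodology; Spearman is an option), flagged at > 0.6. The
environment screen is Spearman on average-ranked data with pairwise
deletion of missing values; p-values use exact permutation enumeration for
n ≤ 8 and the t approximation with n − 2 df otherwise (33 samples make the
approximation adequate; small synthetic tests stay exact). The screen
passes on |ρ| by default — strong negative correlations are as
informative as positive ones — with a signed option, and applies no
multiple-testing correction by default (a Benjamini–Hochberg switch
exists). Succession peaks are the argmax over samples of a taxon's total
abundance, ties to the earlier date.

## The synthetic-data generator

The generator is the package's study design, not a test fixture.

*Reference side.* Planted clusters are connected by chains of reviewed
cross-reference entries and operons among their own members only (a
3-family entry seeds clusters of size ≥ 3, exercising the pairwise-edge
expansion); hubs are extra candidate families co-annotated with ≥ 7
partners interleaved across clusters; decoy family descriptions contain no
screen keyword, so screen truth is exact by construction. TIGRFAM-role
hints are emitted for every TIGRFAM member and GO hints for all members,
consistent with the planted categories, and member descriptions carry
class-consistent keywords — annotation recovery is therefore exact on
clean synthetic data, which is the point: failures isolate pipeline
defects, not label noise.

*Community side.* Taxon t's absolute trajectory is a Gaussian peak,
`w_t(d) = A_t · exp(−(d − day_t)² / (2 σ_t²))` in day-of-year d — the
simplest unimodal shape matching observed single-season order-level
peaks. Within a taxon, mass splits across substrate categories by a fixed
profile (the central stability phenomenon is planted, so the pipeline
must *recover*, not create, it) and evenly across clusters of a category.
Reads are one multinomial draw of size `depth` per sample with ORF
probability ∝ abundance × length; ORF lengths are uniform on 300–3000 bp
so that TPM ≠ raw proportion and the length correction is actually
exercised. Decoy ORFs (a configurable fraction of the catalogue, default
20%) jointly carry a season-constant read mass of `background_weight`
(default 9) times the peak transporter mass. This background is what makes
TPM trajectories track the *absolute* planted Gaussians: sequencing
composition is closed, and without a stable non-transporter bulk the
transporter taxa would renormalize against each other and relative peaks
would shift away from the planted peak days. Real metagenomes have the
same structure — transporters are roughly 1% of ORFs — just with a larger
background than is economical to simulate.

The default community is seven orders whose peak days trace a
spring→autumn succession (days 100, 120, 160, 180, 205, 225, 290; peaks
separated by at least two sampling intervals so the succession order is
identifiable at the 9-day sampling resolution) and whose substrate
profiles reproduce the reported per-order means (e.g. Flavobacteriales
50% cations / 27% amino acids-peptides; Sphingobacteriales 70% cations;
Pelagibacterales 23% nitrate / 15% phosphate). Sampling is 33 MG samples
every 9 days from mid-March and 25 MT samples, four of them on MG dates
(mid-May, mid-June, mid-August, late December) and the rest monthly in
later years. MT counts are drawn from the same composition with
independent noise and optional per-taxon expression multipliers, so
MG–MT coupling is known. Environment variables are baselines with 2–5%
noise; a variable in `env_link` additionally follows (or opposes) its
linked taxon's normalized trajectory with ±80% amplitude.

*What the generator does not emulate* — and hence what passing tests do
not show about real data: read-level errors, assembly artefacts, chimeric
contigs, shared families between distinct real transporters, incomplete
or wrong database hints, correlated (non-multinomial) count overdispersion,
multi-year trends, and taxon profiles that actually drift over a season.
Recovery results bound pipeline correctness, not ecological inference
error on field data.

## Numerical conventions

* TPM columns: exact 10⁶ sums up to floating point; zero-depth columns are
  zeroed, never NaN.
* Quantiles (importer-richness visibility): linear-interpolation sample
  quantile, "greater or equal" comparison; the read filter is a strict
  `> 500` raw reads on the abundant set.
* Correlation degeneracies: zero-variance series yield missing
  coefficients, never 0; pairs with n < 3 are excluded.
* Exact permutation p-values enumerate all n! orderings of one rank
  vector (ties kept as a multiset) and are two-sided on |ρ| with a 1e-12
  comparison guard; cost caps at 8! = 40,320 per pair.
* Determinism: every stochastic routine takes a seed and uses an isolated
  `numpy` generator; identical seeds give byte-identical output tables.
  Cluster ids are canonicalized by smallest member accession, so record
  order never changes results.

## Problem sizes used in validation

The validation suite and the acceptance script use: 50-cluster references
(10 seeds) for exact screen/cluster recovery; a depth-10⁶, 33-sample
default community for profile recovery (multinomial s.e. per category well
under one percentage point at that depth) and TPM conservation; depth 10⁵
× 20 seeds for succession-order recovery; a depth-2×10⁵ two-taxon
community with disjoint substrate support for the environment screen
(disjoint support makes cluster→taxon attribution unambiguous, so "linked
pair" is well defined); 400 six-ORF contigs for the mislabel-voting rate;
and 200 random graphs (≤ 50 nodes) against an independent union-find
oracle.

## Known limitations

* The five default screen terms are a documented reduction of the fuller
  pattern used in production screens of real database releases; they
  cannot reproduce real-database candidate counts and are configurable.
* Single-cluster ORF assignment discards secondary hits; a real ORF with
  domains from two genuinely different transporters is counted once.
* The strict-majority LCA vote is a stand-in for alignment-weighted
  voting; its recovery ceiling under label noise is the binomial bound
  above.
* The curated override table replaces human literature curation;
  annotation quality on real data is bounded by that table's coverage.
* `mg_mt_correlation` over four matched dates has n = 4; coefficients are
  reported but confidence intervals at that n are essentially
  uninformative, which is why the flag is a plain threshold.
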