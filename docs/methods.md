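# Methods

## Data model and coordinate conventions

TE copies are intervals with a family (consensus) assignment and a
superfamily classification, stored 0-based half-open internally. The
RepeatMasker `.out` reader converts the tool's 1-based inclusive
coordinates and `C` strand code at the boundary, synthesises a unique
`genome:seq:start-end:strand:family#n` copy identifier (annotation tables
carry none), and excludes rows classified `Unknown`/`Unclassified` by
default (overridable), since unclassified repeats cannot be assigned to
family nodes. Overlapping or nested annotation rows are kept as distinct
copies; no merging is attempted.

Alignment hits are consumed in the standard 12-column tabular form;
self-hits are dropped at parse time. Domain hits use the HMMER per-domain
table; the e-value ceiling (default 1e-5, on the domain's independent
e-value) is a configurable choice of this package, not an upstream
constant, and is logged.

## Sequence-similarity network

Edges carry the best local-alignment bitscore for the unordered copy pair:
all hits between two copies, in both directions, collapse to the maximum.
The maximum is used because a bitscore is evidence of shared sequence and
the strongest local alignment is the least noisy summary; it is also
direction-independent, so the network does not depend on which copy was
query. Copies with no surviving hit stay in the network as isolated nodes
(both totals are reported). The default network applies no length or
e-value filter; a human-L1-style preset (minimum copy length 500 bp,
e-value ≤ 1e-30) is exposed through the same parameters.

Clustering is done two ways: connected components, and Louvain modularity
maximisation on edge weights at resolution 1. Louvain is randomised by
nature, so the implementation is seeded (default 0) and deterministic for a
fixed seed; the reported modularity accompanies each partition. Partition
agreement is quantified by the Rand index — the fraction of node pairs that
are together in both partitions or apart in both — computed from the
cluster contingency table. Because every Louvain community lies inside one
connected component, the Louvain-vs-components Rand index measures
sub-partitioning only.

"Connectivity" in the catalytic-domain comparison is the unweighted degree
by default, with weighted degree behind a flag; the choice is an
interpretation of an ambiguous term and both are available. Enrichment of a
boolean node flag inside one cluster uses a two-sided Fisher exact test on
the 2×2 in/out × flagged/unflagged table — the natural exact test for small
clusters. Cluster persistence after masking-and-rebuilding is the Jaccard
overlap with the best-matching rebuilt cluster, with "persists" defined as
overlap ≥ 0.5 (configurable; the threshold is a definition, not an
inference).

## Bipartite content network

Weights per (genome g, family f): copy count; total bp Σ length; percent of
genome 100·Σ/genome_size; percent of TE content 100·Σ/(total TE bp of g).
Node membership is metric-invariant — only weights change — which is
asserted when metrics are compared (again via Louvain partitions of the
genome nodes and the Rand index; the clustering method is a flag).
Singletons are TE nodes of total degree 1, counted on the family side
regardless of metric.

Perturbation profiles (family or superfamily knockout, and repeated random
removal of a fraction of a family's nodes) recompute a fixed statistic set —
node count, edge count, Louvain cluster count, modularity, component count,
and the genome-partition Rand index against baseline — with identical
clustering parameters and seed before and after. Knockout is the exact
set-difference network: rebuilding from filtered copies equals removing the
nodes (for the non-renormalising metrics; the percent-of-TE metric
re-normalises by construction).

Group comparisons (PIWI+/−, DNMT+/−) use the two-sided Wilcoxon rank-sum
test: exact enumeration when the smaller group has ≤ 25 tie-free
observations, tie-corrected normal approximation (with continuity
correction) otherwise; which route ran is recorded in the result. The
paired bootstrap comparisons use the signed-rank variant for the same
sample-size policy at n ≤ 20. No multiple-testing correction is applied;
reported p-values are per-comparison.

## Orthonetwork and collapse

Genome–TE weights use `LengthAdj = log(bp)/log(max bp)`; the normaliser is
the maximum per-genome family total over **all** genome–family edges
(global maximum) by default, which keeps every weight in (0, 1] with
equality at the argmax edge; a per-family maximum is available as an
option since the scope of the normaliser is a genuine design choice. The
log ratio is base-invariant (asserted numerically). Totals of ≤ 1 bp are
rejected rather than silently producing non-positive weights.

Genome–genome edges exist only for pairs sharing at least τ orthogroups
(default 4,500) and are weighted by count divided by the maximum count
among retained pairs, putting both edge types on a common (0, 1] scale.
Raising τ is monotone: it only removes edges.

Collapsing runs Louvain on the full mixed graph (same seed/resolution
conventions as the SSN); each cluster containing genomes becomes a group
node whose degree counts distinct incident families, whose weighted degree
sums members' TE-edge weights, and whose singletons are families incident
to no genome outside the group. Silencing labels are majority votes with
the within-group agreement fraction recorded, because arbitrary inputs can
produce mixed groups even though coherent clades are the expected case.
Group-level comparisons treat each group as one observation.

## Activity classification and bootstrap

A TE is potentially active when any of six transposition-associated Pfam
domains is found: DDE_1 (PF03184), DDE_2 (PF02914), DDE_3 (PF13358),
retrotransposon gag (PF03732), integrase core (PF00665), retroviral
aspartyl protease (PF00077); otherwise inactive. The whitelist is
configurable. Family-level activity is the OR over the family's copies.

The singleton bootstrap resamples a fixed number of genomes (default 30)
from one silencing group, compares active vs inactive singleton counts
within the resample, and repeats (default 1,000×), returning the full
p-value distribution. The comparison is paired (signed-rank) by default
because both counts come from the same genome; an unpaired flag switches to
rank-sum. Groups smaller than the sample size are resampled with
replacement, with a warning.

## Synthetic landscapes

The generator emulates the statistical structure the pipeline detects, not
sequences; similarity is modelled at the hit level. Defaults describe the
study conditions used throughout the tests:

* 40 species in 4 clades; PIWI and DNMT regimes assigned per clade on an
  alternating grid so the two mechanisms are near-orthogonal.
* Family richness and copies per family are 1-truncated Poisson
  (`1 + Poisson(mean − 1)`, mean exact): baseline 12 families/species and
  8 copies/family. PIWI+ species get richness ×2 and copies ×0.5, so
  expected total content is matched between regimes — the planted signal is
  the degree vs weighted-degree dissociation, not a content confound.
* 30% of a species' families are private (singletons); DNMT+ species gain
  on average 4 extra inactive private families of ~2 copies.
* Copy lengths are log-normal (meanlog 6.6, sdlog 0.5, ≈735 bp median,
  clipped at 50 bp); shared-orthogroup counts are Gaussian around 8,000
  within clades and 2,000 between (sd 200), so the default τ=4,500
  separates clades cleanly.
* Hits: within-family pairs connect with probability 0.8 at bitscores
  ~N(450, 40); between-family hits are off by default. A planted convergent
  pair adds cross-family hits at ~N(150, 20) with probability 0.6 — strong
  enough that Louvain merges the two families into one mixed cluster, weak
  enough that the within-family mean stays dominant (enforced:
  within > convergent > 0). "Recently active" families connect completely
  at boosted bitscores and emit PF13358 domain hits. Horizontal transfer
  plants copies of a donor family in a recipient genome; family identity
  drives their subsequent similarity.

All generators are pure functions of (config, seed) — superfamily
assignment uses a CRC32 of the family name rather than Python's randomised
`hash` — and the planted truth (family kinds, activity, clade map, regimes)
is returned with the data.

What the generator does *not* model: sequence-level divergence and
alignment artefacts, overlapping/nested annotations, copy-number variation
within families across a clade, unequal genome sizes, and correlated loss
of the two silencing pathways. Passing tests therefore demonstrate that the
pipeline recovers the planted statistical structure, not that real genomes
contain it.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scales chosen to
exercise every code path: SSNs of ~50–260 copies (6–8 families), content
networks of 8–40 species, 20-seed detection experiments, 100-seed power
studies. Exact-test crossovers (rank-sum n ≤ 25, signed-rank n ≤ 20) keep
small-sample behaviour enumeration-exact and deterministic. Ties fall back
to the corrected normal approximation. Degenerate inputs are defined
explicitly: empty networks give empty partitions, single-node partitions
have Rand index 1, all-identical samples give p = 1, all-zero paired
differences give p = 1 with a warning.

## Known limitations

* Louvain is a heuristic; recovery guarantees hold for the planted regimes
  tested (weight ratio ≥ 10), not adversarial graphs.
* The orthonetwork mixes two weight scales that are individually normalised
  to (0, 1] but not calibrated against each other; cluster granularity
  therefore depends on the relative density of TE and ortholog edges.
* Family names are assumed harmonised across genomes by a shared consensus
  library; no cross-genome family matching is performed.
* The CLI consumes precomputed alignment and domain tables; it does not run
  the annotation or search tools.
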