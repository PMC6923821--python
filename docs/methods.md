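# Methods

## Pipeline overview

`microsplit` integrates two layers of evidence about a microbial community
into one graph object. Per sample group (e.g. Crohn's disease tissue CDT,
Crohn's disease stool CDS, healthy-control stool HCS):

1. taxa × taxa Spearman correlation with BH-FDR → co-occurrence network;
2. taxa × KO Spearman correlation with BH-FDR → KO links, aggregated per
   KEGG module into a density score;
3. both layers assembled into a split graph; weighted maximal cliques
   extracted and ranked;
4. networks of two groups compared by the fraction of edges sharing a
   taxonomic ancestor (pooled two-proportion z-test).

## Correlation stage

Spearman ρ is computed as the Pearson correlation of average ranks (the
standard tie treatment). The two-sided p-value uses the t approximation
t = ρ√((n−2)/(1−ρ²)) with n−2 degrees of freedom; |ρ| = 1 maps to p = 0. An
exact permutation p-value is available for very small groups (n ≤ 8), where
the t approximation is crudest; it enumerates all n! pairings.

The BH family is **all pairs tested in one call** — one group × one rank
analysis. Families are not pooled across groups, because each group's
network is built and interpreted separately. Pairs involving a feature
constant across the group's samples have undefined rank correlation; they
are reported with ρ = NaN and excluded from the family (count logged).

Thresholding is strict, `|ρ| > 0.6` and `q < 0.05`, with the sign retained
on kept edges. The absolute value is deliberate: strong negative
co-exclusions are biologically informative and published association tables
include negative edges under the same rule. `keep_negative=False` restores
a positive-only network.

Correlations run on whatever abundance scale is supplied. Spearman is
invariant to monotone per-feature transforms but **not** to per-sample
renormalization, so an optional relative-abundance flag exists and defaults
to off; whether tables should be rarefied or renormalized first is left to
the user.

## Density stage

For taxon B and module M with KO membership from a static two-column
module map (standing in for a live KEGG lookup),

    density(B, M) = |{KOs of M linked to B}| / |M|.

A KO counts as linked regardless of the sign of its correlation. Density is
kept at full precision internally (`density_exact` is the exact rational)
and displayed at 2 decimals, matching the convention of published tables.

Two boundary decisions, both configurable:

- The upstream text describing the taxon–KO step contains an adjusted
  p-value direction that contradicts every other stage and its own result
  tables; the implemented rule is q < 0.05 throughout.
- The cross-edge threshold is `density ≥ 0.6` by default (`cmp="ge"`),
  not strict `>`: published association tables retain rows printed at
  exactly 0.60, so the non-strict boundary reproduces their semantics.
  `cmp="gt"` gives the strict reading.

One published table row (7 KOs, density 0.89) is arithmetically
inconsistent with its sibling row (6 KOs, 0.67 ⇒ module size 9, while
7/9 = 0.78): with 8 correlated KOs the density would be 0.89, so that row
likely omits one KO. The worked-example tests pin only the
arithmetically consistent rows.

## Split graph and cliques

The split graph keeps taxa and modules as disjoint node sets; clique edges
carry ρ (sign kept as an attribute, magnitude used as weight) and cross
edges carry density. Module–module edges are impossible by construction and
re-checked by validation. Taxa that appear only in density associations are
retained as isolated taxon nodes.

Maximal cliques are enumerated with networkx's pivoting Bron–Kerbosch on
the full mixed graph; the independent module side guarantees at most one
module per clique without special casing. Singleton cliques are suppressed.
Because "high-weighted" has no canonical definition, the clique weight is a
configurable aggregate — sum (default; favors larger informative
components) or mean (scale-free) — of the internal |ρ| values plus the
densities of the cross edges to the attached module. Ties break by clique
size (descending) then lexicographic taxa, so rankings are deterministic.

Two granularities exist because a taxa-only clique can be maximal among
taxa yet extendable by a module node: the default reports mixed-maximal
cliques, and `include_taxa_only=True` adds taxa-side maximal cliques
flagged `taxa_only`. A relaxed attachment mode (`module_attachment="any"`,
module adjacent to ≥ 1 clique member) is exposed behind a flag but not
defaulted; strict completeness is the model's defining property.

GraphML export writes `node_class`, `edge_class`, `weight`, `rho_sign` and
top-k clique memberships, and is importable by Cytoscape or any GraphML
reader.

## Shared-ancestor proportion test

For a network and rank r: n counts edges whose both endpoints have rank r
assigned, x those whose values agree. Edges touching the `unassigned`
aggregation sentinel (or any endpoint without the rank) are excluded from
both counts — an unconfirmed lineage cannot witness a common ancestor; an
include-flag on the aggregation side controls whether the sentinel feature
exists at all.

The z statistic is the pooled two-proportion form, two-sided against the
standard normal, with no continuity correction (the alternative direction
is not prescribed upstream, so two-sided is the conservative choice).
Degenerate pools (x₁+x₂ ∈ {0, n₁+n₂}) report z = 0, p = 1 with a flag
rather than dividing by zero. Significance stars (*** < 0.001, ** < 0.01,
* < 0.05, ns) are annotations only; no multiplicity correction is applied
across ranks. The TSV report always includes the underlying counts so any
p-value can be re-derived.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with planted, machine-readable ground truth:

- **Taxa.** log-abundance = Σ s_b·F_b + √(max(0, 1−Σs_b²))·ε + σ·η with
  F_b the shared factor of planted block b (strength s_b ∈ [0,1]), ε, η
  standard normal, σ = `noise_sd`. Abundances are the exponential —
  log-normal marginals, the standard shape for microbiome abundances. Two
  members of a block at strength s have Pearson log-correlation
  ≈ s²/(1+σ²); at the default s = 0.95, σ = 0.1 that is ≈ 0.89, safely
  above the 0.6 retention threshold at n = 30.
- **KOs.** A planted coupling (taxon, module, fraction f) drives the first
  f·|M| KOs of the module (sorted order, so deterministic) as the taxon's
  log-abundance plus σ noise — a strictly monotone link, so Spearman
  recovery is exact in the noiseless limit. Undriven KOs are independent
  log-normals. A fraction whose product with the module size is not a
  whole number of KOs is a configuration error with an explanation.
- **Lineages.** By default each block's members share a family (and order,
  class), solo taxa get unique families, and phyla cycle over four names —
  enough structure to exercise aggregation and the ancestor test. A custom
  per-taxon lineage plan can be supplied.
- **Groups.** Default sizes mirror a tissue/stool case-control design
  (36 CDT, 10 CDS, 9 HCS); all groups share the planted structure and
  differ only in their sampled noise.

Identical configs (including the seed) give bit-identical outputs. The
ground-truth record (planted edges, resolved driven-KO sets, fractions) is
emitted alongside the TSVs as JSON.

What the generator does **not** emulate: compositional closure, sequencing
depth variation and rarefaction, zero inflation, and phylogenetically
correlated KO content across related taxa. Passing recovery tests on this
generator therefore demonstrates the pipeline's correctness on its own
modeling assumptions, not robustness to compositional artifacts on real
surveys.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately small problems — 20 taxa,
50 KOs over 10 five-KO modules, 30 samples per group, 20 seeds for
recovery, 100–200 replicates for null calibration — sizes at which planted
effects at strength 0.95 / noise 0.1 are comfortably detectable and the
whole suite completes in seconds. Brute-force clique oracles run on graphs
of ≤ 12 nodes, where exhaustive subset enumeration is exact and cheap.

Other numerical details: BH adjustment via statsmodels; rank ties averaged;
ρ clipped to [−1, 1] before p-value computation; TSV round-trips use
17-significant-digit floats with pandas' round-trip parser; canonical
(lexicographic) edge endpoint ordering makes networks independent of input
order.

## Known limitations

- The t-approximation p-value is anticonservative for very small groups;
  the exact permutation option covers n ≤ 8 only.
- Density weights all KOs of a module equally; no KO-importance weighting.
- The ancestor test conditions on the edges present in each network and
  treats them as independent draws, as the underlying test assumes;
  overlapping clique structure violates independence in ways the z-test
  does not model.
- No compositional correction (SparCC/SpiecEasi-style) — by design, this
  package implements the plain Spearman pipeline.
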