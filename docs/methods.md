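# Methods

This note records the statistical conventions, numerical choices and known
limitations of the micropheno engine, in the order data flows through it.

## Data model

A study holds samples, relative-abundance matrices at the five ranks
phylum–genus, a typed parameter set, and caches of alpha diversity and
pairwise dissimilarities. Sample identity is a caller-supplied opaque
string; the abundance and parameter files are joined by exact string match,
with no normalization, since the two-file contract presumes shared ids.
Samples appearing only in the parameter file are kept (they remain
browsable) but flagged `no_microbiome` and excluded from every analysis;
conversely, a sample with abundances but no parameters is analyzable — it
participates in composition, diversity and ordination, just not in
correlation. Validation is a report, never an exception: hard invariant
violations (row sums, undefined parameter names, malformed caches) are
ERRORs, data-quality observations (unclassified taxa, unknown
category/subgroup pairs, flagged samples) are WARNs.

Parameters are typed `continuous`, `nominal`, `ordinal` or `text` and
stored as (sample, name, value) records — missing pairs mean *not
measured*, and nothing is ever imputed. `text` parameters are browsable
only and are rejected by every correlation operation. `nominal` parameters
may color a PCoA plot or define groups but are never correlation targets.
`ordinal` values are stored numerically; by default they are excluded from
correlation, and may opt in under Spearman only, where only the ordering is
used. Pearson on ordinal codes would treat arbitrary level spacing as
metric information, so it is not offered.

## Ingest

Abundance tables may hold counts or fractions; if every row sums to
1 ± 0.01 the table is treated as fractions, otherwise as counts, and the
choice can be forced. Counts are normalized per sample; the raw integers
are retained because Chao1 is undefined on fractions. Lineage headers split
on `;`; empty fields become `unclassified` placeholders at their rank,
parented through the chain, so every taxon reaches phylum and rollup is
total. Unresolvable names are flagged, never dropped.

Imported distance matrices are symmetrized by averaging (D + Dᵀ)/2, with a
warning when the maximum asymmetry exceeds 1e-8; negative entries and
nonzero diagonals are rejected outright, since no dissimilarity
interpretation survives them.

The store is a single SQLite file with tables `samples`, `taxa`,
`abundances`, `parameter_defs`, `parameter_values`, `distances`,
`diversity` — the parameter tables use the name–value design so cohorts
with arbitrary parameter sets share one schema. REAL columns are IEEE
doubles, so numeric round-trips are bit-exact; TSV export uses `%.17g`,
which also round-trips doubles exactly. A store written by a different
schema version is refused with both versions named, and saving a study
whose validation report has ERRORs is refused.

## Pre-processing

**Rollup** sums genus columns into their ancestors at the target rank;
only same-row additions occur, so row sums are preserved to machine
precision and drill-down views at different ranks are mutually consistent.

**Dominant-taxon collapsing.** The display rule "merge low-abundance taxa
into `others`, kept below a threshold" admits two readings: merge every
taxon individually below the threshold, or keep the *total* of `others`
below it. The engine implements the second — taxa are taken from the
smallest mean abundance upward and merged greedily while the mean of
`others` stays strictly below the threshold (default 0.10) — because it is
what "the others category … always set to be below a specific threshold"
denotes, and it guarantees the residual slice never dominates a chart. The
default scope is global (one shared legend across samples); `per_sample`
applies the same greedy rule per row for users who prefer the alternative
reading. Retained taxa keep their exact values; an `others` column is
always appended, possibly zero.

**Alpha diversity.** Shannon uses the natural log by default (a `base`
option gives log₂/log₁₀ conventions), Simpson is reported as the
Gini–Simpson complement 1 − Σpᵢ² so that larger means more diverse (the raw
dominance Σpᵢ² is an option), and Chao1 defaults to the bias-corrected
estimator S_obs + F₁(F₁−1)/(2(F₂+1)), which unlike the classical
F₁²/(2F₂) form is defined when doubletons are absent; the classical form
is available and errors when F₂ = 0. Chao1 requires integer counts and
errors otherwise — it estimates unseen species from singleton/doubleton
frequencies, which relative abundances destroy.

## Dissimilarity

Bray–Curtis is computed on relative abundances by default (a counts mode
exists); Jaccard uses strict presence (> 0) with no detection-limit
epsilon, zero being the only default defensible without assay metadata.
Native UniFrac walks the rooted tree once in postorder, accumulating the
abundance mass descending through each branch: unweighted is the fraction
of branch length leading to leaves present in exactly one sample among
branches present in either; weighted is Σ b·|p_x(b) − p_y(b)| in the raw
(unnormalized) form. Both match scikit-bio's implementations to 1e-9 on
random trees (tested). UniFrac is optional — the engine is self-contained
on Jaccard/Bray–Curtis, and externally computed matrices can be imported.

## Ordination and clustering

PCoA double-centers the squared dissimilarities (B = −½ J D⁽²⁾ J) and
eigendecomposes with a symmetric solver. Eigenvalues within 1e-9 (relative)
of zero are snapped to zero. Non-Euclidean inputs such as Bray–Curtis
produce negative eigenvalues; they are reported in the full spectrum,
surfaced in the HTML report, and excluded from the variance-explained
denominator, which sums positive eigenvalues only — the convention under
which per-axis percentages remain well defined. No correction is applied by
default; the Lingoes additive correction is available via flag. Axis signs
are fixed by making each axis's largest-magnitude coordinate positive, so
output is bit-reproducible.

Clustering is the plain O(n³) agglomerative scheme with single (minimum),
complete (maximum) and average linkage; average is UPGMA, the unweighted
mean over all cross pairs (WPGMA is not offered). Ties in the minimal
inter-cluster distance are broken by the lexicographically smallest node-id
pair. Leaf order places, at each internal node, the child cluster created
earlier in the merge sequence on the left; a leaf child goes right of a
merged cluster, and two leaf children are ordered by sample id. This makes
the order deterministic and invariant to the input sample permutation when
merge heights are distinct, so bar charts and heat maps sorted "by
dendrogram" are stable across runs.

## Correlation search

Coefficients are computed over pairwise-complete samples (per-pair deletion
of missing values). Spearman is Pearson applied to midranks, so ties are
handled by average ranks. A result needs n ≥ 3 and nonzero variance on
both sides; anything else is excluded from the table and counted with its
reason, and defined results with n < 10 carry a `low_n` flag. Tables are
sorted by coefficient in descending order (toggleable), with top-N
positive/negative views. The parameter-vs-taxa search runs on the
pre-collapse matrix — minor taxa included, the synthetic `others` excluded,
since `others` is a display artifact, not a taxon. Two-sided p-values use
the t approximation with n − 2 degrees of freedom for both methods
(displayed, not used for filtering; all defined rows are shown); exact
permutation p for Spearman is available for n ≤ 10, and an optional
Benjamini–Hochberg column can be added per table. p-values are not
multiplicity-adjusted by default because the ranked-search workflow treats
the table as an ordering, not a set of significance claims — the BH option
is the safer path when rows will be reported individually.

## Reporting

The interactive UI this engine descends from is replaced by a static,
self-contained HTML report: interactivity is plumbing, the analytics are
the substance, and a static bundle is diffable and archivable. Every
figure's underlying numbers are also emitted as TSV, making each chart
testable without image comparison; TSV rendering is deterministic, and
regeneration from a stored study is byte-identical. The composition table
shows the top `max_taxa_displayed` (default 10) taxa by global **mean**
abundance — "most abundant" is aggregated as the mean, ties broken
alphabetically — with remaining mass as `others`. The heat map uses a
linear color scale on the fixed [0, 1] abundance domain so panels are
comparable across samples. Pie drill-down renormalizes a taxon's children
to its mass at the next lower rank; drilling below genus is an error.

## Synthetic fixtures

The generator emulates a small adult cohort at the scale of a typical pilot
microbiome study: 20 samples, 60 genera grouped under a random lineage
forest (~1 family per 3 genera, up to ~4 phyla), sequencing depth 50,000
reads. Compositions are Dirichlet-multinomial with concentration decaying
as 50/(rank)^1.2 across genera, giving a few dominant taxa and a long tail;
sampling counts (not fractions) keeps Chao1 defined and the sum-to-one
constraint exact after normalization. Default parameters per type — 40
continuous, 6 nominal, 4 ordinal, 2 text, spread over the category/subgroup
scheme (body composition, blood profile, diet, physical activity, …) — are
enough to exercise category browsing and every exclusion rule while staying
instantaneous; continuous values are Gaussian (mean 50, sd 10). A planted
link replaces a parameter with direction·z(abundance) + σ·N(0,1), where z
is the standardized relative abundance of the chosen taxon, so σ is in
units of the signal and σ = 0 yields Spearman exactly ±1 by monotonicity.
The optional two-group split draws the groups from distinct Dirichlet
concentrations and records labels as a nominal `diet_group` parameter.

What the fixtures do **not** emulate: compositional correlation structure
beyond the Dirichlet, overdispersion, sequencing error, rarefaction
artifacts, and realistic phylogenies (UniFrac tests use random trees).
Passing tests therefore demonstrate the correctness of the computations and
contracts, not field performance on real cohorts — in particular the
planted-link recovery rate says nothing about power against real effect
sizes confounded by compositionality.

## Problem sizes

Test suites and the acceptance script run on generated cohorts of 10–20
samples and 15–60 taxa, 100-seed repetitions for recovery rates, 1000
random pairs for formula checks, and 100 random 8–16-leaf trees for the
UniFrac cross-check — sizes at which every oracle comparison is exhaustive
yet the whole suite completes in seconds.

## Known limitations

- Correlations on relative abundances inherit the compositional-data
  caveat: closure induces spurious negative dependence. SparCC/CLR-style
  compositionality-aware association is out of scope; the ranked search
  reproduces the platform behavior and should be read accordingly.
- No rarefaction or coverage-standardization; diversity is computed on the
  table as imported.
- The `others` greedy rule and the top-10 display rule are distinct
  mechanisms (chart legend vs table columns) and can retain different taxon
  sets by design.
- Taxon lookup in search operations is by name within a rank; identically
  named taxa under different parents (possible with many `unclassified`
  placeholders) resolve to the first match — disambiguate upstream if this
  matters.
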