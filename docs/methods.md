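# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator and what it does and does not emulate, the numerical
conventions, and the design choices made where more than one reasonable
option existed.

## Data model

The atomic unit is a dataset-level differential-expression signature: one
log2 fold change and p-value per gene, derived from a single study ×
genotype × tissue × sex × age combination. Metadata links datasets to
studies and interventions (mutant models); interventions carry a lifespan
label from {long, short, null, candidate, ageing}. Gene identifiers are
opaque, case-sensitive strings; no symbol mapping is attempted. Duplicate
gene rows in an input table are collapsed by keeping the smallest p-value —
a deterministic analogue of keeping the most informative probe when
expression-level information is unavailable in a summary table.

Fold-change matrices over shared genes can be quantile normalised: each
column's sorted values are replaced by the row means of the column-wise
sorted matrix, with ties receiving the mean of the reference values their
rank block spans. With tie-free data this makes all columns share one value
distribution exactly and is idempotent; exact ties are resolved by the
block-mean convention, which can leave tied columns slightly off the common
distribution (ties are measure-zero for continuous fold changes).

## Correlation stage

Spearman correlations (average ranks for ties, computed as Pearson on
ranks via scipy) are taken over the gene intersection of each dataset pair,
refusing pairs sharing fewer than `min_shared` genes (default 100 — the
floor is a guard against meaningless correlations on tiny intersections,
not an estimate of anything). Dataset-level correlations collapse to
intervention level in two stages: arithmetic mean within each study pair,
then an unweighted mean of study-pair means. The unweighted second stage
means a study contributes equally regardless of how many datasets it
produced, which is the point of the rule: replication within one study is
not independent evidence.

The significance threshold for transcriptome-wide correlations is the
empirical `q`-quantile (default 0.95) of |r_s| over all intervention pairs
of a null panel — interventions with no known lifespan effect, simulated
with mutually independent signatures. For independent signatures over G
shared genes the Spearman null is asymptotically Normal(0, 1/(G−1)), so the
threshold should approach 1.96/√(G−1); with G = 2000 that is ≈ 0.044. A
190-pair panel estimates this quantile with ~7% relative Monte-Carlo error,
so calibration checks average several independent panels.

Group statistics contrast same-effect pairs (long–long and short–short)
with opposite-effect pairs (long–short): a two-sided one-sample t-test of
each list against zero, an unpaired two-sided Wilcoxon rank-sum test
between the lists (exact null when the combined n ≤ 20, normal
approximation with continuity correction otherwise), and the fractions of
positive correlations. A degenerate all-equal list returns p = 1 when the
common value is zero.

## Enrichment stage

Genes are ranked by sign(log2FC)·(−log10 p), descending, with p floored at
1e−300 and exact metric ties broken lexicographically by gene id. The
statistic for a set S in a list of N genes is the extremum of the weighted
running sum (weight exponent 1): P_hit accumulates |metric|/Σ|metric| over
members, P_miss accumulates 1/(N−|S|) over non-members. The extremum of
larger magnitude is taken; when the positive and negative extrema tie in
magnitude (to a 1e−12 relative tolerance — the vectorised null path and the
literal scan can differ by a rounding ulp), the one attained earlier in the
list wins. A set spanning the whole list is degenerate (statistic 0, p 1).

The null re-draws |S| positions uniformly without replacement, 10,000 times
by default. Two observations make this cheap: the null depends only on the
|metric| vector and |S|, so it is shared across equally-sized terms of a
catalogue; and between member positions the running sum falls
monotonically, so each draw's extrema lie immediately before/after its |S|
member positions and the statistic costs O(|S| log |S|) rather than O(N).
Two-sided p-values take both tail fractions with add-one smoothing,
2·min((b+1)/(n+1)) capped at 1; tail counts use a 1e−9 relative tolerance
so draws that tie the observed statistic mathematically are counted as
ties. The signed score is direction·(−log10 p); the leading edge is the
member genes at or before the extremum (up) or at or after it (down).

Each dataset's permutation stream is derived from the base seed and a
checksum of its ranked list, so scores are independent of the order tables
are supplied in and identical data always scores identically (which also
makes dataset-level averaging exactly idempotent under duplication).
Dataset scores aggregate to interventions with the same two-stage rule as
correlations.

## Consistency stage

Within each intervention, terms are ranked by score (rank 1 = most
up-regulated, average ranks for ties, missing terms excluded). For a group
of I interventions, each term's observed statistic is the median of its I
ranks. The null distribution draws one rank uniformly and independently
from {1..T} per intervention and takes the median, 10^6 times by default;
draws are shared across terms with the same effective I. The one-sided
p-value is the add-one-smoothed empirical-CDF position of the observed
median among the null medians; both tails are examined, the smaller doubled
and capped at 1, and the direction is the smaller tail's sign. BH
adjustment is applied per group across terms. Terms scored in fewer than
two of the group's interventions are excluded.

The independent-uniform null ignores the within-intervention exclusivity of
ranks (a true joint null would be a permutation without replacement), which
is slightly conservative for any single term; the measured type-I fraction
at p < 0.05 on signal-free panels is ≈ 0.04–0.05. Note what the null does
*not* model: when interventions within a group genuinely share signal,
every term inherits a small consistent bias and the test will — correctly —
flag more terms than a nominal 5%. Calibration is therefore checked on
panels of mutually independent interventions, which is the regime the
test's null describes.

Terms significant in both groups partition into shared-opposite /
shared-same by direction agreement; terms significant in one group are
group-specific. Hub genes are those appearing in the leading edges of ≥ 2
focal terms in at least ⌈I/2⌉ of a group's I interventions ("at least half
of the mice", reading a mouse model as an intervention). When an
intervention has several datasets, a gene belongs to its intervention-level
leading edge if it appears in at least half of the datasets that scored the
term. Per-gene group comparisons use the exact Wilcoxon rank-sum on
quantile-normalised fold changes.

## Term network

All-pairs overlap coefficients oc = |A∩B|/min(|A|,|B|) over the focal
terms' full gene sets (not their leading edges); edges require oc strictly
greater than 0.4, and connected components with fewer than 5 nodes are
removed entirely. Output is independent of term order.

## Ageing comparison and prediction

Gene-level resemblance to ageing is the Spearman correlation of each
dataset's fold changes with the ageing signature of the same tissue,
averaged to intervention level by the two-stage rule; pathway-level
resemblance correlates enrichment-score columns. Group summaries reuse the
one-sample t and rank-sum machinery of the correlation stage.

Candidates are classified by Spearman-correlating their score profile over
the focal (shared-opposite) terms with each group's unweighted mean score
profile: pro-longevity-like if r_long > r_short, anti if the reverse,
indeterminate on an exact tie. The mean-profile reference was chosen over
averaging per-intervention correlations because it is deterministic and the
two agree in expectation on synthetic data; at least 3 shared focal terms
are required. Validation against an evidence table uses the two-sided
Fisher exact test (hypergeometric enumeration of tables at most as probable
as the one observed), with a Haldane 0.5 correction on the sample odds
ratio when a cell is empty.

## Synthetic-data generator

The generator works directly at the fold-change level — differential
expression fitting is upstream of this package's scope. Each lifespan group
g has a latent signature s_g with iid Normal(0, σ_b²) gene effects; genes
of planted terms get ±δ added according to the term's per-group direction.
An intervention mixes the group signature with its own noise,
x_i = w·s_g + (1−w)·ε_i; each dataset observes y_d = x_i + Normal(0, σ_d²);
p-values are two-sided normal, p = 2Φ(−|y|/se), with a single global
standard error so |fold change| and significance stay monotonely coupled.
Null-panel interventions use w = 0. The ageing signature mixes the
short-lived group's signature at weight ρ; candidates mix the long (λ > 0)
or short (λ < 0) signature at weight |λ|.

Defaults: 2000 genes, 1000 terms of 15–40 genes, σ_b = 1, σ_d = 0.5,
se = 0.5, w = 0.8, ρ = 0.8, 20 planted shared-opposite terms at δ = 2.5σ_b
split 10 up-in-long/down-in-short and 10 reversed (real shared-opposite
sets contain both polarities, dominated by one), long/short groups of 4
interventions × 2 studies, an 8-intervention null panel. The catalogue size
follows a feasibility analysis of the recovery experiment: with 10 planted
terms per polarity a planted term's median rank is ≈ 5.5, whose two-sided
median-rank p scales as ~12·55/T², so clearing the BH line at FDR 0.05
needs T ≳ 600, while chance shared-opposite coincidences grow linearly in T
and keep the truth-based FDR ≤ 0.1 only for T ≲ 1800; T = 1000 sits
mid-band.

Planted terms' gene sets are mutually disjoint *and* reserved: non-planted
terms sample only from the remaining genes (overlapping each other freely).
Without the reservation, non-planted terms absorb planted genes and inherit
real shared-opposite signal, making truth-based sensitivity/FDR
ill-defined. A consequence worth knowing: because planted sets are
disjoint, no gene can lead two focal terms, so hub-gene reports and the
focal-term network are empty on purely planted runs — those operations are
exercised by overlapping fixtures instead.

What the generator does not emulate: count-level noise and
mean-variance coupling, batch effects, tissue-specific signatures,
platform differences, gene-gene correlation beyond the shared group
signature, and realistic GO-style nesting of gene sets. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated model, not that real compendia will show effects of the
planted magnitude.

## Experiment problem sizes

The reproducibility experiments (`agemeta.experiments`, also run by
`scripts/acceptance.py`) use: 5 null panels of 20 single-dataset
interventions × 2000 genes for the threshold check; 10 replicates of
200 terms × 8 independent interventions (1000 permutations, 2·10⁵ null
medians) for type-I calibration; 10 replicates of the 20-planted-term
design with 4 single-dataset interventions per group for recovery; and
20 candidates per sign at |λ| = 0.7 for prediction accuracy. These sizes
keep each experiment under a minute on one CPU while leaving the Monte
Carlo error well inside the margins being tested.

## Known limitations

- The enrichment p-value floor is 2/(n_perm+1); score magnitudes saturate
  at log10((n_perm+1)/2), so strongly enriched terms tie at the cap. The
  consistency test tolerates this (ties get average ranks), but score
  magnitudes above the cap are not distinguishable.
- The median-rank null treats T as the full term count even when a few
  terms are missing in some interventions; with widespread missingness the
  per-intervention rank ranges would shrink and the null would be
  mis-scaled.
- The two-sided Wilcoxon switches from the exact null to a
  continuity-corrected normal approximation above a combined n of 20, and
  the exact path does not correct for cross-group ties.
- Intervention-level leading edges use a majority-of-datasets vote; with
  exactly two datasets this is a union, which is permissive.
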