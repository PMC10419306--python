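# Methods

## Scope and data model

`scstate` implements the post-clustering stages of a two-condition
single-cell/single-nucleus comparison: QC, annotation, differential
expression, directed gene-set scoring, condition-specific transcription
factors, and donor-level composition testing. Upstream steps with mature
standalone tools — normalization for integration, batch correction,
embedding, graph clustering — are deliberately out of scope; the pipeline
consumes cluster ids as input (the simulator's ground truth, or labels
produced by any external tool).

Counts travel as gene-by-cell sparse integer matrices read from
Matrix Market triplets (`matrix.mtx` + `features.tsv` + `barcodes.tsv`,
gzipped variants accepted). Gene sets are GMT lines whose member tokens
may carry a `|rep` suffix marking repressors; this dialect keeps the files
valid GMT while encoding direction, which plain GMT cannot.

## QC

Per cell: `n_features` (genes with count > 0), `n_counts` (total counts),
`pct_mito` (percent of counts on genes with a configurable symbol prefix,
default `MT-`; defined as 0 for an all-zero cell, which the feature floor
removes anyway). Discard rules are strict inequalities, so a cell exactly
at a threshold is kept; `apply_thresholds` is monotone in every threshold.
Nuclei from tissues whose parenchymal cells run high in mitochondrial
reads (cardiomyocytes) break a naive mito cut, so the cut can be
*deferred*: pass one filters on features/counts only, annotation assigns
labels, and a second pass applies the mito cap to all cells except the
exempt labels. For cells with non-exempt labels the two-pass scheme is
provably identical to single-pass filtering with the same cap (tested).
Downsampling selects a uniform random subset of cells without replacement
(order-preserving, counts untouched); the default stage order is QC first,
then downsample, and both the targets and the order are configuration.

## Normalization, annotation, gating

Expression is log-normalized per cell: `ln(1 + count * sf / cell_total)`
with `sf = 10,000`, a transform that is monotone within each cell (rank
order preserved) and maps all-zero cells to all-zero columns. Each cluster
is assigned the label whose marker list has the highest mean normalized
expression over the cluster's cells; ties go to the first declared label
and are flagged. This replaces manual annotation from violin plots with an
auditable rule — all per-label scores are reported so a human can override
via configuration.

The co-expression subtype gate flags cells with expression of *both*
gating genes above a threshold (default 0, i.e. any nonzero count — the
weakest defensible gate in sparse UMI data, and invariant to the
normalization since positivity is preserved). Marker validation uses the
ROC AUC computed as Mann–Whitney U / (n_pos · n_neg) with ties counted ½.
Whether a gate should be re-derived per tissue is a scientific choice left
to configuration.

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum test: exact (full enumeration of
the rank-sum distribution) when both groups have ≤ 8 observations and the
data are tie-free, otherwise the normal approximation with tie and
continuity corrections. p-values that underflow are floored at the
smallest positive double so they stay in (0, 1]. Fold changes follow the
Seurat v4 convention: `log2((mean(expm1 a) + c) / (mean(expm1 b) + c))`
with pseudocount `c = 1` (configurable). The default multiple-testing
adjustment is Bonferroni over all genes tested, reproducing the retention
rule of the mainstream `FindMarkers` workflow; BH is available by flag.
No detection-fraction or fold-change prefilter is applied by default;
both exist as options and the `tested` column records which genes entered
the adjustment.

## Gene enrichment score

For a directed set with members g₁…g_G, repressor genes' log2 fold
changes are sign-inverted, and

GES = Σᵢ adjFCᵢ / maxᵢ |adjFCᵢ|

over the entering genes. By default only genes significant in the DE
table enter (matching the adjusted-p < 0.05 retention applied upstream),
and the max-abs normalizer is taken **within the entering set genes** —
the sum's index runs over the set — with a global normalizer available by
option. G is reported both as declared and as scored (set genes missing
from the DE table are dropped and listed). The score satisfies, and the
suite verifies: scale invariance (any c > 0 on all fold changes cancels),
sign equivariance, |GES| ≤ G with equality only for unanimous saturated
contributions, and repressor involution. An empty entering set or an
all-zero normalizer is reported as incomputable with a reason rather than
scored. No p-value is attached to a GES; none is defined for it.

## Condition-specific transcription factors

Two DE runs with the same contrast — cell type of interest vs all other
cell types, run separately inside the disease and the control condition —
are intersected with a user-supplied TF catalog: retained TFs are
significant (adjusted p < α) in disease and *not* significant in control,
where "absent from the control table" counts as not significant and is
recorded as `untested`. The contrast is configurable; type-vs-rest is the
default because it is the standard marker-test grouping. Note the "rest"
population differs between conditions whenever composition or other
planted effects differ, so genes outside the target type can legitimately
appear; the logic is monotone in α through the disease filter and
anti-monotone through the control filter (both tested).

## Composition testing

Per donor, cell-type proportions (optionally within a parent population,
e.g. a gated subtype among T cells — the denominator is the parent count).
For each (cell type, condition), donor proportions are screened with the
single-outlier two-sided Grubbs test, G = max|xᵢ − x̄|/s against
G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²)), t = t_{1−α/(2n), n−2}, at
α = 0.05 (matching the 95% confidence used throughout); a flagged donor is
removed for that cell type's test only and logged. Groups are then
compared with a two-sided pooled-variance Student *t* test (df = n₁+n₂−2;
Welch by flag) and tiered "\*" (p < 0.05), "‡" (0.05 ≤ p < 0.1), "n.s.".
Zero pooled variance returns a flagged degenerate result (t = 0, p = 1
for equal means; p → 0 otherwise) instead of aborting the report, and any
per-type failure is recorded in a `note` column. For rare-subtype
comparisons an optional `nonzero_only` mode restricts each group's test to
donors that actually contain the subtype (screening still sees every
donor); a group reduced below two donors is reported as insufficient
rather than tested — the appropriate outcome when, say, the only
subtype-containing control donor is itself the flagged outlier.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular tissue: counts are negative-binomial,
`X ~ NB(mean = L·f_t[g]·2^β, dispersion θ)`, with log-normal library sizes
L (meanlog 7.6, sdlog 0.35 ≈ 2,000 counts/cell), a shared gene-level
dispersion θ = 2 (typical UMI overdispersion), per-type expression
profiles with 5 exclusive high-expression markers per type, and
mitochondrial genes carrying a type-specific share of expression (40% for
the cardiomyocyte-like type, 3% elsewhere) so deferred filtering has real
work to do. Donor mixture weights get a multiplicative disease shift
followed by Dirichlet jitter (concentration 200, giving a between-donor
proportion s.d. of ≈ 0.03 at w = 0.2) so composition t-tests face
realistic donor variance; weights renormalize, so a planted shift in one
type moves the others reciprocally — a real, intended property of
compositional data. The default fixture is ≈ 300 genes (10 mitochondrial),
5 cell types, 4 donors per condition at ≈ 400 cells each, a 2× disease
shift of the T-cell weight, 20 planted DE genes at |β| ∈ [1.2, 2] split
between T cells and macrophages (disease only), and a 7% TBX21+RUNX1+
subtype among disease T cells whose gating genes are silent elsewhere; an
optional outlier donor has one mixture weight inflated 20×, far beyond
5 s.d. of the other donors. These sizes run the full pipeline in seconds
while leaving each stage non-trivial statistical work.

What the simulator does *not* model: gene–gene correlation, batch or
chemistry effects, ambient RNA, doublets, or donor-specific expression
(as opposed to composition) effects. Passing tests therefore demonstrate
correctness of the statistical machinery under a clean generative model,
not robustness to the full messiness of real tissue data.

## Numerical and design conventions

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bitwise-identical
  matrices and byte-identical result TSVs.
- Matrix orientation is genes × cells (10x convention); Matrix Market
  indices are 1-based on disk, 0-based in memory.
- Annotation ties: first declared label wins, tie logged. GES degenerate
  cases: explicit errors, downgraded to statuses in table output.
- The composition stage treats donors missing a cell type as proportion 0;
  donors with zero cells at a level are excluded with a warning.
- The exact rank-sum path switches to the asymptotic path at group size 9
  or on any tie, mirroring standard practice.

## Known limitations

- Cluster annotation assumes marker sets that separate on mean expression;
  closely related subtypes may need manual override via the reported
  scores.
- The Grubbs screen removes at most one donor per (type, condition); with
  n = 4 donors the statistic is bounded by 1.5 against a critical value of
  1.481, so detection at that size is inherently marginal unless the
  remaining donors are tight.
- Proportion t-tests ignore the compositional constraint beyond
  renormalization (no CLR/ALR transform, by design — the method being
  reproduced uses plain t tests on proportions).
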