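# Methods

This note documents the models and procedures implemented in tamkit,
the assumptions behind them, the parameters that matter, and what the
synthetic-data generators do and do not emulate.

## Data model and normalisation

Expression lives in an `AnnData` (cells × genes).  Raw counts in `X`
must be non-negative integers; per-cell annotations (study, sample,
patient, cancer type, tissue, cluster, condition) are `obs` columns.
Log-normalisation writes a `"lognorm"` layer,
`ln(1 + count/total × 10⁴)`, leaving the raw matrix untouched.  All
per-cell scores and differential expression use this layer; raw counts
feed only the bulk ranking stage.  Cells with zero total counts get
all-zero normalised values with a warning rather than an error — they
occur in pathological fixtures, not in quality-filtered data.

Gene matching is exact and case-sensitive.  Signature genes missing
from a matrix are dropped per operation with a warning; if fewer than
half of a signature is present the operation refuses to score it,
because a mostly-absent signature measures annotation mismatch, not
biology.

## Rank-based per-cell score

Per cell, genes are ranked by decreasing expression with average ranks
on ties; ranks beyond `r_max` are truncated to `r_max + 1`, and the
score is `max(0, 1 − U/(n·r_max))` with `U` the Mann-Whitney statistic
of the signature genes' ranks.  Tie resolution happens before
truncation.  `r_max` defaults to 1500 — the published default of the
rank-score family this reimplements — and is configurable; it bounds
the depth of the expression profile that can influence the score, which
is what makes scores comparable across platforms with different
sensitivity.  The floor at 0 keeps the documented [0, 1] range (a cell
whose signature genes all fall past the cap would otherwise go slightly
negative).

## Control-bin module score

Genes are cut into `n_bins` (default 24) equal-count bins of average
expression; each signature gene contributes `n_ctrl` (default 100)
control genes drawn with replacement from its bin, and the score is the
mean signature expression minus the mean of the pooled controls.  The
draw is deterministic given the seed.  Equal-count binning (rather than
equal-width) keeps control pools non-degenerate under the heavily
skewed mean-expression distributions of scRNA-seq.

## Marker derivation

One-vs-rest two-sided Wilcoxon rank-sum per gene (normal approximation
with tie correction), restricted to genes detected in ≥ 10% of the
cluster and with log2 fold change ≥ 0.25, where fold change is computed
on `expm1` means of the log-normalised values with a pseudocount of 1.
P-values are BH-adjusted per cluster; the cluster signature is the top
10 genes by fold change among those with q < 0.05.  The pct/log2fc
pre-filters mirror the defaults of the standard single-cell marker
tools.  Clusters with fewer than 3 cells are skipped — a rank test on
two cells is noise.

## TAM cluster selection

Threshold = mean + `k_sd` × SD of the per-cell macrophage-signature
scores over the entire dataset, with `k_sd` = 1 and the sample SD
(ddof = 1); clusters whose mean score is strictly above threshold are
selected.  The SD is taken over cells, not over cluster means: with a
handful of clusters a between-cluster SD would be too unstable to
threshold.  When all scores are identical the selection is empty by
construction (strict inequality), with a warning.  Note the rule is
sensitive to the target's prevalence: a cluster comprising a large
fraction of all cells inflates both the dataset mean and SD of its own
score and can fail its own threshold.

## Signature specificity and the gold-standard gate

`Metric_1` is the margin between the highest and second-highest cluster
mean score computed on the pooled (all-cancer-type) means; a tie for
best yields margin 0 and no best hit.  `Metric_2` repeats the best-hit
comparison within each cancer type and counts agreements with the
signature's own cluster (ties never count).  Per-cancer margins are
also reported.  The gate requires the pooled best hit to be the own
cluster, `Metric_2 ≥ 3`, and `Metric_1` strictly greater than 0.1.
Pooled-vs-per-cancer placement of `Metric_1` is a genuine design fork;
the pooled reading was chosen because the gate pairs a single margin
threshold with a separate per-cancer count.

## Composition testing

Fractions are arcsin-square-root transformed (variance-stabilising for
proportions), then modelled per cluster by OLS on a group-means design.
Residual variances across clusters share a scaled-F empirical-Bayes
prior fitted by moment matching on
`e_g = log s²_g − ψ(df/2) + log(df/2)`: the prior degrees of freedom
solve `ψ′(d₀/2) = var(e) − ψ′(df/2)` by Newton inversion of the
trigamma function, and the prior scale is
`exp(mean(e) + ψ(d₀/2) − log(d₀/2))`.  When the observed spread of log
variances is no larger than chi-square sampling noise, `d₀ = ∞` and all
posterior variances collapse to the common value.  The implementation
agrees with the reference empirical-Bayes moderation in R's limma to
numerical precision (checked in the test suite).

Two groups → moderated t on `d₀ + df` degrees of freedom (two-sided);
more → moderated F on `(k − 1, d₀ + df)`.  BH correction is applied
across clusters, once per test call (one family per analysis), with
q < 0.1 the conventional significance threshold.  Samples enter
unweighted and are treated as independent units; repeated samples per
patient are not modelled, and robust down-weighting of outlier
variances is not implemented — both documented limitations.  Because
fractions sum to one, planting an enrichment in one cluster necessarily
depletes the rest; compositional tests cannot attribute direction to a
single cluster, only identify where the evidence is strongest.

## Gene ranking and enrichment

Bulk counts are filtered to genes with nonzero counts in ≥ 20% of
samples and converted to log2-CPM with a 0.5 pseudocount.  Per gene,
OLS on [intercept + cancer-type indicators + response] with the same
variance moderation as the composition test yields a moderated t for
the response coefficient; genes are ranked by it (stable order on
ties).  This is deliberately a linear-model ranker rather than a
negative-binomial GLM: the enrichment stage consumes only the ordering,
and the moderated t provides a covariate-adjusted, variance-stable one.
A design in which response is constant within a covariate level is
refused as confounded.

The enrichment score walks the ranking: hits add
`|r|^w / Σ_hits |r|^w` (weight `w` = 1), misses subtract
`1/(N − N_hits)`; ES is the running-sum value of maximal absolute
deviation.  The null is gene-permutation (random same-size sets), the
p-value counts sign-matched null scores at least as extreme with a
`+1` floor, and NES divides ES by the mean |null ES| of matching sign.
The multilevel adaptive refinement of small p-values used by some
preranked-GSEA implementations is omitted; p-values are floored at
`1/(n_perm + 1)`, so `n_perm` bounds attainable significance.

## Spatial analysis

Membership thresholds are strict, as printed: score > 0.8 member,
< 0.4 nonmember, otherwise unassigned.  Unassigned cells are excluded
as focal cells but remain eligible as neighbours under their cell-type
label.  Neighbourhoods use brute-force Euclidean k-nearest neighbours
(default k = 5, with a sweep utility over k ∈ {1, 5, 10, 20} since the
choice is a free parameter) with self excluded and ties at the k-th
distance broken by cell-id order — the deterministic tie-break is the
reason for brute force over a kd-tree; the two agree exactly on
tie-free data.  Composition pools neighbour counts over focal cells
before normalising, so dense regions weigh in proportion to their cell
count.

## Quartiles, co-occurrence, ordination, percentiles

Quartile strata use linear-interpolation quantiles at 25/75%; strict
inequality beyond a threshold assigns lower/upper, ties at a threshold
stay middle.  The Mann-Whitney test reports the first sample's U and
rank sum, with exact enumeration of all labellings for pooled n ≤ 12
and a tie- and continuity-corrected normal approximation otherwise.
Sample-level signature scores aggregate per-cell scores by mean
(median by flag), or score a bulk profile directly with the rank-based
scorer (valid because the score only uses within-sample ranks).

Cluster co-occurrence is Spearman rho on per-sample fractions.  PCoA
double-centres `−½D²` and embeds on the positive eigenvalues;
negative eigenvalues are reported, never embedded.  Hierarchical
clustering of per-cluster mean expression uses Euclidean distance with
complete linkage by default (average/Ward available), leaves in sorted
label order for deterministic ties, exportable as Newick.
Marker-percentile profiles restrict to positively expressing cells,
cut them into 100 equal-count bins with ties kept in the lower bin,
and report per-bin cluster fractions; the pooled profile equals the
composition of all positive cells.

## Synthetic data: what it emulates, what it does not

The single-cell generator produces negative-binomial counts
(variance `μ + μ²·φ`, default dispersion 0.5) over multiple studies:
disjoint per-cluster marker genes with mean multiplied by
`2^marker_log2fc` (default 2, i.e. 4-fold), gene-wise multiplicative
lognormal batch factors per study (default SD 0.3), and per-sample
cluster compositions drawn from a Dirichlet with concentration 10 per
cluster, whose log-weights shift with the sample's condition — small
study counts, a few hundred cells per sample, emulating the structure
(not the scale) of a multi-study pan-cancer atlas.  The bulk generator
emulates an ICI cohort: five cancer types as a covariate with lognormal
per-type gene offsets, ~25% responders, and responder-specific
`2^effect` shifts on signature genes.  The spatial generator places
circular niches of co-located cell types (an ECM-macrophage/fibroblast
niche and an interferon-γ-macrophage/T-cell niche by default) over a
uniform Poisson background, with lognormal expression noise around
cell-type marker profiles.

Not emulated: doublets, ambient RNA, UMI saturation, gene-gene
correlation beyond cluster structure, patient-level nesting of samples,
spatial segmentation errors.  Passing tests therefore demonstrate that
the algorithms recover the signals they are specified to recover under
a faithful noise model — not that any particular biological claim holds
in real data.

## Numerical choices

- Average ranks on ties everywhere a rank is taken; truncation after
  tie resolution.
- Trigamma inversion by Newton iteration from the asymptotic start
  `x ≈ 0.5 + 1/y`, with closed-form limits for extreme arguments;
  relative tolerance 1e-10.
- Variances below 1e-300 are floored before moderation to avoid log
  underflow on degenerate all-equal groups.
- BH adjustment excludes NaN inputs from the family size and propagates
  them.
- GSEA null ES values are computed from sorted hit positions by the
  same piecewise-linear extremum formula used for the observed score,
  so observed and null scores are exactly comparable.
- All generators and permutation procedures take explicit integer
  seeds; spawned sub-seeds stay below 2³¹.

## Problem sizes

Default simulation sizes (a few studies × a few hundred cells, 1.5-2k
genes, 120-sample cohorts, ~1k spatial cells, 2000 permutations, 500-
2000 Monte-Carlo replicates) were chosen so that every planted signal
is comfortably detectable and calibration estimates have Monte-Carlo
error well below the margins being tested, while the whole suite runs
on a laptop-class single core in minutes.
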