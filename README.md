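# tamkit

Analysis toolkit for tumour-associated macrophage (TAM) single-cell
atlases: rank-based signature scoring, macrophage cluster selection,
signature-specificity gating for bulk deconvolution, differential
cluster-composition testing, enrichment-based association with
immunotherapy response, quartile-stratified comparisons, spatial subset
assignment with neighbourhood composition, and marker-percentile
profiling — all exercisable end to end on synthetic data with known
ground truth.

## Who it is for

Computational immunologists and tumour-microenvironment researchers who
have (or simulate) a clustered scRNA-seq atlas of myeloid cells and want
to: derive per-cluster marker signatures, decide which signatures are
trustworthy in bulk RNA-seq, test whether cluster composition differs
between tumour conditions, relate signatures to immune-checkpoint-
inhibitor (ICI) response cohorts, and validate subsets in spatial
transcriptomics.

## The statistics at the core

**Rank-based signature score.** For a cell with expression vector `x`
and a signature `S` of `n` genes, rank all genes by decreasing
expression (average ranks on ties), truncate ranks at `r_max + 1`
(default `r_max` = 1500), and compute the Mann-Whitney statistic
`U = Σ_{g∈S} rank(g) − n(n+1)/2`.  The score
`max(0, 1 − U/(n·r_max))` lies in [0, 1], equals 1 when the signature
genes occupy the top ranks, and is invariant to any strictly monotone
transform of the cell's expression — the property that lets the same
scorer run on single-cell, bulk and spatial profiles.

**TAM cluster selection.** A cluster is called macrophage when its mean
signature score exceeds `mean + 1·SD` of the per-cell scores over the
entire dataset.

**Signature specificity.** On an all-cell-type atlas,
`Metric_1` = margin between the best and second-best cluster mean score
and `Metric_2` = number of cancer types whose best-hit cluster is the
signature's own.  A signature is *gold standard* when its own cluster is
the overall best hit, `Metric_2 ≥ 3` and `Metric_1 > 0.1` (strict).

**Composition testing.** Cluster fractions per sample are transformed by
`y = asin(√p)`; per cluster, `y` is modelled by OLS on group indicators,
and residual variances are moderated by an empirical-Bayes scaled-F
prior fitted via trigamma moment matching:
`s²_post = (d₀·s₀² + df·s²)/(d₀ + df)`.  Two groups give a moderated t
on `d₀ + df` degrees of freedom, more give a moderated F; q-values are
Benjamini-Hochberg with the conventional q < 0.1 threshold.

**Preranked enrichment.** Genes are ranked by a covariate-adjusted
moderated t for response; a signature's enrichment score is the maximal
deviation of the weighted Kolmogorov-Smirnov running sum; significance
and NES come from a gene-permutation null.

**Spatial subsets.** Cells with signature score > 0.8 are members of a
subset, < 0.4 nonmembers; the neighbourhood of a subset is the pooled
cell-type composition of each member's k nearest neighbours (Euclidean,
default k = 5).

## Worked example

Simulate a three-study atlas in which cluster `c2` is planted at ~2.7×
composition weight in metastatic samples, recover the cluster marker
signatures, apply the selection rule, and test the composition shift:

```python
from tamkit import core, proportions, scoring, synthdata

cfg = synthdata.SCSimConfig(
    n_studies=3, n_samples_per_study=6, n_clusters=4, n_genes=800,
    cells_per_sample=(80, 150), marker_log2fc=2.0,
    condition_effects={"primary": {}, "metastasis": {"c2": 1.0}}, seed=7)
adata, truth = synthdata.simulate_sc_atlas(cfg)
core.lognormalize(adata)

markers, signatures = scoring.derive_cluster_signatures(adata, n_top=10)
recovered = sum(len(set(s.genes) & set(truth.marker_genes[s.own_cluster]))
                for s in signatures)
print(f"marker recovery: {recovered}/{sum(len(s.genes) for s in signatures)}")

scores = scoring.rank_cell_scores(adata, signatures[0], r_max=800)
selected = scoring.select_tam_clusters(scores, adata.obs["cluster"])
print(f"clusters selected by the {signatures[0].name} signature: "
      f"{sorted(selected)}")

props = proportions.sample_cluster_proportions(adata.obs)
for r in sorted(proportions.moderated_test(props), key=lambda r: r.q):
    print(f"cluster {r.cluster}: t = {r.statistic:+.2f}, q = {r.q:.2e}")
```

prints

```
marker recovery: 40/40
clusters selected by the c0 signature: ['c0']
cluster c2: t = -6.38, q = 7.24e-10
cluster c0: t = +2.81, q = 6.66e-03
cluster c1: t = +2.87, q = 6.66e-03
cluster c3: t = +2.04, q = 4.17e-02
```

All 40 planted marker genes land in the derived top-10 signatures; the
`c0` signature selects exactly its own cluster under the 1-SD rule; and
the planted `c2` enrichment is by far the most significant composition
difference (the t statistic is metastasis-vs-primary with groups in
sorted order, so the enriched cluster appears with a negative sign;
the other clusters shift the opposite way because fractions must sum
to 1).

The same stages are scriptable from a shell via the `tamkit` CLI
(`tamkit simulate sc`, `tamkit markers`, `tamkit score`,
`tamkit proportions`, `tamkit rank`, `tamkit gsea`,
`tamkit spatial-assign`, `tamkit spatial-knn`, ...); every subcommand
reads and writes MTX/CSV/GMT/JSON.

## Layout

- `src/tamkit/core.py` — data model, MTX/CSV/GMT/YAML I/O, log-normalisation
- `src/tamkit/synthdata.py` — single-cell / bulk / spatial generators
- `src/tamkit/scoring.py` — per-cell scorers, marker test, TAM selection
- `src/tamkit/specificity.py` — Metric_1 / Metric_2, gold-standard gate
- `src/tamkit/proportions.py` — arcsin-sqrt moderated composition test, BH
- `src/tamkit/enrichment.py` — covariate-adjusted ranking, preranked GSEA
- `src/tamkit/spatial.py` — threshold membership, kNN composition
- `src/tamkit/association.py` — quartiles, Mann-Whitney, co-occurrence,
  PCoA, hierarchical clustering, marker percentiles
- `docs/methods.md` — models, assumptions, parameter choices, limitations
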