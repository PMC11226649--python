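"""Per-cell signature scoring, marker derivation and TAM cluster selection.

Two per-cell scorers are provided:

* :func:`rank_cell_scores` — a rank-based score in [0, 1] built from the
  Mann-Whitney U statistic of the signature genes' capped expression ranks
  within each cell.  Because only within-cell ranks enter, the score is
  invariant to any strictly monotone transform of a cell's expression
  vector, which makes it robust to normalisation differences between
  datasets and platforms.
* :func:`module_score` — mean signature expression minus the mean of
  expression-matched control genes drawn from average-expression bins.

On top of the scorers sit the one-vs-rest Wilcoxon marker test used to
derive top-10 cluster signatures, and the selection rule that flags
macrophage clusters as those whose mean signature score exceeds the
dataset mean by ``k_sd`` standard deviations.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .core import GeneSignature, get_dense, resolve_signature_genes
from .proportions import bh_adjust

__all__ = [
    "rank_cell_scores",
    "module_score",
    "derive_cluster_signatures",
    "cluster_mean_scores",
    "select_tam_clusters",
]


def rank_cell_scores(adata: ad.AnnData, sig: GeneSignature,
                     r_max: int = 1500, layer: str = "lognorm") -> pd.Series:
    """Rank-based signature score per cell (UCell-style), in [0, 1].

    Per cell, all genes are ranked by decreasing expression (ties get
    average ranks), ranks beyond ``r_max`` are truncated to ``r_max + 1``,
    and the score is ``max(0, 1 - U / (n * r_max))`` where ``U`` is the
    Mann-Whitney U statistic of the ``n`` signature genes' ranks:
    ``U = sum(ranks) - n(n+1)/2``.  A score of 1 means the signature genes
    occupy the very top ranks of the cell.

    Parameters
    ----------
    adata
        Cells x genes container with the expression layer to score.
    sig
        Signature to score; genes missing from the matrix are dropped
        (error if fewer than half remain).
    r_max
        Rank cap; genes ranked deeper than this contribute identically.
    """
    if r_max < 1:
        raise ValueError("r_max must be >= 1")
    genes = resolve_signature_genes(adata.var_names, sig)
    X = get_dense(adata, layer)
    ranks = rankdata(-X, axis=1)  # average ranks, descending expression
    np.minimum(ranks, r_max + 1, out=ranks)
    cols = adata.var_names.get_indexer(genes)
    n = len(genes)
    U = ranks[:, cols].sum(axis=1) - n * (n + 1) / 2
    score = np.maximum(0.0, 1.0 - U / (n * r_max))
    return pd.Series(score, index=adata.obs_names, name=sig.name)


def score_signatures(adata: ad.AnnData, sigs: Sequence[GeneSignature],
                     r_max: int = 1500, layer: str = "lognorm") -> pd.DataFrame:
    """Rank-based scores for several signatures; cells x signatures."""
    return pd.DataFrame({s.name: rank_cell_scores(adata, s, r_max, layer)
                         for s in sigs})


def module_score(adata: ad.AnnData, sig: GeneSignature, n_bins: int = 24,
                 n_ctrl: int = 100, seed: int = 0,
                 layer: str = "lognorm") -> pd.Series:
    """Control-bin module score per cell.

    Genes are partitioned into ``n_bins`` equal-count bins by their average
    expression over all cells.  For every signature gene, ``n_ctrl`` control
    genes are drawn (with replacement) from that gene's bin; the score is
    the mean expression of the signature genes minus the mean over the
    pooled control draws.  Deterministic given ``seed``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    genes = resolve_signature_genes(adata.var_names, sig)
    X = get_dense(adata, layer)
    n_genes = X.shape[1]
    if n_genes < n_bins:
        warnings.warn(f"only {n_genes} genes; reducing bins from {n_bins}")
        n_bins = n_genes
    gene_means = X.mean(axis=0)
    order = np.argsort(gene_means, kind="stable")
    bin_id = np.empty(n_genes, dtype=np.int64)
    bin_id[order] = np.arange(n_genes) * n_bins // n_genes

    rng = np.random.default_rng(seed)
    cols = adata.var_names.get_indexer(genes)
    ctrl_cols = np.concatenate([
        rng.choice(np.flatnonzero(bin_id == bin_id[c]), size=n_ctrl,
                   replace=True)
        for c in cols
    ])
    score = X[:, cols].mean(axis=1) - X[:, ctrl_cols].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name=sig.name)


def _tie_term(col: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of one gene's values."""
    _, counts = np.unique(col, return_counts=True)
    counts = counts[counts > 1].astype(np.float64)
    return float((counts ** 3 - counts).sum())


def derive_cluster_signatures(
    adata: ad.AnnData,
    cluster_key: str = "cluster",
    n_top: int = 10,
    min_pct: float = 0.1,
    min_log2fc: float = 0.25,
    q_max: float = 0.05,
    layer: str = "lognorm",
) -> tuple[pd.DataFrame, list[GeneSignature]]:
    """One-vs-rest Wilcoxon marker test and top-``n_top`` cluster signatures.

    Per cluster, genes detected in at least ``min_pct`` of the cluster's
    cells and with log2 fold change >= ``min_log2fc`` are tested with a
    two-sided Wilcoxon rank-sum (normal approximation with tie correction)
    against all other cells.  Fold changes are computed on ``expm1`` means
    of the log-normalised values with a pseudocount of 1.  P-values are
    BH-adjusted per cluster; the signature is the ``n_top`` genes with the
    largest fold change among those with q < ``q_max``.

    Returns the full marker table (cluster, gene, log2fc, p, q, pct_in,
    pct_out) and one :class:`GeneSignature` per cluster.  Clusters with
    fewer than 3 cells are skipped with a warning.
    """
    clusters = pd.Series(adata.obs[cluster_key], index=adata.obs_names)
    labels = sorted(map(str, clusters.dropna().unique()))
    if len(labels) < 2:
        raise ValueError("need at least two clusters to derive markers")
    X = get_dense(adata, layer)
    var_names = np.asarray(adata.var_names)

    rows: list[dict] = []
    sigs: list[GeneSignature] = []
    for cl in labels:
        mask = (clusters.astype(str) == cl).to_numpy()
        n1 = int(mask.sum())
        n2 = int((~mask).sum())
        if n1 < 3:
            warnings.warn(f"cluster {cl!r} has {n1} cells (<3); skipped")
            continue
        Xin, Xout = X[mask], X[~mask]
        pct_in = (Xin > 0).mean(axis=0)
        pct_out = (Xout > 0).mean(axis=0)
        mu_in = np.expm1(Xin).mean(axis=0)
        mu_out = np.expm1(Xout).mean(axis=0)
        log2fc = np.log2((mu_in + 1) / (mu_out + 1))
        keep = np.flatnonzero((pct_in >= min_pct) & (log2fc >= min_log2fc))
        if keep.size == 0:
            warnings.warn(f"cluster {cl!r}: no genes pass the pct/log2fc "
                          "filters")
            continue

        N = n1 + n2
        Xk = X[:, keep]
        R = rankdata(Xk, axis=0)
        R1 = R[mask].sum(axis=0)
        mu_R1 = n1 * (N + 1) / 2
        ties = np.array([_tie_term(Xk[:, j]) for j in range(keep.size)])
        var_R1 = n1 * n2 / 12.0 * ((N + 1) - ties / (N * (N - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var_R1 > 0, (R1 - mu_R1) / np.sqrt(var_R1), 0.0)
        p = 2 * norm.sf(np.abs(z))
        q = bh_adjust(p)

        for j, gi in enumerate(keep):
            rows.append(dict(cluster=cl, gene=var_names[gi],
                             log2fc=log2fc[gi], p=p[j], q=q[j],
                             pct_in=pct_in[gi], pct_out=pct_out[gi]))
        # significant genes ordered by descending fold change, stable ties
        sig_genes = [var_names[keep[j]]
                     for j in sorted(range(keep.size),
                                     key=lambda j: (-log2fc[keep[j]], j))
                     if q[j] < q_max][:n_top]
        if not sig_genes:
            warnings.warn(f"cluster {cl!r}: no significant markers "
                          f"(q < {q_max}); no signature emitted")
            continue
        if len(sig_genes) < n_top:
            warnings.warn(f"cluster {cl!r}: only {len(sig_genes)} "
                          f"significant markers (< {n_top})")
        sigs.append(GeneSignature(name=str(cl), genes=tuple(sig_genes),
                                  own_cluster=str(cl)))

    markers = pd.DataFrame(
        rows, columns=["cluster", "gene", "log2fc", "p", "q",
                       "pct_in", "pct_out"])
    return markers, sigs


def cluster_mean_scores(scores: pd.Series, groups: pd.Series) -> pd.Series:
    """Arithmetic mean score per group, ordered by descending mean."""
    aligned = groups.reindex(scores.index)
    if aligned.isna().any():
        raise ValueError("group labels missing for some scored cells")
    means = scores.groupby(aligned.astype(str), observed=True).mean()
    return means.sort_values(ascending=False, kind="stable")


def select_tam_clusters(scores: pd.Series, clusters: pd.Series,
                        k_sd: float = 1.0) -> set[str]:
    """Clusters whose mean score exceeds the dataset mean by ``k_sd`` SDs.

    The threshold is ``mean + k_sd * SD`` of the per-cell scores over the
    entire dataset (sample SD, ddof=1); a cluster is selected when its mean
    per-cell score is strictly above the threshold.  With zero dispersion
    nothing can clear a strict threshold, so the selection is empty (with a
    warning).
    """
    if len(scores) < 2:
        raise ValueError("need at least two cells")
    sd = float(scores.std(ddof=1))
    if sd == 0:
        warnings.warn("all scores identical (SD = 0); no cluster selected")
        return set()
    threshold = float(scores.mean()) + k_sd * sd
    means = cluster_mean_scores(scores, clusters)
    return set(means.index[means > threshold])
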