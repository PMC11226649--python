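"""Quartile-stratified comparisons, co-occurrence and profiling utilities.

This module collects the sample-level association machinery: aggregating
per-cell scores to samples (or scoring bulk profiles directly), splitting
samples at the quartiles of a score, the Mann-Whitney U test used to
compare strata, Spearman co-occurrence of cluster fractions across
samples, classical principal-coordinates analysis (PCoA) of composition
distances, hierarchical clustering of cluster mean-expression profiles,
and the percentile-resolved cluster membership profile of a marker gene.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata

from .core import get_dense
from .proportions import ProportionTable

__all__ = [
    "sample_signature_score",
    "quartile_split",
    "mann_whitney_u",
    "spearman_cooccurrence",
    "pcoa",
    "hierarchical_cluster_means",
    "marker_percentile_membership",
]

LOWER, UPPER, MIDDLE = "lower", "upper", "middle"


def sample_signature_score(scores: pd.Series, samples: pd.Series,
                           statistic: str = "mean") -> pd.Series:
    """Aggregate per-cell scores to one score per sample.

    ``scores`` holds per-cell values for the designated cell population
    (e.g. MANA score per CD8 T cell); ``samples`` maps those cells to
    samples.  Samples without any designated cell simply do not appear.
    ``statistic`` is ``"mean"`` (default) or ``"median"``.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    aligned = samples.reindex(scores.index)
    if aligned.isna().any():
        raise ValueError("sample label missing for some scored cells")
    grouped = scores.groupby(aligned.astype(str), observed=True)
    out = grouped.mean() if statistic == "mean" else grouped.median()
    return out.rename(scores.name)


def bulk_signature_scores(expr: pd.DataFrame, sig, r_max: int = 1500
                          ) -> pd.Series:
    """Rank-based signature score of each bulk sample profile.

    Each row (sample) of ``expr`` is treated as a single "cell" and scored
    with the rank-based scorer; useful for quartile analyses on bulk
    cohorts where no per-cell resolution exists.
    """
    from .scoring import rank_cell_scores
    adata = ad.AnnData(X=expr.to_numpy(dtype=np.float64),
                       obs=pd.DataFrame(index=expr.index.astype(str)),
                       var=pd.DataFrame(index=expr.columns.astype(str)))
    adata.layers["lognorm"] = adata.X
    return rank_cell_scores(adata, sig, r_max=r_max)


def quartile_split(sample_scores: pd.Series) -> pd.Series:
    """Stratify samples into lower / middle / upper quartile groups.

    Thresholds are the 25th and 75th percentiles (linear-interpolation
    quantiles).  Strictly below the lower threshold -> ``lower``; strictly
    above the upper -> ``upper``; ties at a threshold stay ``middle``.
    With fewer than 4 samples the split is undefined and raises.
    """
    if len(sample_scores) < 4:
        raise ValueError("need at least 4 samples for a quartile split")
    lo, hi = np.quantile(sample_scores.to_numpy(dtype=np.float64),
                         [0.25, 0.75])
    out = pd.Series(MIDDLE, index=sample_scores.index,
                    name=sample_scores.name)
    out[sample_scores < lo] = LOWER
    out[sample_scores > hi] = UPPER
    if not (out == LOWER).any() and not (out == UPPER).any():
        warnings.warn("all scores equal at the quartile thresholds; "
                      "lower and upper strata are empty")
    return out


def _exact_mwu_p(pooled_ranks: np.ndarray, n1: int, u_obs: float,
                 alternative: str) -> float:
    """Exact p by enumeration of all C(n, n1) group labellings."""
    n = pooled_ranks.size
    offset = n1 * (n1 + 1) / 2
    us = np.array([sum(c) - offset
                   for c in itertools.combinations(pooled_ranks, n1)])
    tol = 1e-9
    p_ge = float((us >= u_obs - tol).mean())
    p_le = float((us <= u_obs + tol).mean())
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def mann_whitney_u(x, y, alternative: str = "two-sided",
                   exact_max_n: int = 12) -> tuple[float, float, float]:
    """Mann-Whitney U test with tie handling; returns ``(U, W, p)``.

    ``U`` is the U statistic of the first sample, ``W`` its rank sum.
    For ``n1 + n2 <= exact_max_n`` the p-value is computed exactly by
    enumerating every group labelling of the pooled values; otherwise by
    the normal approximation with tie and continuity corrections.
    ``alternative = "greater"`` tests whether ``x`` tends to exceed ``y``.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    W = float(ranks[:n1].sum())
    U = W - n1 * (n1 + 1) / 2

    if n <= exact_max_n:
        p = _exact_mwu_p(ranks, n1, U, alternative)
        return U, W, p

    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((counts ** 3) - counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return U, W, 1.0
    sigma = np.sqrt(sigma2)
    if alternative == "greater":
        z = (U - mu - 0.5) / sigma
        p = float(norm.sf(z))
    elif alternative == "less":
        z = (U - mu + 0.5) / sigma
        p = float(norm.cdf(z))
    else:
        cc = 0.5 * np.sign(U - mu)
        z = (U - mu - cc) / sigma if U != mu else 0.0
        p = min(1.0, float(2.0 * norm.sf(abs(z))))
    return U, W, p


def spearman_cooccurrence(props: ProportionTable | pd.DataFrame
                          ) -> pd.DataFrame:
    """Pairwise Spearman rho between cluster fractions across samples.

    Zero-variance clusters yield NaN rows/columns (with a warning); the
    diagonal is fixed at 1.
    """
    frac = props.fractions if isinstance(props, ProportionTable) else props
    if len(frac) < 3:
        raise ValueError("need at least 3 samples for co-occurrence")
    constant = frac.columns[frac.nunique() <= 1]
    if len(constant):
        warnings.warn("zero-variance cluster(s) give undefined rho: "
                      f"{list(map(str, constant))}")
    M = frac.to_numpy(dtype=np.float64)
    R = np.apply_along_axis(rankdata, 0, M)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(R, rowvar=False)
    C = np.atleast_2d(C)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=frac.columns, columns=frac.columns)


def pcoa(dist: pd.DataFrame | np.ndarray, n_axes: int = 2
         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal-coordinates analysis (metric MDS).

    Double-centres ``-0.5 * D^2``, eigendecomposes, and embeds on the top
    positive eigenvalues: coordinates are eigenvectors scaled by the
    square root of their eigenvalues.  Negative eigenvalues (from
    non-Euclidean distances) are returned but never embedded.  Raises when
    no eigenvalue is positive.
    """
    D = dist.to_numpy(dtype=np.float64) if isinstance(dist, pd.DataFrame) \
        else np.asarray(dist, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12 * max(abs(evals[0]), 1.0), 0.0)
    n_pos = int((evals > tol).sum())
    if n_pos == 0:
        raise ValueError("no positive eigenvalues; distances carry no "
                         "Euclidean structure")
    m = min(n_axes, n_pos)
    coords = evecs[:, :m] * np.sqrt(evals[:m])
    labels = (dist.index if isinstance(dist, pd.DataFrame)
              else pd.RangeIndex(n))
    coord_df = pd.DataFrame(coords, index=labels,
                            columns=[f"PCo{i + 1}" for i in range(m)])
    return coord_df, evals


def composition_distance(props: ProportionTable | pd.DataFrame
                         ) -> pd.DataFrame:
    """Euclidean distances between samples' cluster-composition vectors."""
    frac = props.fractions if isinstance(props, ProportionTable) else props
    D = squareform(pdist(frac.to_numpy(dtype=np.float64), metric="euclidean"))
    return pd.DataFrame(D, index=frac.index, columns=frac.index)


def hierarchical_cluster_means(adata: ad.AnnData, cluster_key: str = "cluster",
                               method: str = "complete",
                               layer: str = "lognorm",
                               ) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of per-cluster mean expression profiles.

    Mean log-normalised expression per cluster, Euclidean distances,
    agglomeration with the requested linkage.  Clusters are processed in
    sorted label order so equal-distance merges resolve deterministically.
    Returns the SciPy linkage matrix and the leaf labels.
    """
    clusters = pd.Series(adata.obs[cluster_key], index=adata.obs_names)
    labels = sorted(map(str, clusters.dropna().unique()))
    if len(labels) < 2:
        raise ValueError("need at least two clusters")
    X = get_dense(adata, layer)
    means = np.stack([X[(clusters.astype(str) == cl).to_numpy()].mean(axis=0)
                      for cl in labels])
    Z = linkage(means, method=method, metric="euclidean")
    return Z, labels


def dendrogram_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a SciPy linkage matrix as a Newick string."""
    tree = to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{node.dist:.6g}"
        left, right = walk(node.left), walk(node.right)
        return f"({left},{right}):{node.dist:.6g}"

    return f"({walk(tree.left)},{walk(tree.right)});"


def marker_percentile_membership(adata: ad.AnnData, gene: str,
                                 cluster_key: str = "cluster",
                                 n_bins: int = 100,
                                 layer: str = "lognorm") -> pd.DataFrame:
    """Cluster composition along the expression percentiles of one marker.

    Cells positively expressing ``gene`` are ordered by expression and cut
    into ``n_bins`` equal-count bins; tied expression values stay together
    in the lower bin.  Each row of the result is one bin's cluster-
    membership fractions (summing to 1) plus the bin's cell count; bins
    emptied by tie merging are omitted.
    """
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} not in matrix")
    col = int(adata.var_names.get_loc(gene))
    expr = get_dense(adata, layer)[:, col]
    clusters = pd.Series(adata.obs[cluster_key],
                         index=adata.obs_names).astype(str)
    pos = expr > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError(f"gene {gene!r} is not expressed in any cell")
    if n_pos < n_bins:
        warnings.warn(f"only {n_pos} positive cells; reducing bins from "
                      f"{n_bins} to {n_pos}")
        n_bins = n_pos

    vals = expr[pos]
    labs = clusters[pos].to_numpy()
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    raw_bin = np.arange(n_pos) * n_bins // n_pos
    # ties keep the bin of their first (lowest-index) occurrence
    first = np.searchsorted(sorted_vals, sorted_vals, side="left")
    bins = raw_bin[first]

    df = pd.DataFrame({"bin": bins, "cluster": labs[order]})
    counts = (df.groupby(["bin", "cluster"], observed=True).size()
              .unstack(fill_value=0))
    n_per_bin = counts.sum(axis=1)
    out = counts.div(n_per_bin, axis=0)
    out.insert(0, "n_cells", n_per_bin)
    out.index.name = "percentile_bin"
    return out
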