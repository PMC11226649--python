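"""Differential cluster-composition testing between sample groups.

Cell-type fractions are variance-stabilised with the arcsin-square-root
transform and modelled per cluster by ordinary least squares on a
group-means design.  Residual variances are then shrunk towards a common
prior by empirical Bayes: a scaled-F prior with ``d0`` degrees of freedom
and scale ``s0^2`` is fitted to the observed log-variances by moment
matching on the digamma/trigamma scale, and each cluster's posterior
variance is the precision-weighted blend

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df).

Two groups give a moderated t statistic on ``d0 + df`` degrees of freedom;
more groups give a moderated F.  Benjamini-Hochberg adjustment across
clusters controls the FDR, with q < 0.1 the conventional significance
threshold in this pipeline.

Samples are treated as independent units; repeated samples per patient are
not modelled (a limitation, not an option).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

__all__ = [
    "ProportionTable",
    "ModeratedTestResult",
    "sample_cluster_proportions",
    "arcsin_sqrt_transform",
    "squeeze_variances",
    "moderated_test",
    "bh_adjust",
]


@dataclasses.dataclass
class ProportionTable:
    """Per-sample cluster fractions with sample-level metadata.

    ``fractions`` is samples x clusters and each row sums to 1;
    ``condition`` and ``n_cells`` are indexed by sample.
    """

    fractions: pd.DataFrame
    condition: pd.Series
    n_cells: pd.Series

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("per-sample fractions must sum to 1")
        if ((self.fractions < 0) | (self.fractions > 1)).any().any():
            raise ValueError("fractions must lie in [0, 1]")
        self.condition = self.condition.reindex(self.fractions.index)
        self.n_cells = self.n_cells.reindex(self.fractions.index)


@dataclasses.dataclass
class ModeratedTestResult:
    cluster: str
    groups: tuple[str, ...]
    statistic: float          # moderated t (2 groups) or F (>2 groups)
    df_residual: float
    d0: float                 # prior degrees of freedom (may be inf)
    s0_sq: float              # prior variance
    p: float
    q: float
    group_means: dict[str, float]       # transformed scale
    group_fractions: dict[str, float]   # raw fraction scale


def sample_cluster_proportions(cells: pd.DataFrame,
                               sample_key: str = "sample",
                               cluster_key: str = "cluster",
                               condition_key: str = "condition",
                               ) -> ProportionTable:
    """Cluster fractions per sample from a per-cell annotation table.

    Cells without a cluster label are ignored; samples left with no
    labelled cell are dropped with a warning.  Clusters absent from a
    sample get fraction 0.
    """
    tab = cells[[sample_key, cluster_key]].copy()
    n_total = tab.groupby(sample_key, observed=True).size()
    tab = tab.dropna(subset=[cluster_key])
    empty = n_total.index.difference(
        tab[sample_key].unique())
    if len(empty):
        warnings.warn(f"{len(empty)} sample(s) without labelled cells "
                      f"dropped: {sorted(map(str, empty))}")
    counts = (tab.groupby([sample_key, cluster_key], observed=True)
              .size().unstack(fill_value=0))
    counts.columns = counts.columns.astype(str)
    n_cells = counts.sum(axis=1)
    fractions = counts.div(n_cells, axis=0)
    if condition_key in cells.columns:
        condition = (cells.dropna(subset=[cluster_key])
                     .groupby(sample_key, observed=True)[condition_key]
                     .first())
    else:
        condition = pd.Series(index=fractions.index, dtype=object)
    return ProportionTable(fractions=fractions,
                           condition=condition.reindex(fractions.index),
                           n_cells=n_cells)


def arcsin_sqrt_transform(p):
    """Variance-stabilising transform ``asin(sqrt(p))``, [0,1] -> [0, pi/2]."""
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("proportions must lie in [0, 1]")
    return np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0)))


def _trigamma_inverse(y: float, tol: float = 1e-10,
                      max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing trigamma makes the Newton step with the tetragamma
    derivative globally convergent from the large-x asymptotic start
    ``x ~ 0.5 + 1/y``.
    """
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:          # trigamma(x) ~ 1/x^2 for small x
        return 1.0 / np.sqrt(y)
    if y < 1e-6:         # trigamma(x) ~ 1/x for large x
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def squeeze_variances(s2: Sequence[float], df: float
                      ) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of per-cluster residual variances.

    Fits a scaled-F prior to the observed sample variances ``s2`` (each on
    ``df`` residual degrees of freedom) by moment matching of
    ``e_g = log(s2_g) - digamma(df/2) + log(df/2)``: the prior degrees of
    freedom ``d0`` solve ``trigamma(d0/2) = var(e) - trigamma(df/2)``
    (sample variance, ddof=1), inverted by Newton iteration on the trigamma
    function.  When the spread of the log variances is no larger than
    expected from chi-square sampling noise alone, ``d0`` is infinite and
    every posterior variance collapses to the common value ``exp(mean(e))``.

    Returns ``(d0, s0_sq, s2_post)``.
    """
    s2 = np.asarray(s2, dtype=np.float64)
    if np.any(s2 <= 0) or not np.all(np.isfinite(s2)):
        raise ValueError("variances must be finite and > 0")
    if df <= 0:
        raise ValueError("residual df must be > 0")
    n = s2.size
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if n == 1:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        return d0, s0_sq, np.full(n, s0_sq)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
        return d0, s0_sq, np.full(n, s0_sq)
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, s2_post


def moderated_test(props: ProportionTable,
                   condition: pd.Series | None = None,
                   d0_override: float | None = None,
                   ) -> list[ModeratedTestResult]:
    """Moderated t/F test of cluster composition differences between groups.

    Per cluster, arcsin-sqrt transformed fractions are regressed on group
    indicators; residual variances are moderated jointly over all clusters
    via :func:`squeeze_variances`.  Two groups yield a two-sided moderated
    t on ``d0 + df`` degrees of freedom; more groups a moderated F on
    ``(k - 1, d0 + df)``.  Q-values are BH-adjusted across clusters.

    ``d0_override`` forces the prior degrees of freedom (``0`` disables
    moderation entirely, reproducing the classical tests); intended for
    calibration checks.
    """
    cond = props.condition if condition is None else condition
    cond = cond.reindex(props.fractions.index)
    if cond.isna().any():
        raise ValueError("condition label missing for some samples")
    groups = sorted(map(str, cond.unique()))
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    sizes = cond.astype(str).value_counts()
    small = [g for g in groups if sizes[g] < 2]
    if small:
        raise ValueError(f"condition(s) with fewer than 2 samples: {small}")

    Y = arcsin_sqrt_transform(props.fractions.to_numpy())  # samples x clusters
    gidx = [np.flatnonzero((cond.astype(str) == g).to_numpy())
            for g in groups]
    n, k = Y.shape[0], len(groups)
    df_res = n - k
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    means = np.stack([Y[ix].mean(axis=0) for ix in gidx])  # groups x clusters
    resid = Y.copy()
    for g, ix in enumerate(gidx):
        resid[ix] -= means[g]
    s2 = (resid ** 2).sum(axis=0) / df_res
    s2 = np.maximum(s2, 1e-300)

    if d0_override is None:
        d0, s0_sq, s2_post = squeeze_variances(s2, df_res)
    elif d0_override == 0:
        d0, s0_sq, s2_post = 0.0, float("nan"), s2
    else:
        d0 = float(d0_override)
        _, s0_sq, _ = squeeze_variances(s2, df_res)
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)

    df_total = d0 + df_res
    ns = np.array([len(ix) for ix in gidx], dtype=np.float64)
    raw_means = np.stack([props.fractions.to_numpy()[ix].mean(axis=0)
                          for ix in gidx])

    stats = np.empty(Y.shape[1])
    pvals = np.empty(Y.shape[1])
    if k == 2:
        se = np.sqrt(s2_post * (1.0 / ns[0] + 1.0 / ns[1]))
        stats = (means[1] - means[0]) / se
        pvals = 2.0 * t_dist.sf(np.abs(stats), df_total)
    else:
        grand = (ns @ means) / n
        ms_between = ((ns[:, None] * (means - grand) ** 2).sum(axis=0)
                      / (k - 1))
        stats = ms_between / s2_post
        pvals = f_dist.sf(stats, k - 1, df_total)
    qvals = bh_adjust(pvals)

    results = []
    for j, cl in enumerate(props.fractions.columns):
        results.append(ModeratedTestResult(
            cluster=str(cl), groups=tuple(groups),
            statistic=float(stats[j]), df_residual=float(df_res),
            d0=float(d0), s0_sq=float(s0_sq), p=float(pvals[j]),
            q=float(qvals[j]),
            group_means={g: float(means[i, j]) for i, g in enumerate(groups)},
            group_fractions={g: float(raw_means[i, j])
                             for i, g in enumerate(groups)},
        ))
    return results


def moderated_test_frame(results: list[ModeratedTestResult]) -> pd.DataFrame:
    """Flatten test results to a tidy DataFrame (one row per cluster)."""
    rows = []
    for r in results:
        row = dict(cluster=r.cluster, statistic=r.statistic,
                   df_residual=r.df_residual, d0=r.d0, s0_sq=r.s0_sq,
                   p=r.p, q=r.q)
        for g, m in r.group_means.items():
            row[f"mean_transformed_{g}"] = m
        for g, m in r.group_fractions.items():
            row[f"mean_fraction_{g}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * n / j`` on the sorted scale, capped at 1
    and mapped back to input order.  NaN entries propagate as NaN and are
    excluded from ``n``.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q
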