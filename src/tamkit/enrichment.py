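"""Covariate-adjusted gene ranking and preranked gene-set enrichment.

The ranking stage regresses per-gene log-CPM on an intercept, cancer-type
indicators and the binary response label, and ranks genes by the moderated
t statistic of the response coefficient (variance moderation reuses
:func:`tamkit.proportions.squeeze_variances`).  This is a linear-model
ranker, not a negative-binomial GLM: the enrichment stage only needs a
covariate-adjusted per-gene ordering.

Enrichment of a signature in the ranking uses the weighted Kolmogorov-
Smirnov running-sum statistic: walking the ranked list, hits add their
normalised weight ``|r|^w / sum_hits |r|^w`` and misses subtract
``1/(N - N_hits)``; the enrichment score (ES) is the running-sum value of
maximal absolute deviation.  Significance comes from a gene-permutation
null (random same-size gene sets); NES divides ES by the mean |null ES| of
matching sign, and p-values are floored at ``1/(n_perm + 1)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneSignature
from .proportions import bh_adjust, squeeze_variances

__all__ = [
    "EnrichmentResult",
    "rank_genes",
    "gsea_es",
    "gsea_permutation",
    "run_gsea_panel",
]


@dataclasses.dataclass
class EnrichmentResult:
    signature: str
    es: float
    nes: float
    p: float
    q: float
    n_perm: int
    n_hits: int
    leading_edge: tuple[str, ...]


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_genes(counts: pd.DataFrame, response: pd.Series,
               covariate: pd.Series | None = None,
               min_sample_frac: float = 0.2) -> pd.Series:
    """Rank genes by moderated-t association with a binary response.

    Parameters
    ----------
    counts
        Bulk raw counts, samples x genes.
    response
        Binary label per sample; booleans or two levels (the
        lexicographically larger level is treated as "response = 1").
    covariate
        Optional categorical covariate (e.g. cancer type) adjusted for via
        indicator columns.
    min_sample_frac
        Genes with nonzero counts in fewer than this fraction of samples
        are dropped before ranking.

    Returns a Series of moderated t statistics indexed by gene, sorted
    descending with ties left in stable input order.
    """
    response = response.reindex(counts.index)
    if response.isna().any():
        raise ValueError("response label missing for some samples")
    levels = sorted(map(str, response.unique()))
    if len(levels) != 2:
        raise ValueError(f"response must have exactly 2 levels, got {levels}")
    y = (response.astype(str) == levels[1]).to_numpy(dtype=np.float64)
    if y.sum() < 3 or (1 - y).sum() < 3:
        raise ValueError("need at least 3 samples per response group")

    keep = (counts > 0).mean(axis=0) >= min_sample_frac
    C = counts.loc[:, keep].to_numpy(dtype=np.float64)
    genes = counts.columns[keep]
    lib = C.sum(axis=1)
    logcpm = np.log2((C + 0.5) / (lib + 1.0)[:, None] * 1e6)

    cols = [np.ones_like(y)]
    if covariate is not None:
        cov = covariate.reindex(counts.index).astype(str)
        if cov.isna().any():
            raise ValueError("covariate missing for some samples")
        for lv in sorted(cov.unique())[1:]:
            cols.append((cov == lv).to_numpy(dtype=np.float64))
        for lv in sorted(cov.unique()):
            if response[cov == lv].nunique() < 2:
                raise ValueError(
                    f"response is constant within covariate level {lv!r}; "
                    "design is confounded")
    cols.append(y)
    X = np.column_stack(cols)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (confounded)")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ logcpm            # p x genes
    resid = logcpm - X @ beta
    df = n - p
    s2 = (resid ** 2).sum(axis=0) / df
    s2 = np.maximum(s2, 1e-300)
    d0, _s0, s2_post = squeeze_variances(s2, df)
    se = np.sqrt(s2_post * XtX_inv[-1, -1])
    t = beta[-1] / se
    ranked = pd.Series(t, index=genes, name="moderated_t")
    return ranked.sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def _es_from_positions(absw: np.ndarray, pos: np.ndarray, n_total: int
                       ) -> float:
    """Signed max-deviation ES for hits at sorted 0-based ``pos``.

    ``absw`` are |statistic|^weight for the full ranking.  The running sum
    is piecewise linear between hits, so its extrema occur immediately
    before or after a hit; both candidate sets are evaluated in O(m).
    """
    m = pos.size
    w = absw[pos]
    wsum = w.sum()
    if wsum == 0:
        w = np.ones(m)
        wsum = float(m)
    miss = 1.0 / (n_total - m)
    cw = np.cumsum(w) / wsum
    misses_before = pos - np.arange(m)          # misses preceding hit j
    after = cw - misses_before * miss           # value just after hit j
    before = np.concatenate(([0.0], cw[:-1])) - misses_before * miss
    cand = np.concatenate((after, before))
    return float(cand[np.argmax(np.abs(cand))])


def gsea_es(ranked: pd.Series, sig: GeneSignature, weight_exp: float = 1.0
            ) -> tuple[float, np.ndarray]:
    """Enrichment score of a signature in a ranked list, with the trace.

    Returns ``(ES, running_sum)`` where ``running_sum[i]`` is the value of
    the weighted KS walk after position ``i`` of the ranking.
    """
    if ranked.isna().any():
        raise ValueError("ranked statistics contain NaN")
    if ranked.index.duplicated().any():
        raise ValueError("ranked list has duplicate genes")
    in_sig = ranked.index.isin(sig.genes)
    n_hits = int(in_sig.sum())
    N = len(ranked)
    if n_hits == 0:
        raise ValueError(f"no genes of signature {sig.name!r} in the ranking")
    if n_hits == N:
        raise ValueError("signature covers the whole ranking")
    absw = np.abs(ranked.to_numpy()) ** weight_exp
    w = np.where(in_sig, absw, 0.0)
    wsum = w.sum()
    if wsum == 0:
        w = in_sig.astype(np.float64)
        wsum = float(n_hits)
    steps = np.where(in_sig, w / wsum, -1.0 / (N - n_hits))
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_permutation(ranked: pd.Series, sig: GeneSignature,
                     n_perm: int = 10_000, seed: int = 0,
                     weight_exp: float = 1.0) -> EnrichmentResult:
    """Gene-permutation significance for one signature.

    The null distribution is the ES of ``n_perm`` random gene sets of the
    same size.  The p-value counts sign-matched null scores at least as
    extreme as the observed ES, with the +1 floor; NES normalises by the
    mean |null ES| of matching sign.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, running = gsea_es(ranked, sig, weight_exp)
    in_sig = ranked.index.isin(sig.genes)
    m = int(in_sig.sum())
    N = len(ranked)
    absw = np.abs(ranked.to_numpy()) ** weight_exp

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(N, size=m, replace=False))
        null[i] = _es_from_positions(absw, pos, N)

    sign = 1.0 if es >= 0 else -1.0
    matched = null[np.sign(null) == sign] if es != 0 else null[null >= 0]
    if matched.size == 0:
        warnings.warn(f"signature {sig.name!r}: no sign-matched "
                      "permutations; NES undefined")
        nes = float("nan")
        p = 1.0 / (n_perm + 1)
    else:
        p = (1.0 + float((np.abs(matched) >= abs(es)).sum())) \
            / (1.0 + matched.size)
        nes = es / float(np.abs(matched).mean())

    # leading edge: hits at or before the extremum of the running sum
    peak = int(np.argmax(np.abs(running)))
    order = np.asarray(ranked.index)
    if es >= 0:
        leading = tuple(g for g in order[:peak + 1] if g in set(sig.genes))
    else:
        leading = tuple(g for g in order[peak:] if g in set(sig.genes))
    return EnrichmentResult(signature=sig.name, es=es, nes=float(nes),
                            p=float(p), q=float("nan"), n_perm=n_perm,
                            n_hits=m, leading_edge=leading)


def run_gsea_panel(ranked: pd.Series, sigs: Sequence[GeneSignature],
                   n_perm: int = 10_000, seed: int = 0,
                   weight_exp: float = 1.0) -> list[EnrichmentResult]:
    """Permutation GSEA over a signature panel with BH adjustment.

    Results are sorted by descending NES (NaN NES last); q-values are
    BH-adjusted across the panel.  Each signature gets an independent
    permutation stream derived from ``seed``.
    """
    if len(sigs) == 0:
        raise ValueError("empty signature panel")
    names = [s.name for s in sigs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate signature names in panel")
    seeds = np.random.SeedSequence(seed).spawn(len(sigs))
    results = [
        gsea_permutation(ranked, s, n_perm=n_perm,
                         seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                         weight_exp=weight_exp)
        for s, ss in zip(sigs, seeds)
    ]
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    results.sort(key=lambda r: (np.isnan(r.nes), -r.nes if not np.isnan(r.nes)
                                else 0.0))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [dict(signature=r.signature, es=r.es, nes=r.nes, p=r.p, q=r.q,
                 n_perm=r.n_perm, n_hits=r.n_hits,
                 leading_edge="|".join(r.leading_edge)) for r in results]
    return pd.DataFrame(rows)
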