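"""Signature-specificity metrics and the gold-standard gate.

A cluster signature derived from a macrophage-only atlas is only usable in
bulk expression data if it picks out its own cluster even when every other
cell type is present.  Two statistics quantify this on an all-cell-type
atlas scored per cell:

* ``metric1`` — the margin between the highest and second-highest cluster
  mean score, computed on the pooled (all cancer types) cluster means.
* ``metric2`` — the number of cancer types in which the best-hit cluster
  is the signature's own cluster.

A signature is gated "gold standard" when its own cluster is the overall
best hit, ``metric2 >= 3`` cancer types agree, and ``metric1`` is strictly
greater than 0.1.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SpecificityRecord", "specificity_metrics", "gate_gold_standard"]


@dataclasses.dataclass
class SpecificityRecord:
    signature: str
    own_cluster: str
    metric1: float                    # pooled best-vs-second margin (>= 0)
    metric2: int                      # cancer types whose best hit == own
    n_cancer_types: int
    best_hit_overall: str | None      # None on a tie for best
    metric1_by_cancer: dict[str, float]
    gold_standard: bool | None = None


def _best_and_margin(means: pd.Series) -> tuple[str | None, float]:
    """Best-scoring label and margin to the runner-up; ties -> (None, 0)."""
    if len(means) == 0:
        raise ValueError("no cluster means")
    if len(means) == 1:
        return str(means.index[0]), float(means.iloc[0])
    top = means.sort_values(ascending=False, kind="stable")
    if top.iloc[0] == top.iloc[1]:
        return None, 0.0
    return str(top.index[0]), float(top.iloc[0] - top.iloc[1])


def specificity_metrics(scores: pd.DataFrame, cells: pd.DataFrame,
                        own_cluster: Mapping[str, str],
                        cluster_key: str = "cluster",
                        cancer_key: str = "cancer_type",
                        ) -> list[SpecificityRecord]:
    """Compute both specificity metrics for each scored signature.

    Parameters
    ----------
    scores
        Cells x signatures score table (e.g. from
        :func:`tamkit.scoring.score_signatures`) on the all-cell-type atlas.
    cells
        Per-cell annotation indexed like ``scores`` with cluster and cancer
        type labels.
    own_cluster
        Map signature name -> the cluster the signature was derived from.
    """
    clusters = cells[cluster_key].reindex(scores.index).astype(str)
    cancers = cells[cancer_key].reindex(scores.index).astype(str)
    cancer_levels = sorted(cancers.unique())
    present = set(clusters.unique())

    records = []
    for name in scores.columns:
        if name not in own_cluster:
            raise ValueError(f"no own-cluster mapping for signature {name!r}")
        own = str(own_cluster[name])
        if own not in present:
            raise ValueError(
                f"own cluster {own!r} of signature {name!r} absent from data")
        col = scores[name]
        pooled_means = col.groupby(clusters, observed=True).mean()
        best_overall, metric1 = _best_and_margin(pooled_means)

        metric2 = 0
        m1_by_cancer: dict[str, float] = {}
        for ct in cancer_levels:
            sub = col[cancers == ct]
            means_ct = sub.groupby(clusters[cancers == ct],
                                   observed=True).mean()
            best_ct, margin_ct = _best_and_margin(means_ct)
            m1_by_cancer[ct] = margin_ct
            if best_ct is not None and best_ct == own:
                metric2 += 1
        records.append(SpecificityRecord(
            signature=str(name), own_cluster=own, metric1=metric1,
            metric2=metric2, n_cancer_types=len(cancer_levels),
            best_hit_overall=best_overall, metric1_by_cancer=m1_by_cancer))
    return records


def gate_gold_standard(records: list[SpecificityRecord],
                       m1_min: float = 0.1, m2_min: int = 3,
                       ) -> list[SpecificityRecord]:
    """Set ``gold_standard`` on each record (thresholds as printed rules).

    Gold standard requires the overall best hit to be the signature's own
    cluster, agreement in at least ``m2_min`` cancer types, and a pooled
    margin strictly greater than ``m1_min``.
    """
    for r in records:
        r.gold_standard = bool(
            r.metric2 >= m2_min
            and r.metric1 > m1_min
            and r.best_hit_overall == r.own_cluster)
    return records


def specificity_frame(records: list[SpecificityRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    return df.drop(columns=["metric1_by_cancer"]).assign(
        **{f"metric1_{ct}": [r.metric1_by_cancer.get(ct, np.nan)
                             for r in records]
           for ct in sorted({c for r in records
                             for c in r.metric1_by_cancer})})
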