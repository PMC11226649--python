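"""Shared data structures, file I/O and normalisation.

The in-memory container for expression data is :class:`anndata.AnnData`,
oriented cells x genes with raw integer counts in ``X``.  Per-cell
annotations (study, sample, patient, cancer type, tissue, cluster) live in
``adata.obs``; log-normalised expression is stored as the ``"lognorm"``
layer and is the input to every per-cell score and differential-expression
computation downstream.  Raw counts feed only the bulk ranking stage.

On disk the package speaks plain-text formats: MatrixMarket triplets
(``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, genes x cells by the 10x
convention), dense CSV, GMT gene-set files and CSV annotation tables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

logger = logging.getLogger("tamkit")

#: annotation columns recognised on a cell table; only ``sample`` and
#: ``cluster`` are required by specific operations, which check for them.
OBS_COLUMNS = ("study", "sample", "patient", "cancer_type", "tissue", "site",
               "cluster", "celltype", "condition")


@dataclasses.dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene list, optionally tied to the cluster it marks.

    Parameters
    ----------
    name
        Unique signature label, e.g. ``"18_ECMMac"``.
    genes
        Ordered gene symbols; must be unique and non-empty.
    own_cluster
        The cluster whose transcriptional state the signature summarises,
        when the signature was derived from a cluster (used by the
        specificity metrics).
    """

    name: str
    genes: tuple[str, ...]
    own_cluster: str | None = None

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclasses.dataclass
class AnalysisConfig:
    """Default parameters for every analysis stage.

    Attributes are grouped by stage; all can be overridden from YAML via
    :meth:`from_yaml`.  Units: ``r_max`` is a rank (genes), spatial
    thresholds are on the [0, 1] score scale, coordinates are micrometres.
    """

    # rank-based per-cell scoring
    r_max: int = 1500
    # control-bin module score
    module_n_bins: int = 24
    module_n_ctrl: int = 100
    # marker derivation
    marker_n_top: int = 10
    marker_min_pct: float = 0.1
    marker_min_log2fc: float = 0.25
    marker_q_max: float = 0.05
    # macrophage cluster selection
    k_sd: float = 1.0
    # gold-standard specificity gate
    m1_min: float = 0.1
    m2_min: int = 3
    # FDR significance threshold used throughout
    q_threshold: float = 0.1
    # preranked GSEA
    gsea_n_perm: int = 10_000
    gsea_weight: float = 1.0
    # spatial membership + neighbourhoods
    spatial_hi: float = 0.8
    spatial_lo: float = 0.4
    knn_k: int = 5
    # marker percentile profiling
    percentile_bins: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# signatures (GMT)
# ---------------------------------------------------------------------------

def read_signatures(path: str | Path) -> list[GeneSignature]:
    """Read gene signatures from a GMT file.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``.  Gene order
    is preserved; duplicate genes within a line are dropped (first occurrence
    wins) with a warning; duplicate signature names raise.
    """
    sigs: list[GeneSignature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise ValueError(f"duplicate signature name {name!r}")
            seen.add(name)
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"signature {name!r}: {len(genes) - len(deduped)} "
                    f"duplicated gene(s) removed")
            if not deduped:
                raise ValueError(f"{path}:{lineno}: signature {name!r} has "
                                 f"an empty gene list")
            sigs.append(GeneSignature(name, tuple(deduped)))
    return sigs


def write_signatures(sigs: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sigs:
            desc = s.own_cluster if s.own_cluster is not None else "na"
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_matrix(matrix_path: Path, orientation: str):
    """Return (csr cells x genes, gene_ids, cell_ids)."""
    if matrix_path.is_dir():
        mtx = matrix_path / "matrix.mtx"
        genes = matrix_path / "genes.tsv"
        barcodes = matrix_path / "barcodes.tsv"
        X = sp.csr_matrix(mmread(mtx))
        gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str)
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str)
        if orientation == "genes-by-cells":
            X = X.T.tocsr()
        elif orientation != "cells-by-genes":
            raise ValueError(f"unknown orientation {orientation!r}")
        return X, list(gene_ids), list(cell_ids)
    if matrix_path.suffix == ".mtx":
        raise ValueError(
            "bare .mtx given; pass the directory holding matrix.mtx, "
            "genes.tsv and barcodes.tsv")
    # dense CSV: first column cell ids, header gene ids
    df = pd.read_csv(matrix_path, index_col=0)
    return (sp.csr_matrix(df.to_numpy()), [str(g) for g in df.columns],
            [str(c) for c in df.index])


def read_dataset(matrix_path: str | Path, annotation_path: str | Path,
                 orientation: str = "genes-by-cells") -> ad.AnnData:
    """Load a count matrix and its per-cell annotation into one AnnData.

    Cells present in only one of the two inputs are dropped (with a logged
    count); an empty intersection or duplicated identifiers raise.
    """
    X, gene_ids, cell_ids = _read_matrix(Path(matrix_path), orientation)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in matrix")
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell ids in matrix")
    data = X.data if sp.issparse(X) else np.asarray(X)
    if data.size and ((data < 0).any() or np.any(data != np.round(data))):
        raise ValueError("raw counts must be non-negative integers")

    annot = pd.read_csv(annotation_path, dtype={"cell_id": str})
    if "cell_id" not in annot.columns:
        raise ValueError("annotation CSV needs a cell_id column")
    if annot["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in annotation")
    annot = annot.set_index("cell_id")

    keep = [c for c in cell_ids if c in annot.index]
    if not keep:
        raise ValueError("no overlap between matrix cells and annotation")
    n_drop_matrix = len(cell_ids) - len(keep)
    n_drop_annot = len(annot) - len(keep)
    if n_drop_matrix or n_drop_annot:
        logger.warning(
            "dropped %d matrix cell(s) and %d annotation row(s) without a "
            "partner", n_drop_matrix, n_drop_annot)

    pos = pd.Index(cell_ids).get_indexer(keep)
    adata = ad.AnnData(
        X=sp.csr_matrix(X[pos]),
        obs=annot.loc[keep].copy(),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
    )
    adata.obs_names = keep
    return adata


def write_dataset(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write MTX triplet (genes x cells) plus annotation.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X).T  # genes x cells on disk
    mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    obs = adata.obs.copy()
    obs.insert(0, "cell_id", adata.obs_names)
    obs.to_csv(outdir / "annotation.csv", index=False)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def lognormalize(adata: ad.AnnData, scale: float = 1e4,
                 layer: str = "lognorm") -> ad.AnnData:
    """Add a log-normalised layer: ``ln(1 + count / cell_total * scale)``.

    Cells with zero total get all-zero normalised values (with a warning).
    The raw matrix is untouched.  Returns ``adata`` for chaining.
    """
    X = sp.csr_matrix(adata.X, dtype=np.float64, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with zero total count; "
                      "their normalised values are 0")
        totals = np.where(zero, 1.0, totals)
    X = X.multiply((scale / totals)[:, None]).tocsr()
    X.data = np.log1p(X.data)
    adata.layers[layer] = X
    return adata


def get_dense(adata: ad.AnnData, layer: str | None = "lognorm") -> np.ndarray:
    """Dense float array of a layer (or ``X`` when ``layer`` is None)."""
    M = adata.X if layer is None else adata.layers[layer]
    if sp.issparse(M):
        return np.asarray(M.todense(), dtype=np.float64)
    return np.asarray(M, dtype=np.float64)


def resolve_signature_genes(var_names: Sequence[str], sig: GeneSignature,
                            min_frac: float = 0.5) -> list[str]:
    """Signature genes present in the matrix, in signature order.

    Missing genes are dropped with a warning; fewer than ``min_frac`` of the
    signature present (or none at all) raises — a mostly-absent signature
    cannot be scored meaningfully.  Matching is case-sensitive and exact.
    """
    index = set(map(str, var_names))
    present = [g for g in sig.genes if g in index]
    if not present:
        raise ValueError(f"no genes of signature {sig.name!r} in matrix")
    frac = len(present) / len(sig.genes)
    if frac < min_frac:
        raise ValueError(
            f"only {len(present)}/{len(sig.genes)} genes of signature "
            f"{sig.name!r} present (<{min_frac:.0%})")
    if frac < 1.0:
        warnings.warn(
            f"signature {sig.name!r}: {len(sig.genes) - len(present)} "
            f"gene(s) absent from matrix ({frac:.0%} present)")
    return present
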