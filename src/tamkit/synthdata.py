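"""Synthetic single-cell, bulk and spatial data with known ground truth.

Every downstream stage of the pipeline is exercisable on data from this
module, so each generator plants a configurable, recoverable signal:

* :func:`simulate_sc_atlas` — a multi-study single-cell atlas of
  negative-binomial counts with planted clusters, disjoint per-cluster
  marker genes (mean multiplied by ``2**marker_log2fc`` in the owning
  cluster), gene-wise multiplicative per-study batch factors, and
  Dirichlet sample compositions whose log-weights shift with the sample's
  condition.
* :func:`simulate_bulk_cohort` — a responder / non-responder bulk cohort
  with a cancer-type covariate and signature-linked expression shifts in
  responders.
* :func:`simulate_spatial` — spatial point patterns with circular niches
  of co-located cell types over a uniform background, plus lognormal-noise
  expression profiles per cell type.

All generators are deterministic given their config seed.  The negative
binomial is parameterised by mean and dispersion, variance
``mu + mu^2 * dispersion``, the standard overdispersion model for UMI
counts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .proportions import ProportionTable

__all__ = [
    "SCSimConfig", "SynthTruth", "simulate_sc_atlas",
    "BulkSimConfig", "simulate_bulk_cohort",
    "Niche", "SpatialSimConfig", "simulate_spatial",
    "default_spatial_config", "simulate_proportion_cohort",
]

_CANCER_TYPES = ("LUAD", "RCC", "GBM", "CRC", "BRCA", "SKCM", "LIHC", "OV")


# ---------------------------------------------------------------------------
# single-cell atlas
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SCSimConfig:
    """Single-cell atlas simulation parameters.

    Defaults are a desk-scale version of a multi-study pan-cancer atlas:
    a handful of studies, each contributing several samples of a few
    hundred cells, six planted clusters with ten disjoint markers each
    (4-fold upregulated), moderate study batch effects and overdispersed
    counts.  ``condition_effects`` maps condition -> cluster -> additive
    log-fold shift of that cluster's Dirichlet composition weight; the
    default is a two-condition null (no shift).
    """

    n_studies: int = 4
    n_samples_per_study: int = 6
    n_clusters: int = 6
    n_genes: int = 1500
    cells_per_sample: tuple[int, int] = (80, 200)
    markers_per_cluster: int = 10
    marker_log2fc: float = 2.0
    batch_sd: float = 0.3
    nb_dispersion: float = 0.5
    baseline_mean: float = 0.3
    condition_effects: dict[str, dict[str, float]] = dataclasses.field(
        default_factory=lambda: {"A": {}, "B": {}})
    composition_concentration: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        ints = dict(n_studies=self.n_studies,
                    n_samples_per_study=self.n_samples_per_study,
                    n_clusters=self.n_clusters, n_genes=self.n_genes,
                    markers_per_cluster=self.markers_per_cluster)
        for k, v in ints.items():
            if v < 1:
                raise ValueError(f"{k} must be >= 1, got {v}")
        lo, hi = self.cells_per_sample
        if lo < 1 or hi < lo:
            raise ValueError("cells_per_sample must be a valid (lo, hi) "
                             "range with lo >= 1")
        if self.marker_log2fc < 0:
            raise ValueError("marker_log2fc must be >= 0")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be >= 0")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("nb_dispersion and baseline_mean must be > 0")
        if self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError(
                f"{self.n_clusters} clusters x {self.markers_per_cluster} "
                f"markers exceed n_genes={self.n_genes}")
        if len(self.condition_effects) < 1:
            raise ValueError("need at least one condition")


@dataclasses.dataclass
class SynthTruth:
    """Ground truth of a simulated atlas."""

    cluster_of_cell: dict[str, str]
    marker_genes: dict[str, tuple[str, ...]]
    sample_condition: dict[str, str]
    planted_enriched_clusters: dict[str, tuple[str, ...]]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """Negative binomial with variance ``mean + mean^2 * dispersion``."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_sc_atlas(config: SCSimConfig
                      ) -> tuple[ad.AnnData, SynthTruth]:
    """Simulate a multi-study single-cell atlas with planted structure.

    Returns an AnnData (cells x genes, raw counts in ``X``, annotations in
    ``obs``) and the :class:`SynthTruth` used to generate it.  Sample
    conditions cycle deterministically through the configured conditions;
    each study is assigned a cancer type from a fixed palette.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cluster_names = [f"c{i}" for i in range(config.n_clusters)]
    conditions = sorted(config.condition_effects)

    marker_genes: dict[str, tuple[str, ...]] = {}
    mpc = config.markers_per_cluster
    for ci, cl in enumerate(cluster_names):
        marker_genes[cl] = tuple(genes[ci * mpc:(ci + 1) * mpc])

    # per-cluster mean profiles: baseline everywhere, markers upshifted
    base = np.full((config.n_clusters, n_genes), config.baseline_mean)
    fold = 2.0 ** config.marker_log2fc
    for ci in range(config.n_clusters):
        base[ci, ci * mpc:(ci + 1) * mpc] *= fold

    # per-study gene-wise multiplicative batch factors
    batch = np.ones((config.n_studies, n_genes))
    if config.batch_sd > 0:
        batch = rng.lognormal(0.0, config.batch_sd,
                              size=(config.n_studies, n_genes))

    alpha0 = config.composition_concentration
    blocks, obs_rows = [], []
    cluster_of_cell: dict[str, str] = {}
    sample_condition: dict[str, str] = {}
    cell_counter = 0
    sample_idx = 0
    for si in range(config.n_studies):
        study = f"study{si}"
        cancer = _CANCER_TYPES[si % len(_CANCER_TYPES)]
        for _ in range(config.n_samples_per_study):
            sample = f"sample{sample_idx:03d}"
            cond = conditions[sample_idx % len(conditions)]
            sample_idx += 1
            sample_condition[sample] = cond
            shifts = config.condition_effects[cond]
            alpha = np.array([alpha0 * np.exp(shifts.get(cl, 0.0))
                              for cl in cluster_names])
            comp = rng.dirichlet(alpha)
            lo, hi = config.cells_per_sample
            n_cells = int(rng.integers(lo, hi + 1))
            cl_idx = rng.choice(config.n_clusters, size=n_cells, p=comp)
            mu = base[cl_idx] * batch[si]
            counts = _nb_draw(rng, mu, config.nb_dispersion)
            blocks.append(sp.csr_matrix(counts))
            for ci in cl_idx:
                cell_id = f"cell{cell_counter:07d}"
                cell_counter += 1
                cluster_of_cell[cell_id] = cluster_names[ci]
                obs_rows.append(dict(
                    cell_id=cell_id, study=study, sample=sample,
                    patient=f"patient{sample}", cancer_type=cancer,
                    tissue="tumour", site="primary",
                    cluster=cluster_names[ci], condition=cond))

    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = ad.AnnData(X=sp.vstack(blocks).tocsr(), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    planted = {
        cond: tuple(cl for cl, s in sorted(shifts.items()) if s > 0)
        for cond, shifts in config.condition_effects.items()
    }
    truth = SynthTruth(cluster_of_cell=cluster_of_cell,
                       marker_genes=marker_genes,
                       sample_condition=sample_condition,
                       planted_enriched_clusters=planted)
    return adata, truth


def simulate_proportion_cohort(n_per_group: Mapping[str, int],
                               n_clusters: int = 8,
                               n_cells: int = 1000,
                               concentration: float = 10.0,
                               effects: Mapping[str, Mapping[str, float]]
                               | None = None,
                               seed: int = 0) -> ProportionTable:
    """Sample-level composition cohort without per-cell expression.

    Directly draws per-sample cluster compositions from condition-shifted
    Dirichlet distributions and realises them as multinomial cell counts —
    the composition model of :func:`simulate_sc_atlas` without the
    expression layer.  Intended for calibration and power studies of the
    composition test.
    """
    rng = np.random.default_rng(seed)
    clusters = [f"c{i}" for i in range(n_clusters)]
    effects = effects or {}
    rows, conds, totals = [], [], []
    samples = []
    i = 0
    for cond in sorted(n_per_group):
        shifts = effects.get(cond, {})
        alpha = np.array([concentration * np.exp(shifts.get(cl, 0.0))
                          for cl in clusters])
        for _ in range(n_per_group[cond]):
            comp = rng.dirichlet(alpha)
            counts = rng.multinomial(n_cells, comp)
            rows.append(counts / n_cells)
            conds.append(cond)
            totals.append(n_cells)
            samples.append(f"sample{i:03d}")
            i += 1
    fractions = pd.DataFrame(rows, index=samples, columns=clusters)
    return ProportionTable(fractions=fractions,
                           condition=pd.Series(conds, index=samples),
                           n_cells=pd.Series(totals, index=samples))


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BulkSimConfig:
    """Bulk responder / non-responder cohort simulation parameters.

    Defaults emulate an immune-checkpoint-inhibitor cohort at desk scale:
    ~120 patients across five cancer types with a ~25% response rate.
    ``signatures`` maps signature name -> gene tuple over the simulated
    gene universe; ``signature_effect_log2fc`` gives the mean log2 shift
    of those genes in responders.
    """

    n_samples: int = 120
    n_genes: int = 2000
    cancer_types: tuple[str, ...] = ("bladder", "lung", "melanoma",
                                     "renal", "gastric")
    response_rate: float = 0.25
    signatures: dict[str, tuple[str, ...]] = dataclasses.field(
        default_factory=dict)
    signature_effect_log2fc: dict[str, float] = dataclasses.field(
        default_factory=dict)
    library_size_mean: float = 2e5
    nb_dispersion: float = 0.3
    cancer_effect_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.response_rate < 1:
            raise ValueError("response_rate must lie in (0, 1)")
        if self.n_samples < 6 or self.n_genes < 10:
            raise ValueError("cohort too small to simulate")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion and library size must be > 0")
        for name, eff in self.signature_effect_log2fc.items():
            if name not in self.signatures:
                raise ValueError(f"effect given for unknown signature "
                                 f"{name!r}")
            if not np.isfinite(eff):
                raise ValueError(f"effect for {name!r} must be finite")


def simulate_bulk_cohort(config: BulkSimConfig
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a bulk RNA-seq cohort with signature-linked response shifts.

    Returns ``(counts, meta)``: counts samples x genes (integer), meta with
    ``sample``, ``cancer_type`` and boolean ``response`` columns.  Genes of
    a signature with a configured effect have their negative-binomial mean
    multiplied by ``2**effect`` in responders.  Signature genes outside
    the simulated gene universe raise, listing the offenders.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    gene_set = set(genes)
    for name, sig_genes in config.signatures.items():
        missing = [g for g in sig_genes if g not in gene_set]
        if missing:
            raise ValueError(f"signature {name!r} has unknown genes: "
                             f"{missing}")

    rel = rng.lognormal(0.0, 1.0, size=config.n_genes)
    rel /= rel.sum()
    ct_offsets = {
        ct: rng.lognormal(0.0, config.cancer_effect_sd, size=config.n_genes)
        if config.cancer_effect_sd > 0 else np.ones(config.n_genes)
        for ct in config.cancer_types
    }

    effect_mult = np.ones(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name, eff in config.signature_effect_log2fc.items():
        for g in config.signatures[name]:
            effect_mult[gene_pos[g]] *= 2.0 ** eff

    sample_ids = [f"bulk{i:04d}" for i in range(config.n_samples)]
    cancers = [config.cancer_types[i % len(config.cancer_types)]
               for i in range(config.n_samples)]
    response = rng.random(config.n_samples) < config.response_rate
    # guarantee both groups are populated at any realised rate
    if response.sum() < 3:
        response[:3] = True
    if (~response).sum() < 3:
        response[-3:] = False

    counts = np.empty((config.n_samples, config.n_genes), dtype=np.int64)
    for i in range(config.n_samples):
        mu = rel * config.library_size_mean * ct_offsets[cancers[i]]
        if response[i]:
            mu = mu * effect_mult
        counts[i] = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=genes)
    meta = pd.DataFrame({"sample": sample_ids, "cancer_type": cancers,
                         "response": response}).set_index("sample")
    return counts_df, meta


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Niche:
    """A circular niche: centre (µm), radius (µm), cell count and mixture."""

    center: tuple[float, float]
    radius: float
    n_cells: int
    mixture: dict[str, float]

    def validate(self) -> None:
        if self.radius <= 0:
            raise ValueError("niche radius must be > 0")
        if self.n_cells < 0:
            raise ValueError("niche n_cells must be >= 0")
        total = sum(self.mixture.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("niche mixture must sum to 1")


@dataclasses.dataclass
class SpatialSimConfig:
    """Spatial point-pattern simulation parameters.

    ``arena`` is (width, height) in µm; background cells arrive as a
    Poisson process with ``background_density`` cells/µm² and draw their
    type from ``background_mixture`` (uniform over profiled cell types
    when None).  Expression per cell is the cell type's marker profile
    times lognormal noise.
    """

    arena: tuple[float, float] = (1000.0, 1000.0)
    niches: list[Niche] = dataclasses.field(default_factory=list)
    background_density: float = 5e-4
    background_mixture: dict[str, float] | None = None
    celltype_marker_profiles: dict[str, dict[str, float]] = \
        dataclasses.field(default_factory=dict)
    baseline_expression: float = 0.05
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        w, h = self.arena
        if w <= 0 or h <= 0:
            raise ValueError("arena dimensions must be > 0")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        if not self.celltype_marker_profiles:
            raise ValueError("need at least one cell-type profile")
        for niche in self.niches:
            niche.validate()
            unknown = set(niche.mixture) - set(self.celltype_marker_profiles)
            if unknown:
                raise ValueError(f"niche mixture has unprofiled cell types: "
                                 f"{sorted(unknown)}")
        if self.background_mixture is not None:
            if not np.isclose(sum(self.background_mixture.values()), 1.0,
                              atol=1e-9):
                raise ValueError("background mixture must sum to 1")


def default_spatial_config(seed: int = 0) -> SpatialSimConfig:
    """Two-niche lung-tumour-like design: an ECM-macrophage/fibroblast
    niche and an interferon-gamma-macrophage/T-cell niche over a mixed
    background, with collagen / chemokine / T-cell marker profiles."""
    profiles = {
        "TAM_ECM": {"CD68": 3.0, "COL1A1": 2.5, "COL1A2": 2.5,
                    "COL3A1": 2.0, "SPARC": 1.5},
        "TAM_IFNG": {"CD68": 3.0, "CXCL9": 2.5, "CXCL10": 2.0,
                     "STAT1": 1.5},
        "TAM_other": {"CD68": 3.0, "LYZ": 1.5},
        "fibroblast": {"COL1A1": 3.0, "COL1A2": 3.0, "COL3A1": 2.5,
                       "PDGFRB": 2.0},
        "T_cell": {"CD3D": 3.0, "CD3E": 2.5, "TRAC": 2.0, "CD8A": 1.5},
        "cancer_cell": {"EPCAM": 3.0, "KRT18": 2.5},
        "neutrophil": {"S100A8": 3.0, "S100A9": 2.5},
        "NK_cell": {"NKG7": 3.0, "GNLY": 2.5},
    }
    niches = [
        Niche(center=(250.0, 500.0), radius=150.0, n_cells=250,
              mixture={"TAM_ECM": 0.5, "fibroblast": 0.5}),
        Niche(center=(750.0, 500.0), radius=150.0, n_cells=250,
              mixture={"TAM_IFNG": 0.5, "T_cell": 0.5}),
    ]
    return SpatialSimConfig(
        arena=(1000.0, 1000.0), niches=niches, background_density=5e-4,
        background_mixture={"TAM_other": 0.3, "cancer_cell": 0.4,
                            "neutrophil": 0.15, "NK_cell": 0.15},
        celltype_marker_profiles=profiles, seed=seed)


def simulate_spatial(config: SpatialSimConfig) -> pd.DataFrame:
    """Simulate a spatial cell table (cell_id, x, y, celltype, genes...).

    Niche cells are placed uniformly within their disc, background cells
    uniformly over the arena; a simulation yielding zero cells raises.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.arena
    celltypes = sorted(config.celltype_marker_profiles)
    genes = sorted({g for prof in config.celltype_marker_profiles.values()
                    for g in prof})

    xs, ys, types = [], [], []
    for niche in config.niches:
        if niche.n_cells == 0:
            continue
        r = niche.radius * np.sqrt(rng.random(niche.n_cells))
        theta = rng.random(niche.n_cells) * 2 * np.pi
        xs.append(niche.center[0] + r * np.cos(theta))
        ys.append(niche.center[1] + r * np.sin(theta))
        mix_types = sorted(niche.mixture)
        probs = np.array([niche.mixture[t] for t in mix_types])
        types.append(rng.choice(mix_types, size=niche.n_cells, p=probs))

    n_bg = int(rng.poisson(config.background_density * w * h))
    if n_bg:
        xs.append(rng.random(n_bg) * w)
        ys.append(rng.random(n_bg) * h)
        if config.background_mixture is None:
            bg_types, bg_probs = celltypes, None
        else:
            bg_types = sorted(config.background_mixture)
            bg_probs = np.array([config.background_mixture[t]
                                 for t in bg_types])
        types.append(rng.choice(bg_types, size=n_bg, p=bg_probs))

    if not xs:
        raise ValueError("simulation produced zero cells")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ct = np.concatenate(types)
    n = x.size

    mean_matrix = np.full((len(celltypes), len(genes)),
                          config.baseline_expression)
    for ti, t in enumerate(celltypes):
        for g, m in config.celltype_marker_profiles[t].items():
            mean_matrix[ti, genes.index(g)] = m
    t_idx = np.array([celltypes.index(t) for t in ct])
    noise = rng.lognormal(0.0, config.noise_sd, size=(n, len(genes))) \
        if config.noise_sd > 0 else np.ones((n, len(genes)))
    expr = mean_matrix[t_idx] * noise

    table = pd.DataFrame({
        "cell_id": [f"spot{i:06d}" for i in range(n)],
        "x": x, "y": y, "celltype": ct,
    })
    for gi, g in enumerate(genes):
        table[g] = expr[:, gi]
    return table
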