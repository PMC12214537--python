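"""Synthetic single-cell and bulk data with the study's effect structure.

The single-cell generator emulates a two-arm (disturbed-flow vs normal-flow)
mouse carotid artery experiment: seven canonical vascular cell types with
planted marker genes, negative-binomial UMI counts with lognormal library-size
variation, and three planted effects that mirror the study design —

* elevated cell-to-cell transcriptional noise in designated types under
  disturbed flow (gene-wise lognormal jitter of each cell's mean vector),
* phenotype modulation of VSMCs under disturbed flow (extracellular-matrix
  genes up, contractile genes down, symmetric log-fold shift),
* cardiovascular risk genes boosted in designated types.

The bulk generator emulates paired lesion cohorts (early vs advanced,
IPH vs non-IPH, stable vs ruptured) with a log2-scale signature shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .io import BulkDataset, CountDataset, GeneSetCollection

__all__ = [
    "SimConfig",
    "CELL_TYPES",
    "TYPE_MARKERS",
    "MODULATED_GENES",
    "CONTRACTILE_GENES",
    "DEFAULT_RISK_GENES",
    "MITO_GENES",
    "planted_genes",
    "generate_sc_dataset",
    "generate_bulk_cohort",
]

CELL_TYPES = (
    "endothelial",
    "VSMC",
    "fibroblast",
    "pericyte",
    "macrophage",
    "granulocyte",
    "T cell",
)

# Canonical markers of the seven major artery cell types.
TYPE_MARKERS: dict[str, list[str]] = {
    "endothelial": ["Pecam1", "Vwf"],
    "VSMC": ["Tagln", "Myh11"],
    "fibroblast": ["Lum", "Dcn"],
    "pericyte": ["Rgs5", "Pdgfrb"],
    "macrophage": ["C1qa", "Lyz2"],
    "granulocyte": ["S100a8", "S100a9"],
    "T cell": ["Cd3g", "Trbc2"],
}

# VSMC phenotype-modulation signature: ECM/fibroblast-like vs contractile.
MODULATED_GENES = ["Lum", "Dcn", "Fn1", "Bgn", "Mmp2", "Col1a1", "Tnfrsf11b"]
CONTRACTILE_GENES = ["Acta2", "Tagln", "Myh11", "Myl6", "Myl9"]

# Small demo set of frequently studied GWAS cardiovascular risk genes.
DEFAULT_RISK_GENES = [
    "Edn1", "Nos3", "Pcsk9", "Fn1", "Hdac9", "Apob", "Apoe", "Vegfa",
    "Ldlr", "Lpl", "Cdkn2b", "Sort1", "Il6r", "Mmp3", "Lpa",
]

MITO_GENES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Co3", "mt-Atp6", "mt-Atp8",
    "mt-Cytb", "mt-Nd3", "mt-Nd4", "mt-Nd4l", "mt-Nd5", "mt-Nd6",
]

GROUPS = ("d-flow", "n-flow")


@dataclass
class SimConfig:
    """Parameters of the synthetic single-cell experiment.

    noise_inflation maps cell type -> SD (sigma) of the gene-wise lognormal
    mean jitter applied to d-flow cells of that type only; 0 means no planted
    noise. ``noise_base_sd`` is an optional shared jitter SD applied to every
    cell of both groups (default 0). The jitter is mean-centered
    (exp(eps - sigma^2/2)), so marginal mean profiles are preserved at any
    sigma. risk_gene_boost maps cell type -> log-fold boost of the risk genes
    in that type. modulation_shift is the symmetric log-fold shift of
    modulated (up) and contractile (down) genes in d-flow VSMCs.
    """

    n_cell_types: int = 7
    cells_per_type_per_group: int = 200
    n_genes: int = 2000
    n_marker_genes_per_type: int = 20
    baseline_mean: float = 2.0
    dispersion: float = 10.0  # NB inverse-dispersion theta
    marker_fold: float = 8.0
    mito_fraction: float = 0.05
    noise_base_sd: float = 0.0
    noise_inflation: dict[str, float] = field(default_factory=lambda: {"endothelial": 0.5})
    modulation_shift: float = 0.5
    risk_gene_boost: dict[str, float] = field(default_factory=lambda: {"fibroblast": 1.0})
    risk_genes: list[str] = field(default_factory=lambda: list(DEFAULT_RISK_GENES))
    library_cv: float = 0.3
    n_samples_per_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_types", "cells_per_type_per_group", "n_genes",
                     "n_marker_genes_per_type", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_cell_types > len(CELL_TYPES):
            raise ValidationError(f"at most {len(CELL_TYPES)} cell types supported")
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be >= 1")
        if not 0 <= self.mito_fraction < 1:
            raise ValidationError("mito_fraction must be in [0, 1)")
        if any(v < 0 for v in self.noise_inflation.values()):
            raise ValidationError("noise_inflation values must be >= 0")
        if self.noise_base_sd < 0:
            raise ValidationError("noise_base_sd must be >= 0")
        if self.modulation_shift < 0:
            raise ValidationError("modulation_shift must be >= 0")
        if any(v < 0 for v in self.risk_gene_boost.values()):
            raise ValidationError("risk_gene_boost values must be >= 0")
        planted_genes(self)  # raises if the gene universe cannot host the plan

    @property
    def cell_types(self) -> tuple[str, ...]:
        return CELL_TYPES[: self.n_cell_types]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _gene_universe(cfg: SimConfig) -> list[str]:
    """Deterministic gene name list: named biology first, filler genes after."""
    named: dict[str, None] = {}
    for t in cfg.cell_types:
        for g in TYPE_MARKERS[t]:
            named[g] = None
    for g in MODULATED_GENES + CONTRACTILE_GENES + list(cfg.risk_genes) + MITO_GENES:
        named[g] = None
    if len(named) > cfg.n_genes:
        raise ValidationError("n_genes too small for the named gene complement")
    filler = [f"Gene{i:04d}" for i in range(1, cfg.n_genes - len(named) + 1)]
    return list(named) + filler


def planted_genes(cfg: SimConfig) -> dict[str, object]:
    """Ground truth of the simulation: which genes carry which planted role."""
    genes = _gene_universe(cfg)
    gene_index = {g: i for i, g in enumerate(genes)}
    markers: dict[str, list[str]] = {}
    filler_cursor = 0
    filler = [g for g in genes if g.startswith("Gene")]
    for t in cfg.cell_types:
        base = list(TYPE_MARKERS[t])
        if t == "VSMC":
            base += [g for g in CONTRACTILE_GENES if g not in base]
        if t == "fibroblast":
            base += [g for g in MODULATED_GENES if g not in base]
        need = max(0, cfg.n_marker_genes_per_type - len(base))
        extra = filler[filler_cursor : filler_cursor + need]
        if len(extra) < need:
            raise ValidationError("more marker genes requested than genes available")
        filler_cursor += need
        markers[t] = (base + extra)[: cfg.n_marker_genes_per_type]
    return {
        "genes": genes,
        "gene_index": gene_index,
        "markers": markers,
        "risk_genes": [g for g in cfg.risk_genes if g in gene_index],
        "modulated": MODULATED_GENES,
        "contractile": CONTRACTILE_GENES,
        "mito": [g for g in MITO_GENES if g in gene_index],
        "noise_inflation": dict(cfg.noise_inflation),
        "modulation_shift": cfg.modulation_shift,
        "risk_gene_boost": dict(cfg.risk_gene_boost),
    }


def marker_gene_sets(cfg: SimConfig) -> GeneSetCollection:
    """Canonical marker map usable by annotate_clusters."""
    return GeneSetCollection({t: TYPE_MARKERS[t] for t in cfg.cell_types})


def _type_profiles(cfg: SimConfig, truth: dict, rng: np.random.Generator) -> dict[str, dict[str, np.ndarray]]:
    """Per (type, group) mean relative-expression profiles (sum-normalized later)."""
    genes = truth["genes"]
    idx = truth["gene_index"]
    n = len(genes)
    # Gene-level baseline heterogeneity shared by all types.
    base = cfg.baseline_mean * rng.lognormal(mean=0.0, sigma=0.5, size=n)
    mito_idx = [idx[g] for g in truth["mito"]]
    profiles: dict[str, dict[str, np.ndarray]] = {}
    for t in cfg.cell_types:
        mu = base.copy()
        mu[[idx[g] for g in truth["markers"][t]]] *= cfg.marker_fold
        boost = cfg.risk_gene_boost.get(t, 0.0)
        if boost > 0:
            mu[[idx[g] for g in truth["risk_genes"]]] *= np.exp(boost)
        per_group: dict[str, np.ndarray] = {}
        for grp in GROUPS:
            m = mu.copy()
            if t == "VSMC" and grp == "d-flow" and cfg.modulation_shift > 0:
                m[[idx[g] for g in truth["modulated"]]] *= np.exp(cfg.modulation_shift)
                m[[idx[g] for g in truth["contractile"]]] *= np.exp(-cfg.modulation_shift)
            # Pin mitochondrial genes to mito_fraction of the library.
            if mito_idx and cfg.mito_fraction > 0:
                non_mito_mass = m.sum() - m[mito_idx].sum()
                m[mito_idx] = (
                    cfg.mito_fraction * non_mito_mass / (1 - cfg.mito_fraction) / len(mito_idx)
                )
            per_group[grp] = m
        profiles[t] = per_group
    return profiles


def generate_sc_dataset(cfg: SimConfig) -> CountDataset:
    """Draw a CountDataset under the configured study conditions.

    Deterministic for a fixed ``cfg.seed``. Cells are assigned round-robin to
    ``n_samples_per_group`` samples ("mice") within each group.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = planted_genes(cfg)
    genes = truth["genes"]
    profiles = _type_profiles(cfg, truth, rng)
    expected_library = cfg.baseline_mean * cfg.n_genes
    sigma_lib = np.sqrt(np.log(1 + cfg.library_cv**2))

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[tuple[str, str, str]] = []
    for grp in GROUPS:
        for t in cfg.cell_types:
            n_cells = cfg.cells_per_type_per_group
            p = profiles[t][grp]
            p = p / p.sum()
            lib = expected_library * rng.lognormal(-(sigma_lib**2) / 2, sigma_lib, size=n_cells)
            mean = lib[:, None] * p[None, :]
            sd = cfg.noise_base_sd
            if grp == "d-flow":
                sd = float(np.hypot(sd, cfg.noise_inflation.get(t, 0.0)))
            if sd > 0:
                eps = rng.normal(0.0, sd, size=mean.shape)
                mean = mean * np.exp(eps - sd**2 / 2)
            theta = cfg.dispersion
            lam = rng.gamma(theta, mean / theta)
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts.astype(np.int64)))
            for i in range(n_cells):
                meta_rows.append((grp, f"{grp}-m{i % cfg.n_samples_per_group + 1}", t))
    counts = sp.vstack(blocks).T.tocsr()  # genes x cells
    cell_ids = np.array([f"cell{i:05d}" for i in range(counts.shape[1])], dtype=object)
    cell_meta = pd.DataFrame(
        meta_rows, columns=["group", "sample_id", "cell_type"], index=pd.Index(cell_ids, name="barcode")
    )
    return CountDataset(
        counts=counts,
        gene_ids=np.array(genes, dtype=object),
        cell_ids=cell_ids,
        cell_meta=cell_meta,
    )


def generate_bulk_cohort(
    n_pairs: int,
    signature_genes: list[str],
    effect_size: float,
    seed: int = 0,
    groups: tuple[str, str] = ("early", "advanced"),
    n_background_genes: int = 300,
    noise_sd: float = 0.5,
    pair_sd: float = 0.7,
) -> BulkDataset:
    """Paired two-arm bulk cohort on log2 scale with a planted signature shift.

    The second group name is the affected arm: its samples carry an additive
    ``effect_size`` (log2 units) on every signature gene. Samples within a pair
    share a random intercept so paired tests gain power, as in a
    patient-matched lesion design.
    """
    if n_pairs < 2:
        raise ValidationError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    background = [f"Bulk{i:04d}" for i in range(1, n_background_genes + 1)]
    genes = list(dict.fromkeys(list(signature_genes) + background))
    n_genes = len(genes)
    base = rng.uniform(5.0, 10.0, size=n_genes)
    sig_mask = np.isin(genes, list(signature_genes))

    rows, meta = [], []
    for pair in range(n_pairs):
        intercept = rng.normal(0.0, pair_sd, size=n_genes)
        for gi, grp in enumerate(groups):
            vals = base + intercept + rng.normal(0.0, noise_sd, size=n_genes)
            if gi == 1:
                vals = vals + effect_size * sig_mask
            rows.append(vals)
            meta.append((grp, f"pair{pair + 1:02d}"))
    sample_ids = [f"s{i + 1:03d}" for i in range(len(rows))]
    expr = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"), columns=genes)
    sample_meta = pd.DataFrame(meta, columns=["group", "pair_id"], index=expr.index)
    return BulkDataset(expr=expr, sample_meta=sample_meta, is_log2=True)
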