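"""QC filtering, normalization, HVG selection, clustering, annotation and
the two downsampling operations (UMIs per cell, cells per group).

QC boundary semantics follow the strict-inequality removal rule: a cell is
discarded only when detected genes < min_genes, detected genes > max_genes,
or mitochondrial fraction > max_mito — boundary cells are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .io import CountDataset, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("flowsc")

__all__ = [
    "QCThresholds",
    "QCReport",
    "qc_filter",
    "lognormalize",
    "select_hvg",
    "embed_and_cluster",
    "annotate_clusters",
    "downsample_umis",
    "downsample_cells",
]


@dataclass
class QCThresholds:
    min_genes: int = 300
    max_genes: int = 5000
    max_mito: float = 0.10

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if not 0 < self.max_mito <= 1:
            raise ValidationError("max_mito must be in (0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_low_genes: int
    removed_high_genes: int
    removed_high_mito: int
    skipped_stages: list[str] = field(
        default_factory=lambda: ["doublet_removal", "batch_correction"]
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_input", "n_kept", "removed_low_genes",
                    "removed_high_genes", "removed_high_mito", "skipped_stages",
                ],
                "value": [
                    self.n_input, self.n_kept, self.removed_low_genes,
                    self.removed_high_genes, self.removed_high_mito,
                    ";".join(self.skipped_stages),
                ],
            }
        )


def qc_filter(ds: CountDataset, thr: QCThresholds | None = None) -> tuple[CountDataset, QCReport]:
    """Remove low-quality cells; genes are left untouched.

    Removal criteria (a cell may trip several; each is counted independently in
    the report): detected genes < min_genes, detected genes > max_genes,
    mito fraction > max_mito.
    """
    thr = thr or QCThresholds()
    detected = ds.detected_genes()
    mito = ds.mito_fraction()
    low = detected < thr.min_genes
    high = detected > thr.max_genes
    mhigh = mito > thr.max_mito
    keep = ~(low | high | mhigh)
    if not keep.any():
        raise ValidationError("empty after QC: no cell passes the thresholds")
    report = QCReport(
        n_input=ds.n_cells,
        n_kept=int(keep.sum()),
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_high_mito=int(mhigh.sum()),
    )
    return ds.subset_cells(keep), report


def lognormalize(ds: CountDataset, scale: float = 1e4) -> ExpressionMatrix:
    """log CP-scale normalization: value = ln(1 + scale * count / cell_total).

    All-zero cells map to all-zero columns (with a warning) rather than NaN.
    """
    totals = ds.cell_totals().astype(float)
    zero_cells = totals == 0
    if zero_cells.any():
        logger.warning("%d all-zero cells normalized to zero columns", int(zero_cells.sum()))
        totals[zero_cells] = 1.0
    mat = ds.counts.tocsc().astype(float)
    # scale columns by scale/total, then log1p on the nonzeros
    mat = mat @ sp.diags(scale / totals)
    mat.data = np.log1p(mat.data)
    return ExpressionMatrix(
        values=mat.tocsr(),
        gene_ids=ds.gene_ids,
        cell_ids=ds.cell_ids,
        cell_meta=ds.cell_meta,
        normalization=f"logCP{scale:g}",
    )


def select_hvg(expr: ExpressionMatrix, n: int) -> list[str]:
    """Top-n genes by dispersion (variance/mean of normalized values).

    Ties (and the all-zero dispersion-0 genes) resolve by gene order, so the
    selection is deterministic.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n > expr.n_genes:
        raise ValidationError("n exceeds the number of genes")
    v = expr.values
    mean = np.asarray(v.mean(axis=1)).ravel()
    sq = np.asarray(v.multiply(v).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")  # stable: ties by gene order
    return [expr.gene_ids[i] for i in order[:n]]


def embed_and_cluster(
    expr: ExpressionMatrix,
    n_pcs: int = 20,
    resolution: float = 0.5,
    n_neighbors: int = 15,
    hvg: list[str] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """PCA on (HVG-restricted, gene-standardized) values, kNN graph, Leiden.

    Returns one string label per cell; deterministic for a fixed seed.
    """
    import anndata
    import scanpy as sc

    if expr.n_cells < 2:
        raise ValidationError("need at least 2 cells to cluster")
    if hvg is not None:
        gene_pos = expr.gene_index().get_indexer(hvg)
        if (gene_pos < 0).any():
            raise ValidationError("hvg contains genes absent from the matrix")
        X = expr.values[gene_pos].T.toarray()
    else:
        X = expr.values.T.toarray()
    # gene standardization (zero-variance genes left at zero)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    n_pcs_eff = min(n_pcs, X.shape[0] - 1, X.shape[1])
    if n_pcs_eff < n_pcs:
        logger.warning("reducing n_pcs from %d to %d (too few cells/genes)", n_pcs, n_pcs_eff)
    ad = anndata.AnnData(X=X.astype(np.float32))
    sc.pp.pca(ad, n_comps=n_pcs_eff, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(ad, n_neighbors=min(n_neighbors, X.shape[0] - 1), random_state=seed)
    sc.tl.leiden(
        ad,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    return ad.obs["leiden"].astype(str).to_numpy()


def annotate_clusters(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    marker_map: GeneSetCollection,
    tie_tol: float = 1e-9,
) -> dict[str, str]:
    """Assign each cluster the type whose markers have the highest mean expression.

    A winning margin below ``tie_tol`` (including the all-zero case) yields
    "unassigned".
    """
    if len(marker_map) == 0:
        raise ValidationError("marker_map is empty")
    labels = np.asarray(labels)
    gene_index = expr.gene_index()
    set_scores: dict[str, dict[str, float]] = {}
    dense = None
    for cluster in pd.unique(labels):
        mask = labels == cluster
        if dense is None:
            dense = expr.values.tocsc()
        sub = dense[:, np.flatnonzero(mask)]
        cluster_mean = np.asarray(sub.mean(axis=1)).ravel()
        scores = {}
        for name in marker_map.names():
            genes = marker_map[name]
            if not genes:
                raise ValidationError(f"marker set {name!r} is empty")
            pos = gene_index.get_indexer(genes)
            present = pos[pos >= 0]
            scores[name] = float(cluster_mean[present].mean()) if len(present) else 0.0
        set_scores[str(cluster)] = scores
    out: dict[str, str] = {}
    for cluster, scores in set_scores.items():
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        best, best_score = ranked[0]
        runner = ranked[1][1] if len(ranked) > 1 else 0.0
        if best_score <= tie_tol or best_score - runner < tie_tol:
            out[cluster] = "unassigned"
        else:
            out[cluster] = best
    return out


def downsample_umis(
    ds: CountDataset, target: int | None = None, seed: int = 0
) -> CountDataset:
    """Downsample every cell to exactly ``target`` UMIs without replacement.

    Each cell's counts become a multivariate-hypergeometric draw from its
    original UMIs. Cells with fewer than ``target`` total UMIs are dropped
    (with a warning). Default target = minimum cell total.
    """
    totals = ds.cell_totals()
    if target is None:
        target = int(totals.min())
    if target < 1:
        raise ValidationError("target must be >= 1")
    keep = totals >= target
    if not keep.all():
        logger.warning("dropping %d cells below the UMI target %d", int((~keep).sum()), target)
    if not keep.any():
        raise ValidationError("no cell reaches the UMI target")
    ds = ds.subset_cells(keep)
    totals = totals[keep]
    rng = np.random.default_rng(seed)
    csc = ds.counts.tocsc()
    row_parts, col_parts, data_parts = [], [], []
    for j in range(csc.shape[1]):
        start, end = csc.indptr[j], csc.indptr[j + 1]
        rows = csc.indices[start:end]
        vals = csc.data[start:end].astype(np.int64)
        if totals[j] == target:
            drawn = vals
        else:
            drawn = rng.multivariate_hypergeometric(vals, target)
        nz = drawn > 0
        row_parts.append(rows[nz])
        col_parts.append(np.full(int(nz.sum()), j, dtype=np.int64))
        data_parts.append(drawn[nz])
    out = sp.coo_matrix(
        (np.concatenate(data_parts), (np.concatenate(row_parts), np.concatenate(col_parts))),
        shape=csc.shape,
        dtype=np.int64,
    )
    return CountDataset(
        counts=out.tocsr(),
        gene_ids=ds.gene_ids,
        cell_ids=ds.cell_ids,
        cell_meta=ds.cell_meta,
        gene_meta=ds.gene_meta,
    )


def downsample_cells(
    ds: CountDataset,
    min_cells: int = 10,
    seed: int = 0,
    type_col: str = "cell_type",
    group_col: str = "group",
) -> tuple[CountDataset, list[str]]:
    """Equalize group sizes within each cell type by subsampling the larger group.

    Cell types in which either group has fewer than ``min_cells`` cells are
    excluded entirely; the second return value lists them.
    """
    meta = ds.cell_meta
    if type_col not in meta.columns:
        raise ValidationError(f"cell_meta lacks {type_col!r}")
    groups = pd.unique(meta[group_col])
    if len(groups) != 2:
        raise ValidationError("exactly two groups required")
    rng = np.random.default_rng(seed)
    keep_idx: list[np.ndarray] = []
    excluded: list[str] = []
    for ctype in pd.unique(meta[type_col]):
        idx_by_group = {
            g: np.flatnonzero((meta[type_col] == ctype) & (meta[group_col] == g).to_numpy())
            for g in groups
        }
        sizes = {g: len(ix) for g, ix in idx_by_group.items()}
        if min(sizes.values()) < min_cells:
            excluded.append(str(ctype))
            continue
        n = min(sizes.values())
        for g, ix in idx_by_group.items():
            if len(ix) > n:
                ix = rng.choice(ix, size=n, replace=False)
                ix.sort()
            keep_idx.append(ix)
    if not keep_idx:
        raise ValidationError(f"no cell type has >= {min_cells} cells in both groups")
    if excluded:
        logger.warning("cell types excluded by min_cells=%d: %s", min_cells, excluded)
    keep = np.sort(np.concatenate(keep_idx))
    return ds.subset_cells(keep), excluded
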