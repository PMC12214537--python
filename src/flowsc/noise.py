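"""Transcriptional noise as a senescence proxy.

Procedure: after equalizing cell numbers per group within each cell type and
downsampling every cell to the same UMI total, genes are ranked by mean
expression into ten equal-size bins, the extreme bins are dropped, and the
lowest-CV genes within each retained bin form the "invariant" gene set.
Counts restricted to that set are square-root transformed and each cell's
Euclidean distance to its cell-type x group centroid is its noise value.
A second metric takes 1 - Spearman correlation over all genes for every cell
pair within a cell type x group. Noise is summarized per sample ("mouse"),
as a d-flow / n-flow ratio per cell type, and tested per cell type with a
two-sided rank-sum test, BH-adjusted across cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import CountDataset
from .markers import bh_adjust
from .preprocess import downsample_cells, downsample_umis

logger = logging.getLogger("flowsc")

__all__ = [
    "select_invariant_genes",
    "euclidean_noise",
    "spearman_noise",
    "noise_ratio",
    "noise_test",
    "noise_pipeline",
    "NoiseResult",
]


def select_invariant_genes(
    ds: CountDataset,
    n_bins: int = 10,
    cv_frac: float = 0.10,
    groups: np.ndarray | None = None,
) -> list[str]:
    """Low-CV ("invariant") genes from equal-size mean-expression bins.

    Genes with zero mean are excluded, the remainder are ranked by mean and
    split into ``n_bins`` equal-size rank bins; the top and bottom bins are
    dropped and within each retained bin the floor(cv_frac * bin_size) genes
    with lowest CV (sd/mean) are selected (ties by gene order). The result is
    the union over retained bins, in gene order.

    ``groups`` switches to the per-flow-group reading: selection is run
    separately on each group's cells and the union is returned.
    """
    if groups is not None:
        groups = np.asarray(groups)
        chosen: dict[str, None] = {}
        for g in pd.unique(groups):
            sub = ds.subset_cells(groups == g)
            for gene in select_invariant_genes(sub, n_bins=n_bins, cv_frac=cv_frac):
                chosen[gene] = None
        index = {g: i for i, g in enumerate(ds.gene_ids)}
        return sorted(chosen, key=index.get)

    X = ds.counts
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    nonzero = np.flatnonzero(mean > 0)
    if len(nonzero) < n_bins:
        raise ValidationError(f"fewer than {n_bins} genes with nonzero mean")
    order = nonzero[np.argsort(mean[nonzero], kind="stable")]  # ascending mean
    bins = np.array_split(order, n_bins)
    selected: list[int] = []
    for b in bins[1:-1]:
        k = int(np.floor(cv_frac * len(b)))
        if k == 0:
            continue
        cv = np.sqrt(var[b]) / mean[b]
        # lowest CV first, ties by gene index
        pick = b[np.lexsort((b, cv))][:k]
        selected.extend(pick.tolist())
    selected = sorted(set(selected))
    return [ds.gene_ids[i] for i in selected]


def euclidean_noise(
    ds: CountDataset,
    invariant_genes: list[str],
    type_col: str = "cell_type",
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-cell distance to the sqrt-transformed cell-type x group centroid.

    Returns a DataFrame (cell, cell_type, group, sample_id, noise); cells in a
    cell type x group stratum with fewer than 2 cells get NaN (with a warning).
    """
    meta = ds.cell_meta
    gene_pos = pd.Index(ds.gene_ids).get_indexer(invariant_genes)
    if (gene_pos < 0).any():
        raise ValidationError("invariant_genes contains genes absent from the dataset")
    X = np.sqrt(np.asarray(ds.counts[gene_pos].todense(), dtype=float))
    noise = np.full(ds.n_cells, np.nan)
    for (ctype, grp), sub in meta.groupby([type_col, group_col], sort=False, observed=True):
        cells = meta.index.get_indexer(sub.index)
        if len(cells) < 2:
            logger.warning("stratum (%s, %s) has < 2 cells; excluded", ctype, grp)
            continue
        centroid = X[:, cells].mean(axis=1, keepdims=True)
        noise[cells] = np.sqrt(((X[:, cells] - centroid) ** 2).sum(axis=0))
    return pd.DataFrame(
        {
            "cell": ds.cell_ids,
            "cell_type": meta[type_col].to_numpy(),
            "group": meta[group_col].to_numpy(),
            "sample_id": meta["sample_id"].to_numpy(),
            "noise": noise,
        }
    )


def spearman_noise(
    ds: CountDataset,
    type_col: str = "cell_type",
    group_col: str = "group",
) -> pd.DataFrame:
    """1 - Spearman correlation over all genes for every within-stratum cell pair.

    Ranks use the average-tie convention; cells with a constant expression
    vector are skipped (their pairs are omitted) with a warning.
    """
    meta = ds.cell_meta
    records = []
    dense_all = np.asarray(ds.counts.todense(), dtype=float)
    for (ctype, grp), sub in meta.groupby([type_col, group_col], sort=False, observed=True):
        cells = meta.index.get_indexer(sub.index)
        if len(cells) < 2:
            continue
        Y = dense_all[:, cells]
        constant = np.all(Y == Y[0, :], axis=0)
        if constant.any():
            logger.warning(
                "stratum (%s, %s): %d constant cells skipped", ctype, grp, int(constant.sum())
            )
            cells = cells[~constant]
            Y = Y[:, ~constant]
            if Y.shape[1] < 2:
                continue
        ranks = stats.rankdata(Y, axis=0)
        rho = np.corrcoef(ranks, rowvar=False)
        iu, ju = np.triu_indices(len(cells), k=1)
        ids = ds.cell_ids[cells]
        records.append(
            pd.DataFrame(
                {
                    "cell_type": ctype,
                    "group": grp,
                    "cell_i": ids[iu],
                    "cell_j": ids[ju],
                    "noise": 1.0 - rho[iu, ju],
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=["cell_type", "group", "cell_i", "cell_j", "noise"])
    return pd.concat(records, ignore_index=True)


def noise_ratio(
    per_cell_noise: pd.DataFrame,
    numerator: str = "d-flow",
    denominator: str = "n-flow",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-averaged noise and its group ratio per cell type.

    Returns (per_sample, ratios): per_sample has the mean noise per
    (sample_id, cell_type); ratios has, per cell type, the ratio of the
    numerator group's sample-averaged noise to the denominator group's, plus
    the cell-pooled variant. Zero or missing denominators yield NaN.
    """
    df = per_cell_noise.dropna(subset=["noise"])
    per_sample = (
        df.groupby(["cell_type", "group", "sample_id"], observed=True)["noise"]
        .mean()
        .reset_index()
    )
    rows = []
    for ctype, sub in per_sample.groupby("cell_type", observed=True):
        num = sub.loc[sub["group"] == numerator, "noise"]
        den = sub.loc[sub["group"] == denominator, "noise"]
        pooled = df[df["cell_type"] == ctype]
        pnum = pooled.loc[pooled["group"] == numerator, "noise"]
        pden = pooled.loc[pooled["group"] == denominator, "noise"]
        ratio = np.nan
        if len(num) and len(den) and den.mean() > 0:
            ratio = num.mean() / den.mean()
        pooled_ratio = np.nan
        if len(pnum) and len(pden) and pden.mean() > 0:
            pooled_ratio = pnum.mean() / pden.mean()
        rows.append((ctype, ratio, pooled_ratio))
    ratios = pd.DataFrame(rows, columns=["cell_type", "ratio", "ratio_pooled"])
    return per_sample, ratios


def noise_test(
    per_cell_noise: pd.DataFrame,
    group_a: str = "d-flow",
    group_b: str = "n-flow",
) -> pd.DataFrame:
    """Two-sided rank-sum on per-cell noise per cell type, BH across cell types."""
    df = per_cell_noise.dropna(subset=["noise"])
    groups = set(df["group"])
    if not {group_a, group_b} <= groups:
        raise ValidationError("both groups must be present")
    rows = []
    for ctype, sub in df.groupby("cell_type", observed=True):
        a = sub.loc[sub["group"] == group_a, "noise"]
        b = sub.loc[sub["group"] == group_b, "noise"]
        if len(a) == 0 or len(b) == 0:
            continue
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append((ctype, a.mean(), b.mean(), p))
    out = pd.DataFrame(rows, columns=["cell_type", f"mean_{group_a}", f"mean_{group_b}", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


@dataclass
class NoiseResult:
    """Bundle of the full transcriptional-noise procedure."""

    per_cell: pd.DataFrame
    per_sample: pd.DataFrame
    ratios: pd.DataFrame  # cell_type, ratio, ratio_pooled, spearman_ratio
    tests: pd.DataFrame
    invariant_genes: list[str]
    excluded_types: list[str] = field(default_factory=list)
    pairwise: pd.DataFrame | None = None


def noise_pipeline(
    ds: CountDataset,
    n_bins: int = 10,
    cv_frac: float = 0.10,
    min_cells: int = 10,
    umi_target: int | None = None,
    seed: int = 0,
    compute_spearman: bool = True,
    numerator: str = "d-flow",
    denominator: str = "n-flow",
) -> NoiseResult:
    """Equalize cells and UMIs, select invariant genes, compute both noise
    metrics, sample-averaged ratios and per-cell-type tests."""
    balanced, excluded = downsample_cells(ds, min_cells=min_cells, seed=seed)
    down = downsample_umis(balanced, target=umi_target, seed=seed + 1)
    invariant = select_invariant_genes(down, n_bins=n_bins, cv_frac=cv_frac)
    per_cell = euclidean_noise(down, invariant)
    per_sample, ratios = noise_ratio(per_cell, numerator, denominator)
    tests = noise_test(per_cell, numerator, denominator)
    pairwise = None
    if compute_spearman:
        pairwise = spearman_noise(down)
        sp_means = (
            pairwise.groupby(["cell_type", "group"], observed=True)["noise"].mean().unstack()
        )
        sp_ratio = (sp_means[numerator] / sp_means[denominator]).rename("spearman_ratio")
        ratios = ratios.merge(sp_ratio, left_on="cell_type", right_index=True, how="left")
    return NoiseResult(
        per_cell=per_cell,
        per_sample=per_sample,
        ratios=ratios,
        tests=tests,
        invariant_genes=invariant,
        excluded_types=excluded,
        pairwise=pairwise,
    )
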