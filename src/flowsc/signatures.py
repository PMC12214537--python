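"""Phenotype signature scoring: VSMC modulation score, rank-AUC (AUCell-style)
per-cell scores, bulk-cohort signature scores, a preranked enrichment score,
and group comparison with the standard significance bands.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import BulkDataset, ExpressionMatrix, GeneSetCollection
from .markers import bh_adjust, top_markers

logger = logging.getLogger("flowsc")

__all__ = [
    "MODULATED_GENES",
    "CONTRACTILE_GENES",
    "vsmc_modulation_score",
    "auc_signature_score",
    "bulk_signature_score",
    "signature_from_markers",
    "preranked_enrichment",
    "compare_groups",
    "significance_band",
]

# Phenotype-modulated (ECM/fibroblast-like) and contractile VSMC signatures.
MODULATED_GENES = ["Lum", "Dcn", "Fn1", "Bgn", "Mmp2", "Col1a1", "Tnfrsf11b"]
CONTRACTILE_GENES = ["Acta2", "Tagln", "Myh11", "Myl6", "Myl9"]


def _list_means(expr: ExpressionMatrix, genes: list[str], cells: np.ndarray) -> np.ndarray:
    """Mean expression over a fixed gene list; absent genes count as zeros."""
    gene_index = expr.gene_index()
    pos = gene_index.get_indexer(genes)
    present = pos[pos >= 0]
    missing = [g for g, p in zip(genes, pos) if p < 0]
    if missing:
        logger.warning("signature genes absent from the matrix (scored as 0): %s", missing)
    if not len(present):
        return np.zeros(len(cells))
    sums = np.asarray(expr.values[present][:, cells].sum(axis=0)).ravel()
    return sums / len(genes)


def vsmc_modulation_score(
    expr: ExpressionMatrix,
    cells: np.ndarray | None = None,
    modulated: list[str] | None = None,
    contractile: list[str] | None = None,
) -> pd.Series:
    """Per-cell score (1 + mean modulated expression) / (1 + mean contractile).

    Means are over the fixed gene lists on normalized (logCP10K) values, with
    genes missing from the matrix contributing zero. A score of 1 means the
    two list means balance; > 1 indicates phenotype modulation.
    """
    modulated = list(modulated or MODULATED_GENES)
    contractile = list(contractile or CONTRACTILE_GENES)
    if set(modulated) & set(contractile):
        raise ValidationError("modulated and contractile lists must be disjoint")
    gene_index = expr.gene_index()
    if not (
        any(g in gene_index for g in modulated) or any(g in gene_index for g in contractile)
    ):
        raise ValidationError("no signature gene present in the matrix")
    if cells is None:
        cells = np.arange(expr.n_cells)
    else:
        cells = np.asarray(cells)
        if cells.dtype == bool:
            cells = np.flatnonzero(cells)
    num = 1.0 + _list_means(expr, modulated, cells)
    den = 1.0 + _list_means(expr, contractile, cells)
    return pd.Series(num / den, index=pd.Index(expr.cell_ids[cells], name="cell"), name="modulation_score")


def auc_signature_score(
    expr: ExpressionMatrix,
    gene_set: Iterable[str],
    top_frac: float = 0.05,
) -> pd.Series:
    """AUCell-style per-cell score: area under the gene-set recovery curve
    within the top ``top_frac`` of expression-ranked genes, normalized to [0, 1].

    Genes are ranked per cell by decreasing expression with ties broken by
    gene order, making the score deterministic. A set entirely absent from the
    matrix scores 0 everywhere (with a warning).
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValidationError("gene_set is empty")
    if not 0 < top_frac <= 1:
        raise ValidationError("top_frac must be in (0, 1]")
    gene_index = expr.gene_index()
    pos = gene_index.get_indexer(genes)
    present = pos[pos >= 0]
    if not len(present):
        logger.warning("gene set entirely absent from the matrix; scores are 0")
        return pd.Series(0.0, index=pd.Index(expr.cell_ids, name="cell"), name="auc_score")
    G = expr.n_genes
    k = math.ceil(top_frac * G)
    m = len(present)
    X = expr.dense()
    order = np.argsort(-X, axis=0, kind="stable")  # gene indices by decreasing value
    rank_of = np.argsort(order, axis=0, kind="stable")  # inverse permutation, 0-based rank
    member_ranks = rank_of[present, :] + 1  # 1-based
    contrib = np.clip(k - member_ranks + 1, 0, None)
    raw = contrib.sum(axis=0).astype(float)
    max_auc = float(np.minimum(np.arange(1, k + 1), m).sum())
    return pd.Series(raw / max_auc, index=pd.Index(expr.cell_ids, name="cell"), name="auc_score")


def bulk_signature_score(
    bulk: BulkDataset,
    gene_set: Iterable[str],
    method: str = "mean_z",
) -> pd.Series:
    """Per-sample signature score of a bulk cohort.

    "mean_z" (default): per-gene z-score across samples, averaged over the
    signature genes present (zero-variance genes contribute 0). "mean_rank":
    per-sample percentile rank of each gene, averaged over the signature.
    Absent signature genes are dropped with a report; fewer than 2 present is
    an error.
    """
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in bulk.expr.columns]
    dropped = [g for g in genes if g not in bulk.expr.columns]
    if dropped:
        logger.warning("%d signature genes absent from the bulk matrix: %s", len(dropped), dropped)
    if len(present) < 2:
        raise ValidationError("fewer than 2 signature genes present in the bulk matrix")
    if len(bulk.expr) < 2:
        raise ValidationError("need at least 2 samples")
    if method == "mean_z":
        sub = bulk.expr[present]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        z = (sub - mu).div(sd.replace(0.0, np.inf), axis=1)
        score = z.mean(axis=1)
    elif method == "mean_rank":
        ranks = bulk.expr.rank(axis=1, method="average") / bulk.expr.shape[1]
        score = ranks[present].mean(axis=1)
    else:
        raise ValidationError(f"unknown method {method!r}")
    score.name = "signature_score"
    return score


def signature_from_markers(markers: pd.DataFrame, cell_type: str, n: int) -> list[str]:
    """Top-n marker genes of one cluster (decreasing log2FC, p < 0.05)."""
    if cell_type not in set(markers["cluster"].astype(str)):
        raise ValidationError(f"unknown cluster {cell_type!r}")
    tops = top_markers(markers[markers["cluster"].astype(str) == cell_type], n=n)
    return tops[str(cell_type)]


def preranked_enrichment(
    ranked: pd.Series,
    gene_sets: GeneSetCollection | Mapping[str, Iterable[str]] | Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked enrichment: weighted Kolmogorov–Smirnov running-sum score.

    ``ranked`` maps gene -> signed statistic (e.g. log2FC); genes are sorted by
    decreasing statistic (ties by input order). Hits advance the running sum by
    |stat|^weight (normalized), misses retreat by 1/(N - M); the enrichment
    score is the extremum of the running sum, in [-1, 1]. P-values come from
    gene-label permutations (random same-size sets), two-sided on |ES| with the
    add-one rule; FDR is BH across the tested sets.

    Accepts a single gene list or a named collection; returns one row per set
    with columns set, ES, p, fdr, n_genes.
    """
    if isinstance(gene_sets, GeneSetCollection):
        named = {name: gene_sets[name] for name in gene_sets.names()}
    elif isinstance(gene_sets, Mapping):
        named = {str(k): list(v) for k, v in gene_sets.items()}
    else:
        named = {"gene_set": list(gene_sets)}
    order = np.argsort(-ranked.to_numpy(), kind="stable")
    genes = ranked.index.to_numpy()[order]
    stat = np.abs(ranked.to_numpy()[order]) ** weight
    N = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in named.items():
        hits = np.array(sorted(gene_pos[g] for g in dict.fromkeys(members) if g in gene_pos))
        M = len(hits)
        if M < 2:
            raise ValidationError(f"set {name!r} overlaps the ranked list in < 2 genes")
        es = _running_es(stat, hits, N, M)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.choice(N, size=M, replace=False)
            null[b] = _running_es(stat, np.sort(perm), N, M)
        p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        rows.append((name, es, p, M))
    out = pd.DataFrame(rows, columns=["set", "ES", "p", "n_genes"])
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def _running_es(stat: np.ndarray, hits: np.ndarray, N: int, M: int) -> float:
    """Extremum of the GSEA running sum for hit positions (sorted, 0-based)."""
    hit_w = stat[hits]
    denom = hit_w.sum()
    if denom == 0:  # all-zero statistics: fall back to unweighted steps
        hit_w = np.ones(M)
        denom = float(M)
    miss_step = 1.0 / (N - M)
    # running sum only changes direction at hit positions; evaluate extrema there
    cum_hit = np.cumsum(hit_w) / denom
    before = cum_hit - hit_w / denom - (hits - np.arange(M)) * miss_step
    after = cum_hit - (hits + 1 - np.arange(1, M + 1)) * miss_step
    candidates = np.concatenate([before, after, [0.0]])
    return float(candidates[np.argmax(np.abs(candidates))])


def significance_band(p: float) -> str:
    """Printed convention: n.s. / * / ** / *** / **** at 0.05/0.01/0.001/0.0001."""
    if not np.isfinite(p):
        return "n.s."
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def compare_groups(
    scores: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    paired: bool = False,
    pair_col: str = "pair_id",
    test: str = "auto",
) -> pd.Series:
    """Compare a score column across groups with the field's standard tests.

    Two groups: Wilcoxon rank-sum (default) or Student's t; paired designs use
    the signed-rank (or paired t) test via ``pair_col``. More than two groups:
    Kruskal–Wallis. Groups with fewer than 2 observations are excluded with a
    warning. Returns statistic, p, significance band and the test used.
    """
    df = scores.dropna(subset=[value_col])
    sizes = df.groupby(group_col, observed=True).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("groups excluded with < 2 observations: %s", small)
        df = df[~df[group_col].isin(small)]
    groups = list(pd.unique(df[group_col]))
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups with >= 2 observations")
    values = [df.loc[df[group_col] == g, value_col].to_numpy() for g in groups]
    if len(groups) == 2:
        if paired:
            wide = df.pivot(index=pair_col, columns=group_col, values=value_col).dropna()
            a, b = wide[groups[0]].to_numpy(), wide[groups[1]].to_numpy()
            if test in ("auto", "wilcoxon"):
                res = stats.wilcoxon(a, b)
                used = "wilcoxon_signed_rank"
            else:
                res = stats.ttest_rel(a, b)
                used = "paired_t"
        elif test in ("auto", "wilcoxon"):
            res = stats.mannwhitneyu(values[0], values[1], alternative="two-sided")
            used = "wilcoxon_rank_sum"
        else:
            res = stats.ttest_ind(values[0], values[1])
            used = "t_test"
    else:
        res = stats.kruskal(*values)
        used = "kruskal_wallis"
    p = float(res.pvalue)
    return pd.Series(
        {
            "test": used,
            "statistic": float(res.statistic),
            "p": p,
            "band": significance_band(p),
            "groups": ",".join(str(g) for g in groups),
        }
    )
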