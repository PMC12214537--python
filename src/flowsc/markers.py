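"""One-vs-rest Wilcoxon rank-sum marker detection and multiple-testing helpers.

For each cluster and gene, the cluster's cells are compared with all other
cells on normalized expression (two-sided rank-sum). log2 fold change follows
the Seurat convention: log2 of the ratio of expm1-means with pseudocount 1.
Bonferroni correction is applied over all (gene, cluster) tests; the DEG flag
is adjusted p < 0.05. Small groups (both sides <= 25 cells) use the exact
rank-sum null when the data are tie-free; larger groups use the
tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger("flowsc")

__all__ = ["wilcoxon_markers", "top_markers", "bh_adjust"]

EXACT_MAX_N = 25


def _rank_precompute(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row average ranks and tie terms sum(t^3 - t), shared across clusters."""
    N = X.shape[1]
    ranks = stats.rankdata(X, axis=1)
    Xs = np.sort(X, axis=1)
    changes = np.diff(Xs, axis=1) != 0
    tie_term = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        idx = np.flatnonzero(changes[i])  # run boundaries of equal values
        bounds = np.concatenate(([0], idx + 1, [N]))
        t = np.diff(bounds).astype(float)
        tie_term[i] = np.sum(t**3 - t)
    return ranks, tie_term


def _ranksum_pvals(ranks: np.ndarray, tie_term: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values, one per row.

    Tie-corrected normal approximation with 0.5 continuity correction
    (wilcox.test / scipy.mannwhitneyu asymptotic semantics).
    """
    N = ranks.shape[1]
    n1 = int(mask.sum())
    n2 = N - n1
    R1 = ranks[:, mask].sum(axis=1)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (U - mu - np.sign(U - mu) * 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var <= 0, 1.0, np.minimum(p, 1.0))
    return p


def _ranksum_pvals_exact(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-gene exact (tie-free) or asymptotic rank-sum p-values for small groups."""
    out = np.empty(X.shape[0])
    in_idx = np.flatnonzero(mask)
    out_idx = np.flatnonzero(~mask)
    for i in range(X.shape[0]):
        a, b = X[i, in_idx], X[i, out_idx]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            out[i] = 1.0
            continue
        has_ties = len(np.unique(X[i])) < X.shape[1]
        method = "asymptotic" if has_ties else "exact"
        out[i] = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    return out


def wilcoxon_markers(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    min_cells: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest marker table for every cluster label.

    Returns a DataFrame with columns cluster, gene, log2FC, p_raw, p_adj
    (Bonferroni over genes x clusters), pct_in, pct_out, is_deg.
    """
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("at least 2 cluster labels required")
    for lab in uniq:
        if (labels == lab).sum() < min_cells:
            raise ValidationError(f"cluster {lab!r} has fewer than {min_cells} cells")
    X = expr.dense()
    expm1 = np.expm1(X)
    small = all((labels == lab).sum() <= EXACT_MAX_N for lab in uniq) and X.shape[
        1
    ] <= 2 * EXACT_MAX_N
    ranks = tie_term = None
    if not small:
        ranks, tie_term = _rank_precompute(X)
    frames = []
    for lab in uniq:
        mask = labels == lab
        if small:
            p = _ranksum_pvals_exact(X, mask)
        else:
            p = _ranksum_pvals(ranks, tie_term, mask)
        mean_in = expm1[:, mask].mean(axis=1)
        mean_out = expm1[:, ~mask].mean(axis=1)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        pct_in = (X[:, mask] > 0).mean(axis=1)
        pct_out = (X[:, ~mask] > 0).mean(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": str(lab),
                    "gene": expr.gene_ids,
                    "log2FC": log2fc,
                    "p_raw": p,
                    "pct_in": pct_in,
                    "pct_out": pct_out,
                }
            )
        )
    tbl = pd.concat(frames, ignore_index=True)
    tbl["p_adj"] = np.minimum(tbl["p_raw"] * len(tbl), 1.0)  # Bonferroni
    tbl["is_deg"] = tbl["p_adj"] < alpha
    return tbl


def top_markers(
    tbl: pd.DataFrame,
    n: int = 200,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> dict[str, list[str]]:
    """Per cluster: significant rows sorted by decreasing log2FC, first ``n`` genes.

    ``use_adjusted`` switches the p < alpha pool from raw to Bonferroni-adjusted
    p-values. Ties in log2FC resolve by table (gene) order.
    """
    pcol = "p_adj" if use_adjusted else "p_raw"
    out: dict[str, list[str]] = {}
    for cluster, sub in tbl.groupby("cluster", sort=False):
        sig = sub[sub[pcol] < alpha]
        sig = sig.sort_values("log2FC", ascending=False, kind="stable")
        genes = sig["gene"].tolist()
        if len(genes) < n:
            logger.warning(
                "cluster %s: only %d significant genes (requested %d)", cluster, len(genes), n
            )
        out[str(cluster)] = genes[:n]
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (p.adjust method="BH" semantics)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
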