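"""Cell-type CVD risk gene enrichment score.

For each cell type, the top marker genes (by decreasing log2FC with p < 0.05)
are intersected with a GWAS-significant cardiovascular risk gene set; each
intersected gene earns a tier from the mean normalized expression over that
cell type's cells — 0 below 1, 1 on [1, 2], 2 above 2 — and the tiers sum to
the cell type's aggregate risk score. Scores can be stratified by experimental
group (markers from the pooled data, expression from each group's cells).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSetCollection
from .markers import top_markers

logger = logging.getLogger("flowsc")

__all__ = ["per_gene_risk_tier", "celltype_cvd_score", "auc_risk_score_per_cell", "RiskScoreResult"]


def per_gene_risk_tier(mean_expr):
    """Three-tier expression score: 0 if x < 1, 1 if 1 <= x <= 2, 2 if x > 2.

    Accepts a scalar or array of non-negative mean log-normalized expression
    values; boundary values 1.0 and 2.0 both fall in tier 1.
    """
    x = np.asarray(mean_expr, dtype=float)
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValidationError("mean expression must be finite and >= 0")
    tier = np.where(x > 2, 2, np.where(x >= 1, 1, 0))
    if np.isscalar(mean_expr) or np.ndim(mean_expr) == 0:
        return int(tier)
    return tier.astype(int)


@dataclass
class RiskScoreResult:
    """Per-gene tiers and aggregate CVD risk score per cell type (x group)."""

    per_gene: pd.DataFrame  # cell_type, group, gene, mean_expr, tier
    scores: pd.DataFrame  # cell_type, group, score, n_genes

    def validate(self) -> None:
        if len(self.per_gene):
            if not self.per_gene["tier"].isin([0, 1, 2]).all():
                raise ValidationError("tiers outside {0, 1, 2}")
            agg = self.per_gene.groupby(["cell_type", "group"])["tier"].sum()
            merged = self.scores.set_index(["cell_type", "group"])["score"]
            aligned = agg.reindex(merged.index).fillna(0).astype(int)
            if not (aligned == merged).all():
                raise ValidationError("aggregate score != sum of tiers")


def _risk_union(risk_sets: GeneSetCollection | Iterable[str]) -> list[str]:
    if isinstance(risk_sets, GeneSetCollection):
        genes = risk_sets.union()
    else:
        genes = list(dict.fromkeys(risk_sets))
    if not genes:
        raise ValidationError("risk gene set is empty")
    return genes


def celltype_cvd_score(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    risk_sets: GeneSetCollection | Iterable[str],
    markers: pd.DataFrame,
    groups: np.ndarray | None = None,
    top_n: int = 200,
    use_adjusted: bool = False,
) -> RiskScoreResult:
    """Aggregate tiered CVD risk score per cell type, optionally per group.

    ``markers`` is the one-vs-rest marker table computed on the same labels;
    the top-``top_n`` marker pool per type is intersected with the risk genes
    and tiered by mean normalized expression over the scored cells.
    """
    labels = np.asarray(labels)
    if len(labels) != expr.n_cells:
        raise ValidationError("labels length does not match the matrix")
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != expr.n_cells:
            raise ValidationError("groups length does not match the matrix")
    risk_genes = set(_risk_union(risk_sets))
    tops = top_markers(markers, n=top_n, use_adjusted=use_adjusted)
    missing = [str(t) for t in pd.unique(labels) if str(t) not in tops]
    if missing:
        raise ValidationError(f"marker table lacks clusters {missing}")

    gene_index = expr.gene_index()
    dense = expr.values.tocsc()
    per_gene_rows, score_rows = [], []
    strata = [(None, np.ones(expr.n_cells, dtype=bool))] if groups is None else [
        (g, groups == g) for g in pd.unique(groups)
    ]
    for ctype in pd.unique(labels):
        ctype = str(ctype)
        hit_genes = [g for g in tops[ctype] if g in risk_genes]
        for grp, gmask in strata:
            cells = np.flatnonzero((labels == ctype) & gmask)
            grp_name = "all" if grp is None else str(grp)
            if not len(hit_genes):
                logger.warning("cell type %s: empty risk-marker intersection", ctype)
                score_rows.append((ctype, grp_name, 0, 0))
                continue
            if not len(cells):
                score_rows.append((ctype, grp_name, 0, 0))
                continue
            pos = gene_index.get_indexer(hit_genes)
            means = np.asarray(dense[pos][:, cells].mean(axis=1)).ravel()
            tiers = per_gene_risk_tier(means)
            for g, m, t in zip(hit_genes, means, tiers):
                per_gene_rows.append((ctype, grp_name, g, float(m), int(t)))
            score_rows.append((ctype, grp_name, int(tiers.sum()), len(hit_genes)))
    result = RiskScoreResult(
        per_gene=pd.DataFrame(
            per_gene_rows, columns=["cell_type", "group", "gene", "mean_expr", "tier"]
        ),
        scores=pd.DataFrame(score_rows, columns=["cell_type", "group", "score", "n_genes"]),
    )
    result.validate()
    return result


def auc_risk_score_per_cell(
    expr: ExpressionMatrix,
    risk_set: GeneSetCollection | Iterable[str],
    top_frac: float = 0.05,
) -> pd.Series:
    """Per-cell rank-AUC score of the risk gene set (AUCell-style companion)."""
    from .signatures import auc_signature_score

    return auc_signature_score(expr, _risk_union(risk_set), top_frac=top_frac)
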