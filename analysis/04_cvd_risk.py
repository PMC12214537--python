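"""Cell-type CVD risk gene enrichment scores, by flow group.

Intersects each cell type's top markers with the GWAS risk gene list, tiers
each hit by mean normalized expression (0: <1, 1: 1-2, 2: >2), sums the tiers,
and adds the per-cell rank-AUC companion score of the risk set.
"""

import pandas as pd

import flowsc as F
from common import RESULTS, parse_seed, study_config


def main() -> None:
    seed = parse_seed(__doc__)
    cfg = study_config(seed)
    ds = F.generate_sc_dataset(cfg)
    filt, _ = F.qc_filter(ds)
    expr = F.lognormalize(filt)
    labels = filt.cell_meta["cell_type"].to_numpy()
    groups = filt.cell_meta["group"].to_numpy()
    truth = F.planted_genes(cfg)

    markers = F.wilcoxon_markers(expr, labels)
    result = F.celltype_cvd_score(expr, labels, truth["risk_genes"], markers, groups=groups)
    wide = result.scores.pivot(index="cell_type", columns="group", values="score")
    print("aggregate CVD risk score per cell type:")
    print(wide.to_string())
    top = wide.sum(axis=1).idxmax()
    print(f"highest-scoring cell type: {top}")

    auc = F.auc_risk_score_per_cell(expr, truth["risk_genes"])
    per_type = (
        pd.DataFrame({"cell_type": labels, "group": groups, "auc": auc.to_numpy()})
        .groupby(["cell_type", "group"])["auc"].mean().rename("mean_auc_score")
    )
    out = result.scores.merge(per_type.reset_index(), on=["cell_type", "group"])
    F.write_table(out, RESULTS / "cvd_scores.csv", seed=seed,
                  params={"top_n": 200, "n_risk_genes": len(truth["risk_genes"])})
    print(f"-> {RESULTS / 'cvd_scores.csv'}")


if __name__ == "__main__":
    main()
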