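"""Generate the synthetic disturbed-flow study and write it to disk.

Writes the single-cell MTX triplet plus metadata under scratch/data/sc/ (large,
regenerable), the planted ground truth to results/simulation_truth.json, and
three paired bulk cohorts (early/advanced, non-IPH/IPH, stable/ruptured) under
scratch/data/.
"""

import json

import flowsc as F
from common import RESULTS, SCRATCH, parse_seed, study_config


def main() -> None:
    seed = parse_seed(__doc__)
    cfg = study_config(seed)
    ds = F.generate_sc_dataset(cfg)
    paths = F.write_counts_mtx(ds, SCRATCH / "data" / "sc")
    print(f"single-cell dataset: {ds.n_genes} genes x {ds.n_cells} cells -> {paths['matrix']}")

    truth = F.planted_genes(cfg)
    RESULTS.mkdir(exist_ok=True)
    keep = {k: truth[k] for k in
            ("markers", "risk_genes", "modulated", "contractile", "mito",
             "noise_inflation", "modulation_shift", "risk_gene_boost")}
    with open(RESULTS / "simulation_truth.json", "w") as fh:
        json.dump(keep, fh, indent=2)
    print(f"planted ground truth -> {RESULTS / 'simulation_truth.json'}")

    sig = [f"Sig{i:03d}" for i in range(100)]
    cohorts = {
        "bulk_lesion": ("early", "advanced"),
        "bulk_iph": ("non-IPH", "IPH"),
        "bulk_rupture": ("stable", "ruptured"),
    }
    for stem, groups in cohorts.items():
        bulk = F.generate_bulk_cohort(20, sig, effect_size=1.0, seed=seed + 101, groups=groups)
        out = SCRATCH / "data"
        out.mkdir(parents=True, exist_ok=True)
        bulk.expr.to_csv(out / f"{stem}.tsv", sep="\t")
        bulk.sample_meta.to_csv(out / f"{stem}_meta.tsv", sep="\t")
        print(f"{stem}: {bulk.expr.shape[0]} samples x {bulk.expr.shape[1]} genes "
              f"({groups[0]} vs {groups[1]})")


if __name__ == "__main__":
    main()
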