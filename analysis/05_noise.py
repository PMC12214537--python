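"""Transcriptional-noise senescence analysis.

Equalizes cell numbers per group within each cell type, downsamples every cell
to the same UMI total, selects invariant (low-CV) genes, and compares the
Euclidean and 1-Spearman noise metrics between flow groups per cell type.
"""

import flowsc as F
from common import RESULTS, parse_seed, study_config


def main() -> None:
    seed = parse_seed(__doc__)
    cfg = study_config(seed)
    ds = F.generate_sc_dataset(cfg)
    filt, _ = F.qc_filter(ds)

    res = F.noise_pipeline(filt, seed=seed)
    summary = res.tests.merge(res.ratios, on="cell_type")
    print(f"{len(res.invariant_genes)} invariant genes; "
          f"excluded cell types: {res.excluded_types or 'none'}")
    print(summary.to_string(index=False))
    sig = summary[(summary["p_adj"] < 0.05) & (summary["ratio"] > 1)]["cell_type"].tolist()
    print(f"cell types with significant noise increase (BH p < 0.05): {sig}")

    F.write_table(summary, RESULTS / "noise_summary.csv", seed=seed,
                  params={"n_bins": 10, "cv_frac": 0.10, "min_cells": 10})
    print(f"-> {RESULTS / 'noise_summary.csv'}")


if __name__ == "__main__":
    main()
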