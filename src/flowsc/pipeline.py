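"""End-to-end single-cell pipeline driver.

Runs simulate -> QC -> normalize -> markers -> CVD risk score -> noise ->
modulation score on the annotated cell types and writes the summary tables as
CSV. Every stage is seeded from the config, so two runs with the same config
produce byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cvd import celltype_cvd_score
from .io import write_table
from .markers import wilcoxon_markers
from .noise import noise_pipeline
from .preprocess import QCThresholds, lognormalize, qc_filter
from .signatures import vsmc_modulation_score
from .simulate import SimConfig, generate_sc_dataset, planted_genes

__all__ = ["run_sc_pipeline"]


def run_sc_pipeline(
    cfg: SimConfig,
    out_dir: str | Path,
    thresholds: QCThresholds | None = None,
    top_n: int = 200,
    min_cells: int = 10,
) -> dict[str, Path]:
    """Run the full synthetic-study pipeline and write CSV summaries.

    Returns the mapping of output name -> path. Cell types are taken from the
    simulation metadata (the clustering/annotation stages are exercised by
    their own tests; the pipeline scores the annotated types directly).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed
    params = {"n_genes": cfg.n_genes, "cells_per_type_per_group": cfg.cells_per_type_per_group}

    ds = generate_sc_dataset(cfg)
    filtered, report = qc_filter(ds, thresholds)
    expr = lognormalize(filtered)
    labels = filtered.cell_meta["cell_type"].to_numpy()
    groups = filtered.cell_meta["group"].to_numpy()
    truth = planted_genes(cfg)

    markers = wilcoxon_markers(expr, labels)
    risk = celltype_cvd_score(
        expr, labels, truth["risk_genes"], markers, groups=groups, top_n=top_n
    )
    noise = noise_pipeline(filtered, min_cells=min_cells, seed=seed)
    vsmc_mask = labels == "VSMC"
    modulation = pd.DataFrame(
        {
            "score": vsmc_modulation_score(expr, vsmc_mask),
            "group": groups[vsmc_mask],
        }
    ).reset_index()

    paths = {
        "qc_report": out / "qc_report.csv",
        "markers": out / "markers.csv",
        "cvd_scores": out / "cvd_scores.csv",
        "noise_summary": out / "noise_summary.csv",
        "noise_tests": out / "noise_tests.csv",
        "modulation": out / "modulation.csv",
    }
    write_table(report.to_frame(), paths["qc_report"], seed=seed, params=params)
    write_table(markers[markers["is_deg"]], paths["markers"], seed=seed, params=params)
    write_table(risk.scores, paths["cvd_scores"], seed=seed, params=params)
    write_table(noise.ratios, paths["noise_summary"], seed=seed, params=params)
    write_table(noise.tests, paths["noise_tests"], seed=seed, params=params)
    write_table(modulation, paths["modulation"], seed=seed, params=params)
    return paths
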