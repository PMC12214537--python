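"""Shared helpers for the numbered analysis drivers."""

import argparse
from pathlib import Path

from flowsc import SimConfig

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"
SCRATCH = REPO / "scratch"


def study_config(seed: int = 0) -> SimConfig:
    """The default study conditions: 7 artery cell types, two flow groups,
    200 cells/type/group, 2000 genes, endothelial noise jitter sigma = 0.5,
    VSMC modulation shift 0.5, risk genes boosted in fibroblasts."""
    return SimConfig(seed=seed)


def parse_seed(description: str) -> int:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=0)
    return parser.parse_args().seed
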