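"""Shared fixtures: hand-built tiny screens and the packaged golden fixture."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from chemoscreen import (
    CountMatrix,
    GuideLibrary,
    SampleMeta,
    SimConfig,
    simulate_screen,
)

GOLDEN_DIR = Path(__file__).parent / "data" / "golden"


def make_library(gene_guides: dict[str, int], control_genes: tuple[str, ...] = ()):
    """Library with ``gene_guides[g]`` guides per gene, spacers arbitrary."""
    rows = []
    for gene, n in gene_guides.items():
        for k in range(n):
            rows.append((f"{gene}_sg{k + 1}", "ACGT" * 5, gene,
                         gene in control_genes))
    return GuideLibrary(
        pd.DataFrame(rows, columns=["guide_id", "spacer", "gene", "is_control"])
    )


def make_cm(lib: GuideLibrary, samples: list[SampleMeta], counts) -> CountMatrix:
    return CountMatrix(lib.guide_ids.copy(), samples, np.asarray(counts))


@pytest.fixture
def tiny_library() -> GuideLibrary:
    return make_library({"G1": 2, "G2": 2, "CTRL": 1}, control_genes=("CTRL",))


@pytest.fixture
def two_arm_samples() -> list[SampleMeta]:
    return [
        SampleMeta("c1", "S1", "control", lane="L1"),
        SampleMeta("t1", "S1", "treated", compound="drug", lane="L1"),
    ]


@pytest.fixture(scope="session")
def golden_config() -> SimConfig:
    import yaml

    with open(GOLDEN_DIR / "sim_config.yaml") as fh:
        raw = yaml.safe_load(fh)
    return SimConfig(**raw)


@pytest.fixture(scope="session")
def golden_sim(golden_config):
    return simulate_screen(golden_config)
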