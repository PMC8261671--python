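import json
from pathlib import Path

import numpy as np
import pytest

from mrbpome import (
    QuantDataset,
    Sample,
    SimulationParams,
    read_design,
    read_quant_table,
    simulate_ric_experiment,
)

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def fixtures_dir() -> Path:
    return FIXTURES


@pytest.fixture(scope="session")
def toy_design():
    return read_design(FIXTURES / "toy_design.tsv")


@pytest.fixture(scope="session")
def toy_dataset(toy_design):
    return read_quant_table(FIXTURES / "toy_quant.tsv", toy_design)


@pytest.fixture(scope="session")
def toy_expected():
    with open(FIXTURES / "toy_quant_expected.json") as fh:
        return json.load(fh)


def make_design(
    n_bio: int = 3,
    n_ctrl: int = 3,
    method: str = "TOP3",
    conditions=("untreated", "stress"),
):
    """Compact design builder for hand-made datasets."""
    design = []
    for cond in conditions:
        tag = "unt" if cond == "untreated" else "str"
        for r in range(1, n_bio + 1):
            design.append(
                Sample(f"{tag}_bio_{r}", cond, "biological", r, method)
            )
        for r in range(1, n_ctrl + 1):
            design.append(
                Sample(
                    f"{tag}_ctrl_{r}", cond, "competition_control", r, method
                )
            )
    return design


def make_dataset(areas, design, peptide_counts=None, proteins=None):
    areas = np.asarray(areas, dtype=float)
    if proteins is None:
        proteins = [f"PROT{i + 1}" for i in range(areas.shape[0])]
    if peptide_counts is None:
        peptide_counts = (areas > 0).astype(int) * 3
    return QuantDataset(
        proteins=proteins,
        areas=areas,
        peptide_counts=np.asarray(peptide_counts),
        design=design,
    )


@pytest.fixture(scope="session")
def sim_small():
    """Shared small simulation for cross-module tests."""
    params = SimulationParams(n_proteins=300, seed=7)
    return simulate_ric_experiment(params)
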