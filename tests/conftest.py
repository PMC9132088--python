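import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from aapl.synthetic_data import (
    ExperimentDesign,
    SimulationParams,
    assign_ground_truth,
    generate_proteome,
    simulate_experiment,
    simulate_string_edges,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_rows(rows):
    """Build a peptide measurement table from (protein, peptide, start, end, mod,
    condition, replicate, intensity, spc) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "peptide", "start", "end", "mod",
            "condition", "replicate", "intensity", "spectral_count",
        ],
    )


def random_peptide_table(rng: np.random.Generator, max_peptides: int = 20) -> pd.DataFrame:
    """Random valid single-condition measurement table for oracle comparisons."""
    n_pep = int(rng.integers(1, max_peptides + 1))
    rows = []
    pos = 1
    for i in range(n_pep):
        length = int(rng.integers(6, 20))
        start, end = pos, pos + length - 1
        pep = "A" * length
        unmod = float(rng.uniform(0, 1e7))
        rows.append(("P1", pep, start, end, "none", "M5", 1, unmod, int(rng.poisson(5))))
        for _ in range(int(rng.integers(0, 4))):
            p = int(rng.integers(start, end + 1))
            rows.append(
                ("P1", pep, start, end, f"ox:{p}", "M5", 1,
                 float(rng.uniform(0, 2e6)), int(rng.poisson(2)))
            )
        pos = end + 1
    return make_rows(rows)


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def proteome(default_params):
    return generate_proteome(default_params)


@pytest.fixture(scope="session")
def truth(proteome, default_params):
    return assign_ground_truth(proteome, default_params)


@pytest.fixture(scope="session")
def measurements(proteome, truth, design, default_params):
    return simulate_experiment(proteome, truth, design, default_params)


@pytest.fixture(scope="session")
def string_edges(truth):
    return simulate_string_edges(truth, overlap_fraction=0.5, n_decoy_edges=100, seed=1)
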