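import numpy as np
import pandas as pd
import pytest

from afmaturity.io_formats import ExpressionMatrix, SampleMetadata
from afmaturity.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study at a fixed seed, shared across tests."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Expression-noise-free bundle: planted sets must be recovered exactly."""
    return simulate_study(SimulationConfig(seed=2, noise_sd_log2=0.0))


@pytest.fixture
def three_stage_metadata():
    """Minimal 2/2/2 sample sheet."""
    rows = []
    for i, stage in enumerate(["PN", "PN", "PT", "PT", "FT", "FT"]):
        rows.append(SampleMetadata(sample_id=f"S{i + 1}", stage=stage))
    return rows


def make_matrix(values, gene_ids=None, sample_ids=None, scale="rpkm"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale=scale
    )
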