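import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import myostate as ms


@pytest.fixture(scope="session")
def base_config() -> ms.SimConfig:
    return ms.SimConfig(seed=11)


@pytest.fixture(scope="session")
def counts_and_truth(base_config):
    return ms.simulate_counts(base_config)


@pytest.fixture(scope="session")
def logexpr(counts_and_truth):
    counts, _ = counts_and_truth
    return ms.log_normalize(counts)


@pytest.fixture(scope="session")
def hto_truth():
    rng = np.random.default_rng(7)
    tags = [f"HTO{i + 1}" for i in range(4)]
    cells = [f"c{i:04d}" for i in range(500)]
    return pd.Series(rng.choice(tags, len(cells)), index=cells)


@pytest.fixture(scope="session")
def plate_sim():
    """Small screen plate: control, a differentiating and a dedifferentiating
    compound, plus the unstained well."""
    layout = ms.screen_layout(
        {
            "differ": (0.1, 0.05, 0.15, 0.35, 0.35),
            "dediff": (0.4, 0.2, 0.2, 0.1, 0.1),
            "null": (0.2, 0.1, 0.4, 0.2, 0.1),
        }
    )
    cfg = ms.SimConfig(seed=21, plate_layout=layout, n_cells_per_well=2000)
    cells, truth = ms.simulate_plate(cfg)
    return cfg, cells, truth


def make_counts(frame: pd.DataFrame, modality: str = "rna") -> ms.CountMatrix:
    """Build a CountMatrix from a dense features x barcodes DataFrame."""
    return ms.CountMatrix(
        matrix=sp.csr_matrix(frame.to_numpy()),
        features=frame.index.to_numpy(dtype=object),
        barcodes=frame.columns.to_numpy(dtype=object),
        modality=modality,
    )
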