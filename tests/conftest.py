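import numpy as np
import pandas as pd
import pytest

from cellcountqc import DilutionSeriesDataset, StudyDesign
from cellcountqc.synthetic_data import SyntheticConfig, simulate_dilution_series

DESIGN_DFS = (1.0, 0.5, 1 / 3, 0.25, 0.2)


@pytest.fixture
def design() -> StudyDesign:
    """The recommended 5-dilution x 3-tube x 3-observation layout."""
    return StudyDesign()


def make_dataset(
    responses_by_df: dict[float, list[list[float]]],
    response_choice: str = "viable_conc",
    viability: float = 90.0,
    preparation: str = "pbmc",
    method: str = "method_1",
) -> DilutionSeriesDataset:
    """Build a dataset from {df: [[obs per tube], ...]} with consistent totals."""
    rows = []
    for df, tubes in responses_by_df.items():
        for j, obs in enumerate(tubes, start=1):
            for k, y in enumerate(obs, start=1):
                rows.append(
                    {
                        "preparation": preparation,
                        "method": method,
                        "target_df": df,
                        "tube_id": f"df{df:.4f}t{j}",
                        "obs_index": k,
                        "viable_conc": y,
                        "total_conc": y * 100.0 / viability if viability > 0 else y,
                        "pct_viability": viability,
                    }
                )
    frame = pd.DataFrame(rows)
    dfs = sorted(responses_by_df, reverse=True)
    tubes_max = max(len(t) for t in responses_by_df.values())
    obs_max = max(len(o) for t in responses_by_df.values() for o in t)
    design = StudyDesign(tuple(dfs), tubes_max, obs_max)
    return DilutionSeriesDataset(design=design, frame=frame, response_choice=response_choice)


@pytest.fixture
def exact_proportional() -> DilutionSeriesDataset:
    """Noiseless y = 1e6 * DF on the recommended design."""
    stock = 1_000_000.0
    return make_dataset({df: [[stock * df] * 3 for _ in range(3)] for df in DESIGN_DFS})


@pytest.fixture
def noisy_dataset() -> DilutionSeriesDataset:
    """One seeded synthetic series under default (5% CV) conditions."""
    return simulate_dilution_series(SyntheticConfig(seed=101, stock_conc=8e5)).dataset


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
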