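import numpy as np
import pandas as pd
import pytest

from gonodyn.io import ExpressionDataset
from gonodyn.synthetic_data import SimulationConfig, simulate_dataset


def make_samples(replicates: int = 2) -> pd.DataFrame:
    rows = []
    for sex in ("F", "M"):
        for stage in ("T1", "T2"):
            for rep in range(1, replicates + 1):
                rows.append((f"{sex}_{stage}_{rep}", sex, stage, rep))
    frame = pd.DataFrame(rows, columns=["sample_id", "sex", "stage", "replicate"])
    return frame.set_index("sample_id")


@pytest.fixture
def tiny_intensity_dataset() -> ExpressionDataset:
    samples = make_samples(replicates=2)
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, (4, len(samples))),
        index=pd.Index([f"g{i}" for i in range(4)], name="gene_id"),
        columns=samples.index,
    )
    return ExpressionDataset(values=values, samples=samples, platform="intensity")


@pytest.fixture
def tiny_counts_dataset() -> ExpressionDataset:
    samples = make_samples(replicates=3)
    rng = np.random.default_rng(1)
    values = pd.DataFrame(
        rng.poisson(50, (6, len(samples))),
        index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
        columns=samples.index,
    )
    return ExpressionDataset(values=values, samples=samples, platform="counts")


@pytest.fixture(scope="session")
def strong_effect_run():
    """A small counts simulation with strong planted effects plus its truth."""
    config = SimulationConfig(
        n_genes=1200,
        replicates=6,
        platform="counts",
        proportions={
            "meg_up": 0.05,
            "meg_down_opp": 0.05,
            "meg_both": 0.05,
            "feg_up": 0.05,
            "feg_down_opp": 0.05,
            "feg_both": 0.05,
            "shared_up": 0.05,
            "shared_down": 0.05,
            "null": 0.60,
        },
        effect_low=2.0,
        effect_high=4.0,
        log2_mean_loc=7.0,
        log2_mean_scale=1.0,
        dispersion=0.05,
        seed=42,
    )
    return simulate_dataset(config)
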