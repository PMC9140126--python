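import numpy as np
import pandas as pd
import pytest

from stagetrend import ExpressionMatrix, SampleTable, STAGES
from stagetrend.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Planted cohort at study conditions but 50 genes, for fast tests."""
    cfg = SimulationConfig(
        n_genes=50, n_monotone_up=8, n_monotone_down=4,
        batch_shift_sd=0.0, n_batches=1, seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """One seed of the full study-condition cohort (2000 genes, 30/stage)."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def batch_shift_fixture():
    """500 genes, two crossed batches, +2 log2 batch shift, 1.0 condition
    effect on all genes -- the planted harmonization recovery fixture."""
    rng = np.random.default_rng(7)
    ng, n = 500, 80
    cond = np.array(["NAU"] * 40 + ["T2"] * 40)
    batch = np.array((["b1"] * 20 + ["b2"] * 20) * 2)
    base = rng.normal(7, 1, ng)
    X = base[:, None] + rng.normal(0, 1, (ng, n))
    X[:, cond == "T2"] += 1.0
    X[:, batch == "b2"] += 2.0
    genes = [f"g{i}" for i in range(ng)]
    samp = [f"s{i}" for i in range(n)]
    matrix = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samp))
    batches = pd.Series(batch, index=samp)
    condition = pd.Series(cond, index=samp)
    return matrix, batches, condition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
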