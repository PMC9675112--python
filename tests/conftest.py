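import numpy as np
import pandas as pd
import pytest

from npbmix.design import DesignMatrices
from npbmix.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A modest planted-effect cohort shared across fast tests."""
    return simulate_cohort(SimulationConfig(n_dyads=300, seed=12345))


@pytest.fixture(scope="session")
def null_cohort() -> pd.DataFrame:
    return simulate_cohort(SimulationConfig(n_dyads=300, seed=54321, true_effects={}))


def make_selection_design(x: np.ndarray, y: np.ndarray, names=None) -> DesignMatrices:
    """Covariate-free DesignMatrices for sampler/oracle problems."""
    x = np.asarray(x, dtype=float)
    names = names or [f"v{j}" for j in range(x.shape[1])]
    idx = pd.RangeIndex(len(y))
    return DesignMatrices(
        y=np.asarray(y, dtype=float),
        x=pd.DataFrame(x, columns=names, index=idx),
        z=pd.DataFrame(index=idx),
        w=pd.DataFrame(index=idx),
        outcome="birth_weight",
    )


def standardized_columns(rng: np.random.Generator, n: int, p: int) -> np.ndarray:
    x = rng.standard_normal((n, p))
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
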