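import numpy as np
import pandas as pd
import pytest

from exomix.synthetic import DesignConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A compact three-arm cohort with all four temporal profiles."""
    cfg = DesignConfig(n_per_group={"EE": 12, "RE": 12, "CON": 8}, seed=11)
    return simulate_cohort(cfg)


def balanced_samples(
    n_per_group: dict[str, int], timepoints: tuple[str, ...] = ("Pre", "PLate")
) -> pd.DataFrame:
    """Fully balanced complete sample table (no profiles, no covariates)."""
    rows = []
    pid = 0
    for g, n in n_per_group.items():
        for _ in range(n):
            pid += 1
            for t in timepoints:
                rows.append((f"P{pid:04d}", g, t))
    return pd.DataFrame(rows, columns=["participant", "group", "timepoint"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
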