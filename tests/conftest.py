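import numpy as np
import pandas as pd
import pytest

from medigut.synth import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Paper-scale cohort (44 cases / 51 controls) with every participant stooled."""
    cfg = SimulationConfig(seed=11, stool_fraction=1.0)
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort for recovery checks (300/300, all stooled)."""
    cfg = SimulationConfig(n_cases=300, n_controls=300, seed=7, stool_fraction=1.0)
    return generate_cohort(cfg), cfg


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(42)
    mat = rng.integers(0, 50, size=(8, 5))
    return pd.DataFrame(
        mat, index=[f"S{i}" for i in range(8)], columns=[f"T{j}" for j in range(5)]
    )


@pytest.fixture()
def ffq_table():
    """Six FFQ records with both sexes, hand-checkable intakes."""
    rng = np.random.default_rng(3)
    n = 12
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "sex": ["F", "M"] * (n // 2),
            "fruit": rng.uniform(50, 250, n),
            "vegetables": rng.uniform(40, 200, n),
            "legumes": rng.uniform(0, 30, n),
            "whole_grain_foods": rng.uniform(10, 100, n),
            "fish": rng.uniform(0, 60, n),
            "processed_red_meat": rng.uniform(20, 150, n),
            "mufa": rng.uniform(5, 25, n),
            "sfa": rng.uniform(5, 25, n),
            "whole_grains": rng.uniform(0.1, 1.5, n),
            "fiber": rng.uniform(4, 20, n),
            "iron": rng.uniform(4, 15, n),
            "energy": rng.uniform(700, 2500, n),
            "n_missing_items": np.zeros(n, dtype=int),
        }
    )
    return df
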