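import numpy as np
import pandas as pd
import pytest

from netscore.simulate import SimulationConfig, generate_cohort, generate_multi_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with two planted effect modules (seed-fixed)."""
    cfg = SimulationConfig(
        n_genes=120,
        n_samples_per_cohort=(200,),
        n_modules=3,
        module_sizes=(40, 30, 30),
        module_loading=(0.8, 0.8, 0.8),
        survival_effect=(1.0, 0.0, 0.0),
        seed=42,
    )
    cohort, truth = generate_cohort(cfg, 0)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def multi_cohorts():
    """Training + one test cohort with planted structure (seed-fixed)."""
    cfg = SimulationConfig(seed=5)
    cohorts, truth = generate_multi_cohort(cfg)
    return cfg, cohorts, truth


def make_survival(time, event, index=None) -> pd.DataFrame:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    idx = index if index is not None else [f"s{i}" for i in range(len(time))]
    return pd.DataFrame({"time": time, "event": event}, index=idx)
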