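import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ccsens import SimulationConfig, simulate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """6 strains x 2 arms x 3 mice, moderate effects; shared across tests."""
    cfg = SimulationConfig(n_strains=6, mice_per_strain_per_arm=4, seed=42)
    table, truth = simulate_cohort(cfg)
    return table, truth, cfg


@pytest.fixture(scope="session")
def noiseless_config():
    """Effectively deterministic generator (residual variance ~ 0)."""
    return SimulationConfig(
        n_strains=2,
        mice_per_strain_per_arm=2,
        var_strain=0.0,
        var_strain_slope=0.0,
        var_mouse=0.0,
        var_resid=1e-12,
        grand_mean=5000.0,
        day_effects=(0.0, -400.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        cocaine_acute_effect=3000.0,
        ramp=(0.0, 500.0, 400.0, 300.0, 200.0),
        expression_effect=250.0,
        conditioned_effect=800.0,
        sex_effect=0.0,
        site_effect=0.0,
        seed=7,
    )


def one_way_frame(values: np.ndarray, a: int, n: int) -> pd.DataFrame:
    """Long table for a balanced one-way strain layout, one obs per mouse."""
    return pd.DataFrame(
        {
            "y": values,
            "strain": np.repeat([f"S{i:02d}" for i in range(a)], n),
            "mouse_id": [f"m{i:04d}" for i in range(a * n)],
        }
    )
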