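import numpy as np
import pytest

from cumimpact import (
    CIDataset,
    GridSpec,
    Layer,
    SensitivityRecord,
    SynthConfig,
    make_case,
)


@pytest.fixture(scope="session")
def small_case():
    """Desk-scale synthetic case shared by read-only tests."""
    return make_case(SynthConfig(seed=7, n_rows=30, n_cols=30, n_uses=4,
                                 n_envs=5, gazetteer_partitions=3))


@pytest.fixture()
def toy_dataset():
    """5x5 hand-checkable dataset: one use, one env, distance 0."""
    grid = GridSpec(5, 5, 1.0)
    use = np.zeros((5, 5))
    use[1, 1] = 1.0
    use[2, 3] = 0.5
    env = np.ones((5, 5))
    env[4, 4] = 0.0
    return CIDataset(
        grid,
        uses={"U1": Layer(grid, use, "use_intensity")},
        envs={"E1": Layer(grid, env, "env_presence")},
        sensitivities=[SensitivityRecord("U1", "P1", "E1", 0.8, 0.0, 0.9)],
    ).validate()


@pytest.fixture()
def two_use_dataset():
    """Two overlapping uses on a shared env, distance 0 — combination tests."""
    grid = GridSpec(4, 4, 1.0)
    u1 = np.full((4, 4), 1.0)
    u2 = np.full((4, 4), 1.0)
    env = np.ones((4, 4))
    return CIDataset(
        grid,
        uses={"U1": Layer(grid, u1, "use_intensity"), "U2": Layer(grid, u2, "use_intensity")},
        envs={"E1": Layer(grid, env, "env_presence")},
        sensitivities=[
            SensitivityRecord("U1", "P1", "E1", 0.2, 0.0, 1.0),
            SensitivityRecord("U2", "P2", "E1", 0.3, 0.0, 0.5),
        ],
    ).validate()
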