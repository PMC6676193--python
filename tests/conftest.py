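import numpy as np
import pandas as pd
import pytest

from methylink import synthetic


@pytest.fixture(scope="session")
def small_study():
    """A small 2-subject cohort with two planted biclusters (session-wide)."""
    cfg = synthetic.SimulationConfig(
        n_subjects=2, n_probes=300, n_parameters=30,
        n_planted=2, probe_block_size=60, param_block_size=6,
        seed=7,
    )
    return synthetic.generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The default 4-subject study used by the end-to-end checks."""
    cfg = synthetic.SimulationConfig(seed=11)
    return synthetic.generate_study(cfg)


@pytest.fixture()
def toy_beta():
    """A 4-probe x 4-day beta matrix with hand-checkable values."""
    return pd.DataFrame(
        {
            "day-45": [0.40, 0.10, 0.50, 0.30],
            "day-15": [0.55, 0.10, 0.50, 0.35],
            "day+2": [0.10, 0.20, 0.50, 0.30],
            "day+30": [0.20, 0.30, 0.50, 0.40],
        },
        index=pd.Index([f"cg{i}" for i in range(4)], name="probe_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
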