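import warnings

import numpy as np
import pytest

from meq.synth import (CellArchetype, KinematicsModel, TaskConfig,
                       generate_session, make_archetype)
from meq.utils import substream

warnings.filterwarnings("ignore", message="All-NaN slice")
warnings.filterwarnings("ignore", message="Mean of empty slice")


@pytest.fixture(scope="session")
def kin():
    return KinematicsModel()


@pytest.fixture(scope="session")
def small_task():
    return TaskConfig(n_trials_per_condition=3, amplitudes=(10.0, 20.0), seed=7)


@pytest.fixture(scope="session")
def basic_cells():
    rng = substream(42, 0)
    return [make_archetype("invariant", "same", "same", "both", rng, "cA"),
            make_archetype("eye", "same", "eye", "eye", rng, "cB")]


@pytest.fixture(scope="session")
def small_session(small_task, kin, basic_cells):
    """A compact session with traces, shared across tests."""
    return generate_session(small_task, kin, basic_cells, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def constant_rate_cell(rate: float) -> CellArchetype:
    """A cell that only fires at its baseline rate (no burst)."""
    return CellArchetype(peak_rate_eye=0.0, peak_rate_hand=0.0,
                         peak_rate_eyehand=0.0, baseline_rate=rate)
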