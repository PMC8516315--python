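import numpy as np
import pytest

import viforage as vf
from viforage.synthetic import edge_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def fixtures():
    return edge_fixtures()


def random_session(rng, n=300):
    """An arbitrary (not model-generated) two-option session."""
    return vf.SessionRecord(
        choices=rng.integers(0, 2, n),
        rewards=rng.integers(0, 2, n),
        block_id=np.zeros(n, dtype=int),
    )


@pytest.fixture(scope="session")
def dt_sessions():
    """Ten closed-loop DT sessions on the alternating 0.1:0.4 schedule."""
    from viforage.synthetic import MOUSE_DT_PARAMS, RecoverySpec, generate_recovery_dataset

    spec = RecoverySpec(true_params=MOUSE_DT_PARAMS, n_runs=10, seed=7)
    sessions, manifest = generate_recovery_dataset(spec)
    return sessions, manifest
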