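import numpy as np
import pytest

from dynfc.qc import RoiTimeSeriesRun
from dynfc.synthetic import CohortSpec, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_run(rng):
    """A 40-volume, 6-node run with mild node-to-node correlation."""
    shared = rng.standard_normal((40, 1))
    data = 0.5 * shared + rng.standard_normal((40, 6))
    return RoiTimeSeriesRun(
        data=data, tr_seconds=2.0, run_id="run-1",
        node_ids=[f"n{i}" for i in range(6)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Four participants, 20 nodes, default couplings; session-cached."""
    spec = CohortSpec(n_participants=4, n_nodes=20, seed=3)
    return spec, simulate_cohort(spec)
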