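import numpy as np
import pytest

from mbcascade.energy import AICG2PParams
from mbcascade.synthetic import ToyProteinSpec, make_toy_two_state_protein
from mbcascade.topology import build_topology


@pytest.fixture(scope="session")
def toy_system():
    """Small two-module two-state toy: (pre, post, partition)."""
    spec = ToyProteinSpec(n_modules=2)
    return make_toy_two_state_protein(spec)


@pytest.fixture(scope="session")
def toy_params():
    return AICG2PParams()


@pytest.fixture(scope="session")
def toy_topology(toy_system, toy_params):
    pre, post, partition = toy_system
    return build_topology(pre, post, partition, params=toy_params,
                          delta=2.0, delta_v=-1.0)


@pytest.fixture(scope="session")
def toy_ff(toy_topology):
    from mbcascade._kernel import compile_force_field

    return compile_force_field(toy_topology)


def random_event_table(rng, K=4, n_traj=20, censor_prob=0.2, t_end=1e6):
    """Random event table for order/rate oracle tests."""
    import pandas as pd

    rows = []
    for t in range(n_traj):
        for m in range(K):
            censored = rng.random() < censor_prob
            tau = np.nan if censored else float(rng.integers(1, t_end))
            rows.append({"trajectory": t, "module": f"M{m + 1}", "tau": tau,
                         "censored": censored, "t_end": t_end,
                         "frame_steps": 500})
    return pd.DataFrame(rows)
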