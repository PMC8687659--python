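import numpy as np
import pytest

from infoflow.io import Trajectory
from infoflow.simulate import SimConfig, simulate_pair_flight


def make_traj(xy, dt=0.2, bird_id="b", chain="c", generation=2, release=1,
              valid=None):
    xy = np.asarray(xy, dtype=float)
    t = dt * np.arange(len(xy))
    return Trajectory(bird_id, chain, generation, release, t, xy, valid=valid)


@pytest.fixture(scope="session")
def coupled_colony():
    """Twelve coupled pair flights (distinct birds, same release index)."""
    pairs = []
    for i in range(12):
        cfg = SimConfig(n_steps=3000, w_couple=0.6, alpha_attract=0.25,
                        r_coh=10.0, beta_home=0.1, sigma_heading=0.25,
                        q_switch=0.005, tau=1, seed=100 + i)
        pf, _ = simulate_pair_flight(
            cfg, bird_ids=(f"E{i}", f"N{i}"), metadata=(f"pair{i}", 2, 1))
        pairs.append(pf)
    return pairs


@pytest.fixture(scope="session")
def uncoupled_pairs():
    """Six fully uncoupled pair flights (no interaction null)."""
    pairs = []
    for i in range(6):
        cfg = SimConfig(n_steps=1500, w_couple=0.0, alpha_attract=0.0,
                        beta_home=0.1, sigma_heading=0.25, q_switch=0.0,
                        seed=500 + i)
        pf, _ = simulate_pair_flight(
            cfg, bird_ids=(f"E{i}", f"N{i}"), metadata=(f"pair{i}", 2, 1))
        pairs.append(pf)
    return pairs
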