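import numpy as np
import pytest

from troopcall.social import compute_dai, davids_score, eigenvector_centrality
from troopcall.synthetic import (
    TroopConfig,
    make_roster,
    simulate_agonistic,
    simulate_movements,
    simulate_proximity,
)


@pytest.fixture(scope="session")
def default_config():
    return TroopConfig(seed=1)


@pytest.fixture(scope="session")
def roster(default_config):
    return make_roster(default_config)


@pytest.fixture(scope="session")
def dai_matrix(default_config, roster):
    return compute_dai(simulate_proximity(roster, default_config), roster)


@pytest.fixture(scope="session")
def centrality(dai_matrix):
    return eigenvector_centrality(dai_matrix).to_series()


def simulated_model_frame(seed: int, n_events: int | None = None):
    """Full generative chain -> observation table + truth, for recovery tests."""
    kwargs = {"seed": seed}
    if n_events is not None:
        kwargs["movement_count"] = n_events
    config = TroopConfig(**kwargs)
    troop = make_roster(config)
    cent = eigenvector_centrality(
        compute_dai(simulate_proximity(troop, config), troop)
    ).to_series()
    dominance = davids_score(simulate_agonistic(troop, config), troop)
    rank = dict(zip(dominance.individuals, dominance.rank))
    relatives = {ind.id: ind.n_relatives for ind in troop}
    _, truth = simulate_movements(troop, cent, config)
    obs = truth["observations"].copy()
    obs["rank"] = [rank[i] for i in obs["id"]]
    obs["relatives"] = [relatives[i] for i in obs["id"]]
    return obs, truth
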