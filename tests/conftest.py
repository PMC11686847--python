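import pytest

from oodyn import (
    SimulationConfig,
    classify_decay_clusters,
    compute_tpm,
    simulate_experiment,
    spike_in_calibrate,
    stage_profiles,
)


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition simulation: 9 clusters x 200 genes, n=3/group."""
    return simulate_experiment(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_calibrated(default_sim):
    exp, ref, _, _ = default_sim
    return spike_in_calibrate(compute_tpm(exp), exp, ref)


@pytest.fixture(scope="session")
def default_profile(default_sim, default_calibrated):
    exp, _, _, _ = default_sim
    return stage_profiles(default_calibrated, exp)


@pytest.fixture(scope="session")
def default_cluster_map(default_profile):
    return classify_decay_clusters(default_profile)
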