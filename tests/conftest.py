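import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


def run_evidence(scenario, fit_settings=None, n_sim=None):
    """Simulate-fit cycles for a scenario; returns arrays (e_h1, e_h2, e_h3)."""
    from aipower import evidence_between, evidence_within, fit_experiment
    from aipower.simulate import simulate_experiment

    n = scenario.n_sim if n_sim is None else n_sim
    es = np.empty((n, 3))
    for j in range(n):
        data = simulate_experiment(scenario, sim_index=j)
        post = fit_experiment(data, scenario.r_g1, scenario.r_g2, fit_settings)
        es[j] = (evidence_within(post, 1), evidence_within(post, 2),
                 evidence_between(post))
    return es[:, 0], es[:, 1], es[:, 2]
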