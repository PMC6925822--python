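import pytest

from emsadp import CallStreams, DemandModel, GreedyPolicy, default_seoul_like_scenario

TRAIN_ITERATIONS = 2000
HEADLINE_REPS = 30


@pytest.fixture(scope="session")
def headline_scenario():
    """The reference experiment cell: ALS ratio 0.83, alpha = beta = 0.2."""
    return default_seoul_like_scenario(seed=0, als_ratio=0.83, alpha=0.2, beta=0.2)


@pytest.fixture(scope="session")
def trained_default(headline_scenario):
    """Value table learned on the reference cell (shared across tests)."""
    from emsadp import train

    return train(headline_scenario, TRAIN_ITERATIONS, gamma=0.9, seed=0)


@pytest.fixture(scope="session")
def headline_comparison(headline_scenario, trained_default):
    """CRN-paired ADP vs greedy comparison on the reference cell."""
    from emsadp import ADPPolicy, crn_compare

    return crn_compare(
        headline_scenario,
        {"adp": ADPPolicy(trained_default.table, gamma=0.9),
         "greedy": GreedyPolicy()},
        replications=HEADLINE_REPS, seed=123)


@pytest.fixture
def seoul():
    """Default scenario factory."""
    return default_seoul_like_scenario


@pytest.fixture
def light_scenario():
    """Reduced-demand variant for fast episode-level tests."""
    s = default_seoul_like_scenario(seed=0, als_ratio=0.83, alpha=0.1, beta=0.1)
    return s.with_(demand=DemandModel(daily_calls=40.0,
                                      hourly_profile=s.demand.hourly_profile,
                                      prior_high=s.demand.prior_high))


@pytest.fixture
def light_episode(light_scenario):
    from emsadp import run_episode

    return run_episode(light_scenario, GreedyPolicy(), horizon_days=2.0,
                       warmup_days=0.5, streams=CallStreams(42))
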