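import random

import pytest

from taskswitch.agents import BeliefAgentParams, BeliefStateAgent, run_agent
from taskswitch.synthetic_data import (SyntheticBehaviourConfig,
                                       SyntheticNeuralConfig,
                                       generate_behaviour, generate_calcium)
from taskswitch.task_env import EnvConfig, TaskEnv

# best-fit belief-state parameters on the primary behavioural dataset
BELIEF_BEST_FIT = dict(zeta=0.6858, beta=1.997, epsilon=0.049,
                     epsilon_prime=0.280)
# best-fit basic SARSA (epsilon, alpha) on the primary dataset
BASIC_BEST_FIT = dict(epsilon=0.236, alpha=0.9)
# best-fit parameters on the silencing dataset, and the fitted factors
SILENCING_BASE = dict(zeta=0.7698, beta=1.987, epsilon=0.1072,
                      epsilon_prime=0.4516)
SILENCING_FACTORS = (0.2143, 0.5016)


@pytest.fixture(scope="session")
def trained_belief_session():
    """A trained belief-state agent's test-phase log and mismatch trace."""
    log, truth = generate_behaviour(SyntheticBehaviourConfig(
        mode="agent_driven", agent_params=BeliefAgentParams(**BELIEF_BEST_FIT),
        n_train_steps=50_000, n_test_steps=30_000, seed=11))
    return log, truth.trace


@pytest.fixture(scope="session")
def scripted_log():
    log, _ = generate_behaviour(SyntheticBehaviourConfig(
        mode="scripted_policy", n_blocks=41, trials_per_block=16, seed=3))
    return log


@pytest.fixture(scope="session")
def calcium_recording(scripted_log):
    """300-neuron synthetic recording with all planted classes."""
    rec, truth = generate_calcium(SyntheticNeuralConfig(
        n_neurons=300, fraction_pe_positive=0.09, fraction_pe_negative=0.03,
        fraction_type_a=0.05, fraction_type_b=0.05, seed=4), scripted_log)
    return rec, truth


@pytest.fixture()
def fresh_env():
    return TaskEnv(EnvConfig(seed=7))


@pytest.fixture()
def rng():
    return random.Random(123)
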