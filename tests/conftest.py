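import numpy as np
import pandas as pd
import pytest

from habitlab import agents, task_designs as td


@pytest.fixture(scope="session")
def reward_map():
    return td.reward_pairs_reward_map()


@pytest.fixture(scope="session")
def rl_ck_params():
    return agents.ModelParams(
        "rl_ck", alpha_q=0.3, beta_q=6.0, alpha_h=0.2, beta_h=4.0
    )


def simulate_full_reward_pairs(params, seed, reward_map, days=5):
    """Full Reward Pairs protocol: training sessions plus final test."""
    logs = []
    state = None
    for day in range(1, days + 1):
        schedule = td.build_reward_pairs_training_session(day, seed)
        log, state = agents.simulate_task(
            params, schedule, reward_map, seed=seed + day, state=state
        )
        logs.append(log)
    schedule = td.build_reward_pairs_test(seed, day=days)
    log, state = agents.simulate_task(params, schedule, None, seed=seed + 99, state=state)
    logs.append(log)
    return pd.concat(logs, ignore_index=True)


@pytest.fixture(scope="session")
def full_rp_log(rl_ck_params, reward_map):
    """One synthetic participant's complete Reward Pairs log (936 trials)."""
    return simulate_full_reward_pairs(rl_ck_params, seed=7, reward_map=reward_map)


@pytest.fixture(scope="session")
def short_rp_log(rl_ck_params, reward_map):
    """A single 160-trial training session log."""
    schedule = td.build_reward_pairs_training_session(1, 3)
    log, _ = agents.simulate_task(rl_ck_params, schedule, reward_map, seed=5)
    return log
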