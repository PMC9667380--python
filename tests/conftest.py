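import numpy as np
import pandas as pd
import pytest

import trialcea as tc


@pytest.fixture(scope="session")
def breakdown():
    return tc.microcost_interventions(tc.demo_ledger())


@pytest.fixture(scope="session")
def scenario():
    return tc.default_scenario(seed=1)


@pytest.fixture(scope="session")
def full_trial(scenario):
    """Complete (no-missingness) default synthetic trial."""
    return tc.generate_trial(scenario)


@pytest.fixture(scope="session")
def observed_trial(scenario, full_trial):
    """Default trial after MAR dropout."""
    return tc.apply_missingness(full_trial, scenario)


@pytest.fixture(scope="session")
def participant_table(observed_trial, scenario, breakdown):
    return tc.build_participant_table(observed_trial, scenario.unit_costs, breakdown)


@pytest.fixture(scope="session")
def complete_table(full_trial, scenario, breakdown):
    return tc.build_participant_table(full_trial, scenario.unit_costs, breakdown)


def make_deterministic_cost_dataset(arm_effect: dict[int, float], n_per_arm: int = 12):
    """Noise-free long dataset with cost_aud = baseline + arm effect at
    every follow-up wave (used for exact-recovery checks)."""
    rng = np.random.default_rng(0)
    rows = []
    pid = 0
    for arm in (1, 2, 3):
        for i in range(n_per_arm):
            base = 1000.0 + 100.0 * (pid % 7)
            sex = "female" if rng.random() < 0.5 else "male"
            country = ["US", "Australia", "other"][pid % 3]
            for wave in (0, 3, 6, 9, 12):
                y = base if wave == 0 else base + arm_effect.get(arm, 0.0)
                rows.append(
                    dict(participant_id=f"D{pid:03d}", arm=arm, sex=sex,
                         country=country, wave=wave, utility=0.6, madrs=20.0,
                         cost_aud=y)
                )
            pid += 1
    return tc.TrialDataset(pd.DataFrame(rows))
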