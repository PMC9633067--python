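import numpy as np
import pandas as pd
import pytest

from prismadapt.simulation import ExperimentDesign, ObserverParams, simulate_participant


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def noiseless_learner(design):
    """One deterministic participant: lr=0.2, full retention, no noise."""
    params = ObserverParams(learning_rate=0.2, retention=1.0, nofeedback_retention=1.0)
    return simulate_participant(design, params, seed=0, participant_id="p1", group="control")


def random_trial_table(rng: np.random.Generator, participant_id="r1", group="control"):
    """A random (structurally valid) single-participant trial table."""
    rows = []
    for phase, n in (("pre", 12), ("prism", 48), ("post", 48)):
        for t in range(1, n + 1):
            rows.append(
                {
                    "participant_id": participant_id,
                    "group": group,
                    "phase": phase,
                    "trial": t,
                    "target_deg": float(rng.choice([-25.0, 0.0, 25.0])),
                    "error_deg": float(rng.normal(0, 5)),
                    "feedback": phase == "prism",
                }
            )
    return pd.DataFrame(rows)
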