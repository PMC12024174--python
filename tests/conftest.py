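import numpy as np
import pandas as pd
import pytest

import creawell as cw


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized default cohort (n=76)."""
    return cw.generate_cohort(cw.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def large_cohort():
    """Large default-configuration cohort for calibration checks."""
    return cw.generate_cohort(cw.SimulationConfig(n_participants=5000, seed=7))


@pytest.fixture(scope="session")
def large_scores(large_cohort):
    return cw.score_bundle(large_cohort)


@pytest.fixture(scope="session")
def identity_cohort_scores():
    """n=5000 cohort with fully independent latents, scored."""
    cfg = cw.SimulationConfig(
        n_participants=5000,
        target_rho=np.eye(len(cw.ANALYSIS_VARIABLES)),
        missing_rate_per_instrument={
            k: 0.0 for k in cw.synthetic.DEFAULT_MISSING_RATES
        },
        seed=19,
    )
    return cw.score_bundle(cw.generate_cohort(cfg))


@pytest.fixture()
def tiny_responses():
    """Three-participant single-item hand fixture: p1:{a,b}, p2:{a}, p3:{c}."""
    frame = pd.DataFrame(
        {
            "participant_id": ["p1", "p1", "p2", "p3"],
            "item": ["bucket"] * 4,
            "response_text": ["a", "b", "a", "c"],
        }
    )
    return cw.AUTResponseSet.from_frame(frame, participants=["p1", "p2", "p3"])
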