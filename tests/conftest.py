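import numpy as np
import pandas as pd
import pytest

import priorlearn as pl
from priorlearn.synthetic import AgentParams, DesignSpec


@pytest.fixture(scope="session")
def small_spec():
    """A minimal counterbalanced design: 4 participants, 8 blocks over 4
    target locations."""
    return DesignSpec(
        n_participants=4,
        n_blocks=8,
        location_set=tuple(np.arange(4) * 90.0),
        seed=0,
    )


@pytest.fixture(scope="session")
def reset_cohort():
    """Study-scale cohort of resetting agents (no cross-modality transfer):
    20 participants x 40 blocks, lag weights mirroring the observed strategy
    (previous guesses 0.3/0.2/0.1, current hint 0.4)."""
    spec = DesignSpec(n_participants=20, seed=0)
    params = AgentParams(reset_on_switch=True, seed=0)
    trials, calib = pl.simulate_cohort(spec, params, seed=0)
    errors = pl.flag_failures(pl.compute_errors(trials))
    return {"spec": spec, "params": params, "errors": errors, "calib": calib}


@pytest.fixture(scope="session")
def nonreset_cohort():
    """Same cohort but with full transfer across the response switch."""
    spec = DesignSpec(n_participants=20, seed=0)
    params = AgentParams(reset_on_switch=False, seed=0)
    trials, calib = pl.simulate_cohort(spec, params, seed=1)
    errors = pl.flag_failures(pl.compute_errors(trials))
    return {"spec": spec, "params": params, "errors": errors, "calib": calib}


@pytest.fixture(scope="session")
def reset_motor(reset_cohort):
    return pl.estimate_motor_error(reset_cohort["calib"])


@pytest.fixture(scope="session")
def reset_predictors(reset_cohort):
    return pl.build_predictors(reset_cohort["errors"])


def make_error_table(rows):
    """Hand-built error table for predictor arithmetic tests."""
    df = pd.DataFrame(rows)
    defaults = {"participant_id": 1, "block_id": 1, "failed": False}
    for k, v in defaults.items():
        if k not in df.columns:
            df[k] = v
    return df
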