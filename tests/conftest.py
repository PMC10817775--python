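import numpy as np
import pytest

import nof1bayes as nb


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_trial():
    """Ten weekly measurements, 2 baseline + two 4-week periods, K=2."""
    t = np.arange(10.0)
    treatment = np.array([1, 1, 2, 2, 2, 2, 1, 1, 1, 1])
    period = np.array([0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
    value = np.array([55.0, 57.0, 50.0, 49.0, 52.0, 48.0, 56.0, 54.0, 55.0, 58.0])
    return nb.TrialDataset(
        individual_id="P001",
        time=t,
        treatment=treatment,
        value=value,
        period_index=period,
        K=2,
        outcome_bounds=(34.0, 78.0),
        sequence_label="AB",
    )


@pytest.fixture
def crossover_population():
    """Small synthetic crossover study (complete, no missingness)."""
    hyper = nb.HyperParams(
        d=(-3.0, -2.5), sigma_delta=2.0, m=55.0, sigma_mu=4.0,
        ze=float(np.arctanh(0.3)), sigma_ze=0.0, sigma=4.0,
    )
    design = nb.DesignTemplate(baseline_weeks=2, n_periods=4, period_weeks=4)
    data, truth = nb.simulate_population(
        hyper, 8, design,
        nb.DropoutModel(stratum_probs=(1.0, 0.0, 0.0), mar_rate=0.0),
        seed=11, bounds=(-1e9, 1e9),
    )
    return data, truth
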