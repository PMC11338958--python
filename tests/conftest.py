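import numpy as np
import pytest

from gradedsdt import CriterionSet, GaussianSdtModel, RatingProbabilities
from gradedsdt.simulate import (SimulationConfig, simulate_rating_experiment,
                                simulate_trial_amplitudes)

#: fitted evidence model reported for the rating experiment
MU_SIGNAL, SIGMA_SIGNAL = 1.385, 1.344


@pytest.fixture(scope="session")
def fitted_model() -> GaussianSdtModel:
    return GaussianSdtModel(MU_SIGNAL, SIGMA_SIGNAL)


@pytest.fixture(scope="session")
def criteria5() -> CriterionSet:
    return CriterionSet(np.array([0.4, 0.8, 1.2, 1.7, 2.3]))


@pytest.fixture(scope="session")
def analytic_probs(fitted_model, criteria5):
    """Exact rating probabilities implied by the fitted model and criteria."""
    return (RatingProbabilities.analytic("signal", fitted_model, criteria5),
            RatingProbabilities.analytic("noise", fitted_model, criteria5))


@pytest.fixture(scope="session")
def sim_experiment():
    """One seeded default-size rating experiment with trial amplitudes."""
    cfg = SimulationConfig()
    trials, truth = simulate_rating_experiment(cfg, seed=0)
    trials = simulate_trial_amplitudes(trials, cfg.amplitude_noise_sd, seed=0)
    return trials, truth, cfg
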