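import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from compgrowth.config import SimConfig, TreatmentConfig, default_treatments
from compgrowth.simulate import simulate_cohort, simulate_isotope_observations
from compgrowth.turnover import IsotopeSeries

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# (k, m) per treatment over the day 7-35 window of the emulated trial
TRIAL_RATES = {
    "Control": (0.051, 0.033),
    "T3": (0.057, 0.018),
    "T6": (0.061, 0.008),
}
C0, CN = 8.53, 14.31
FIT_DAYS = (7, 9, 14, 21, 28, 35)


@pytest.fixture(scope="session")
def treatments():
    return default_treatments()


@pytest.fixture(scope="session")
def control(treatments):
    return treatments[0]


@pytest.fixture(scope="session")
def t6(treatments):
    return treatments[2]


@pytest.fixture
def noiseless_sim():
    return SimConfig(initial_weight_sd=0.0, weight_noise_sd=0.0, d15n_noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def cohort():
    """One default simulated trial shared across tests."""
    return simulate_cohort(sim=SimConfig(seed=11))


def make_series(name, k, m, noise_sd=0.2, seed=0, days=FIT_DAYS, n_reps=3):
    t, y = simulate_isotope_observations(
        C0, CN, k, m, days, n_reps=n_reps, noise_sd=noise_sd, rng=seed
    )
    return IsotopeSeries(name, t, y, c0=C0, cn=CN)


@pytest.fixture(scope="session")
def fixture_series():
    """A small bank of noisy series spanning the trial's rate combinations."""
    bank = []
    for seed, (name, (k, m)) in enumerate(TRIAL_RATES.items()):
        bank.append((k, make_series(name, k, m, noise_sd=0.2, seed=seed)))
        bank.append((k, make_series(name, k, m, noise_sd=0.4, seed=100 + seed)))
    return bank
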