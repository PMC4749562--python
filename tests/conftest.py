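import numpy as np
import pytest

from switchtissue.types import KineticParams, TranscriptionProfile


@pytest.fixture(scope="session")
def kp() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def grid_46h() -> np.ndarray:
    """The default imaging grid: 46 h at 15-min sampling (185 points)."""
    return np.arange(0.0, 46.001, 0.25)


@pytest.fixture()
def single_switch_profile() -> TranscriptionProfile:
    return TranscriptionProfile(np.array([20.0]), np.array([5.0, 25.0]))


def make_ssa_trace(profile, kp, grid, rng, noise_sd=5.0):
    """Simulate one noisy fluorescence trace from the reporter network,
    starting near the stationary counts of the initial rate."""
    from switchtissue.synthetic import simulate_reporter_ssa

    b0 = profile.rates[0]
    m0 = rng.poisson(b0 / kp.delta_m) if b0 > 0 else 0
    p0 = rng.poisson(kp.alpha * b0 / (kp.delta_m * kp.delta_p)) if b0 > 0 else 0
    _, P = simulate_reporter_ssa(profile, kp, grid, rng, init=(m0, p0))
    return np.clip(kp.kappa * P + rng.normal(0, noise_sd, len(P)), 0, None)
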