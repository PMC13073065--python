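import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_screen():
    """One 96-gene screen with planted effects, simulated once per session."""
    from qhtcp.simulate import ScreenSimConfig, simulate_screen

    cfg = ScreenSimConfig(n_genes=96, seed=7)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_screen_fits(small_screen):
    from qhtcp.growth import fit_screen

    return fit_screen(small_screen.series)


@pytest.fixture(scope="session")
def small_screen_scored(small_screen, small_screen_fits):
    from qhtcp.growth import qc_arrays
    from qhtcp.interactions import score_screen

    qc = qc_arrays(small_screen_fits)
    table = score_screen(
        small_screen_fits, small_screen.design, small_screen.layouts, qc
    )
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
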