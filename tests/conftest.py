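import numpy as np
import pytest

from slipgait.model_core import ModelParams


@pytest.fixture(scope="session")
def nominal() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def vertical_hop(nominal):
    from slipgait.continuation import seed_vertical_hop

    return seed_vertical_hop(nominal, apex_height=1.2)


@pytest.fixture(scope="session")
def forward_hop(nominal):
    from slipgait.continuation import seed_forward_hopping

    return seed_forward_hopping(nominal, 0.5)


@pytest.fixture(scope="session")
def symmetric_run(nominal):
    from slipgait.continuation import seed_symmetric_running

    return seed_symmetric_running(nominal, 2.0)


@pytest.fixture(scope="session")
def sym_study():
    from slipgait import study

    return study.symmetric_study()


@pytest.fixture(scope="session")
def asym_study():
    from slipgait import study

    return study.asymmetric_study()


@pytest.fixture(scope="session")
def trial_fixture_solution():
    """Feasible synthetic stand-in near the fitted skipping-trial
    conditions (the printed trial offset admits no periodic solution in
    this implementation; see the methods note)."""
    from slipgait.io_fixtures import trial_like_skipping

    return trial_like_skipping(
        ModelParams(omega=6.49, phi_l=0.17, phi_r=0.10), 2.86
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
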