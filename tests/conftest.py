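import pytest

from turtlefarm import (EconParams, LifeHistory, OperatingTargets,
                        StockConfig, solve_policy)


@pytest.fixture(scope="session")
def lh():
    return LifeHistory()


@pytest.fixture(scope="session")
def stock():
    return StockConfig()


@pytest.fixture(scope="session")
def targets():
    return OperatingTargets()


@pytest.fixture(scope="session")
def econ():
    return EconParams()


@pytest.fixture(scope="session")
def solved_traditional(lh, stock, targets):
    """Managed rates solved for traditional farming (no adult harvest)."""
    return solve_policy(lh, stock, 0.0, targets)


@pytest.fixture(scope="session")
def solved_04(lh, stock, targets):
    """Managed rates solved for the 40% adult-harvest scenario."""
    return solve_policy(lh, stock, 0.4, targets)
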