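import numpy as np
import pytest

from divergelab.ecoevo import ChemostatEnv, UptakeParams
from divergelab.tradeoff import TradeoffCurve


@pytest.fixture
def mix_env():
    """Mixed-sugar treatment environment (fructose 2.5 g/L + galactose 5 g/L)."""
    return ChemostatEnv(S1=2.5, S2=5.0, D=0.3)


@pytest.fixture
def sym_env():
    """Symmetric two-resource supply used for symmetry invariants."""
    return ChemostatEnv(S1=5.0, S2=5.0, D=0.3)


@pytest.fixture
def params():
    return UptakeParams()


@pytest.fixture
def strong_curve():
    return TradeoffCurve(shape_p=0.5)


@pytest.fixture
def weak_curve():
    return TradeoffCurve(shape_p=2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
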