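import pytest

from chapbind.equilibria import BindingModel, EquilibriumParams
from chapbind.titration import DEFAULT_TARGET_RATIOS, plan_protocol

N_T0 = 6e-4  # 0.6 mM starting client
K_STOCK = 2.1e-3  # 2.1 mM chaperone stock
K_UN = 22.7  # folding constant of the free client at 35 C


@pytest.fixture
def tight_params():
    """Strong binding at both steps, well below the working concentrations."""
    return EquilibriumParams(K_UN=K_UN, Kd1=1e-9, Kd2=1e-9)


@pytest.fixture
def default_protocol():
    return plan_protocol(DEFAULT_TARGET_RATIOS, N_T0, K_STOCK)


@pytest.fixture(params=list(BindingModel), ids=lambda m: m.value)
def model(request):
    return request.param
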