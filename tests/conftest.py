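import hypothesis
import numpy as np
import pytest

from cotransport import IonConditions, SimulationSpec, Stoichiometry

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def stoich_3_1():
    """Wild-type-like 3Na:1Cl:1Gly coupling (z_T = 2)."""
    return Stoichiometry(n_na=3, n_cl=1)


@pytest.fixture
def stoich_2_1():
    """GlyT1-like 2Na:1Cl:1Gly coupling (z_T = 1)."""
    return Stoichiometry(n_na=2, n_cl=1)


@pytest.fixture
def oocyte_conditions():
    """Standard recording bath over a sodium-injected oocyte at 18 °C."""
    return IonConditions(na_o=100.0, cl_o=106.0, gly_o=1.0, temperature_c=18.0)


@pytest.fixture
def noiseless_spec(stoich_3_1, oocyte_conditions):
    return SimulationSpec(
        stoichiometry=stoich_3_1, conditions=oocyte_conditions, seed=7
    )
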