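import numpy as np
import pytest

from amykin import KineticRates, reduce_rates

#: published rate constants per condition (kn in 1/s, ke in L/mol/s), 80 uM peptide
TABLE1 = {
    "alone": (3.73e-6, 3.378),
    "DOPC": (5.97e-6, 1.968),
    "Chol": (2.74e-6, 5.573),
    "7keto": (4.4e-6, 1.227),
}

A_STUDY = 80e-6  # mol/L

HOURS = 3600.0


@pytest.fixture
def control_rates():
    kn, ke = TABLE1["alone"]
    return KineticRates(kn=kn, ke=ke, a=A_STUDY)


@pytest.fixture
def control_params(control_rates):
    return reduce_rates(control_rates)


@pytest.fixture
def grid_48h():
    """25-point uniform grid over the 48 h observation window, in seconds."""
    return np.linspace(0.0, 48 * HOURS, 25)
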