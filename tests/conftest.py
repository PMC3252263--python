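import pytest

from prcsync import make_circuit, make_template
from prcsync.prc import PRCModel


@pytest.fixture(scope="session")
def templates():
    return {name: make_template(name)
            for name in ("exc_I", "exc_II", "inh_I", "inh_II")}


@pytest.fixture(scope="session")
def exc1_pair():
    """Two identical unit-period neurons with the excitatory Type I PRC."""
    t = make_template("exc_I")
    return make_circuit(t, t, period_a=1.0)


@pytest.fixture(scope="session")
def exc2_pair():
    t = make_template("exc_II")
    return make_circuit(t, t, period_a=1.0)


@pytest.fixture(scope="session")
def inh2_pair():
    t = make_template("inh_II")
    return make_circuit(t, t, period_a=1.0)


def zero_prc(coupling_sign="excitatory"):
    """A PRC with no resetting and no noise (f = 0, sigma = 0)."""
    return PRCModel(
        mean_coeffs=[0.0, 0.0, 0.0],
        sigma_upper_coeffs=[0.0],
        sigma_lower_coeffs=[0.0],
        prc_type="I",
        coupling_sign=coupling_sign,
    )
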