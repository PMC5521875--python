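import warnings

import numpy as np
import pytest

from pdmcircuit import laguerre_basis
from pdmcircuit.synthetic import make_circuit, make_theta_inputs, simulate_ca1


@pytest.fixture(scope="session")
def basis():
    """Default discrete Laguerre basis (alpha 0.7, L 5, M 120)."""
    return laguerre_basis()


@pytest.fixture(scope="session")
def connected_session():
    """One 600 s session from a fully known circuit: 3 CA3 inputs all
    connected to a single CA1 unit."""
    circuit = make_circuit(n_ca3=3, n_ca1=1, connect_prob=1.0, seed=11)
    inputs = make_theta_inputs(3, 600.0, seed=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        output = simulate_ca1(inputs, circuit, seed=13)[0]
    return circuit, inputs, output


def true_filter_values(circuit, j=0):
    """Concatenated ground-truth filter values (all feedforward + feedback)
    for CA1 unit j."""
    parts = [circuit.basis.B @ circuit.ff_coeffs[(i, j)]
             for i in range(circuit.n_ca3) if circuit.connectivity[i, j]]
    parts.append(circuit.basis.B @ circuit.fb_coeffs(j))
    return np.concatenate(parts)
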