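import numpy as np
import pytest

import thermoreg as tr


@pytest.fixture(scope="session")
def toy_chain():
    """Canonical 2-reaction chain X0(4) <=> X1 <=> X2(1) with K = (1, 1)."""
    return tr.generate_toy_pathway("chain", 2, (1.0, 1.0), (4.0, 1.0))


@pytest.fixture(scope="session")
def toy_solution(toy_chain):
    net, state, thermo = toy_chain
    sol = tr.solve_steady_state(net, thermo, state)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def full_model():
    """Glycolysis-PPP-TCA under condition 1 with synthetic favourable K."""
    net, state = tr.build_ecoli_pathway("glycolysis_ppp_tca", "high_nad_low_nadp")
    thermo = tr.generate_synthetic_thermo(net, 300.0, seed=1)
    return net, state, thermo


@pytest.fixture(scope="session")
def full_solution(full_model):
    net, state, thermo = full_model
    sol = tr.solve_steady_state(net, thermo, state)
    assert sol.converged
    return sol


def chain2_closed_form(K1, K2, B0, B2):
    """Independent closed form for the 2-chain intermediate at alpha=(1,1).

    Flux balance K1 B0/x - x/(K1 B0) = K2 x/B2 - B2/(K2 x) solves to
    x^2 = (K1 B0 + B2/K2) / (K2/B2 + 1/(K1 B0)).
    """
    return np.sqrt((K1 * B0 + B2 / K2) / (K2 / B2 + 1.0 / (K1 * B0)))


def chain2_activity_closed_form(a, b=1.0):
    """Intermediate of the canonical chain under activities (a, b):
    n_B^2 = (16a + 4b) / (4b + a)."""
    return np.sqrt((16 * a + 4 * b) / (4 * b + a))
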