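import numpy as np
import pytest

import microcirc as mc

LOW = np.array([1.0, 10.0, 3.0, 2.0])
HIGH = np.array([30.0, 50.0, 30.0, 20.0])
VIP_STEP = np.array([0.0, 0.0, 0.0, 10.0])


@pytest.fixture(scope="session")
def low_circuit():
    return mc.generic_circuit("low")


@pytest.fixture(scope="session")
def high_circuit():
    return mc.generic_circuit("high")


@pytest.fixture(scope="session")
def low_fp(low_circuit):
    return mc.steady_state(low_circuit, 0.0, r0=LOW)


@pytest.fixture(scope="session")
def high_fp(high_circuit):
    return mc.steady_state(high_circuit, 0.0, r0=HIGH)


@pytest.fixture(scope="session")
def v1_low():
    return mc.v1_circuit("low")


def draw_stable_wd(rng, max_tries=200):
    """One random (W, d) pair on the microcircuit sign pattern with a
    linearly stable operating point: magnitudes log-uniform in [0.1, 5],
    inverse gains log-uniform in [0.1, 10]; rejects draws whose
    linearization is unstable or near-singular."""
    from microcirc.sampling import GENERIC_SIGN_PATTERN

    for _ in range(max_tries):
        W = GENERIC_SIGN_PATTERN * np.exp(rng.uniform(np.log(0.1), np.log(5.0), (4, 4)))
        d = np.exp(rng.uniform(np.log(0.1), np.log(10.0), 4))
        A = np.diag(d) - W
        # rate-dynamics Jacobian is -(1/tau) D^-1 A: stable iff eig(D^-1 A) in
        # the right half plane
        eig = np.linalg.eigvals(A / d[:, None])
        if np.all(eig.real > 1e-3):
            return W, d
    raise RuntimeError("could not draw a stable (W, d) pair")
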