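import numpy as np
import pytest

from grnstab import assign_parameters, gen_random, solve_fixed_point


@pytest.fixture
def small_net():
    """Sparse random network (N=40) with moderate regulation, solvable fast."""
    es = gen_random(40, 0.03, 0.5, seed=11)
    return assign_parameters(es, omega_max=2.0, h=2.0, seed=12)


@pytest.fixture
def small_solution(small_net):
    ss = solve_fixed_point(small_net, seed=13)
    assert ss.converged
    return ss


@pytest.fixture
def dense_net():
    """Denser network (N=30) in which nearly every gene regulates."""
    es = gen_random(30, 0.15, 0.5, seed=21)
    return assign_parameters(es, omega_max=1.5, h=1.0, seed=22)


def fd_jacobian(fun, x0, eps=1e-7, scale=1e-4):
    """Central finite differences of a vector-valued function."""
    x0 = np.asarray(x0, dtype=float)
    f0 = np.asarray(fun(x0))
    jac = np.zeros((f0.size, x0.size))
    for j in range(x0.size):
        dx = eps * max(abs(x0[j]), scale)
        xp, xm = x0.copy(), x0.copy()
        xp[j] += dx
        xm[j] -= dx
        jac[:, j] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (2 * dx)
    return jac
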