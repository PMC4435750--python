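import numpy as np
import pytest
from scipy.integrate import solve_ivp

from netrecon import SignedNetwork, TimeCourse


def simulate_linear_ode(A, x0, T=2.0, m=50):
    """Exact trajectory of dx/dt = A x via an adaptive integrator."""
    sol = solve_ivp(
        lambda t, x: A @ x, (0.0, T), x0,
        t_eval=np.linspace(0.0, T, m), rtol=1e-10, atol=1e-12,
    )
    return TimeCourse(times=sol.t, states=sol.y.T)


def linear_courses(A, n_courses, T=2.0, m=50, seed=0):
    rng = np.random.default_rng(seed)
    return [
        simulate_linear_ode(A, rng.uniform(0.2, 1.0, A.shape[0]), T=T, m=m)
        for _ in range(n_courses)
    ]


@pytest.fixture
def two_node_system():
    """Decay chain: node 1 self-decays, activates node 2 which self-decays."""
    return np.array([[-1.0, 0.0], [1.0, -1.0]])


@pytest.fixture
def three_node_cascade():
    return np.array([[-1.0, 0.0, 0.0], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])


@pytest.fixture
def five_node_ring():
    """Negative-feedback ring; oscillatory, so trajectories are informative."""
    A = np.zeros((5, 5))
    np.fill_diagonal(A, -0.5)
    A[0, 4] = -1.0
    for i in range(1, 5):
        A[i, i - 1] = 1.0
    return A


@pytest.fixture
def small_reference():
    adj = np.zeros((4, 4), dtype=int)
    adj[1, 0] = 1
    adj[2, 1] = -1
    adj[3, 0] = 1
    return SignedNetwork(adj)


def network_with_edges(n, edge_list):
    """Build a SignedNetwork from (source, target, sign) tuples (0-based)."""
    adj = np.zeros((n, n), dtype=int)
    for s, t, sign in edge_list:
        adj[t, s] = sign
    return SignedNetwork(adj)
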