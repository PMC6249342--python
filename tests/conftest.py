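import numpy as np
import pytest

import covnet


@pytest.fixture(scope="session")
def small_cohort():
    """Two groups x 30 subjects x 90 ROIs with default planted structure."""
    table, truth = covnet.generate_cohort(covnet.CohortSpec(seed=11))
    return table, truth


@pytest.fixture(scope="session")
def small_residuals(small_cohort):
    table, _ = small_cohort
    return covnet.residualize(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_cohort(**kwargs):
    spec = covnet.CohortSpec(**kwargs)
    return covnet.generate_cohort(spec)


@pytest.fixture(scope="session")
def path3():
    """Path graph on 3 nodes: 0-1-2."""
    A = np.zeros((3, 3), dtype=np.int8)
    A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
    return A


def complete_graph(n):
    A = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(A, 0)
    return A


def star_graph(n_leaves):
    """Center node 0 with n_leaves pendant nodes."""
    A = np.zeros((n_leaves + 1, n_leaves + 1), dtype=np.int8)
    A[0, 1:] = 1
    A[1:, 0] = 1
    return A


def cycle_graph(n):
    A = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        A[i, (i + 1) % n] = A[(i + 1) % n, i] = 1
    return A


def ring_lattice(n, k):
    """Each node connected to its k nearest neighbors (k even)."""
    A = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            A[i, j] = A[j, i] = 1
    return A


def graph_from_adjacency(A, density=None):
    n = A.shape[0]
    E = int(A.sum()) // 2
    labels = [f"n{i}" for i in range(n)]
    return covnet.BinaryGraph(np.asarray(A, dtype=np.int8),
                              E / (n * (n - 1) / 2), E, labels)
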