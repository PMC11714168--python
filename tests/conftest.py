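"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the package's vectorised code
paths: plain Python set arithmetic, ``statistics.median``, triple loops,
and a dense linear solve, so equation-level tests compare two independent
routes to the same quantity.
"""

import statistics

import numpy as np
import pandas as pd
import pytest

from citmic import GeneSet, GeneSetCollection


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def jaccard_bf(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def median_bf(a: set, b: set, expr: dict) -> float:
    ov = a & b
    return statistics.median(expr[g] for g in ov) if ov else 0.0


def bipartite_bf(cells, gos, expr: dict) -> np.ndarray:
    W = np.zeros((len(cells), len(gos)))
    for i, c in enumerate(cells):
        for j, g in enumerate(gos):
            W[i, j] = jaccard_bf(set(c.genes), set(g.genes)) * \
                median_bf(set(c.genes), set(g.genes), expr)
    return W


def crosstalk_bf(W: np.ndarray) -> np.ndarray:
    """Triple-loop one-mode projection with zero diagonal."""
    n, m = W.shape
    R = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for k in range(m):
                R[i, j] += W[i, k] * W[j, k]
    return R


def rwr_solve(R: np.ndarray, restart_prob: float,
              dangling_uniform: bool = True) -> np.ndarray:
    """Closed-form stationary distribution: pi = r (I - (1-r) P)^-1 u."""
    n = R.shape[0]
    P = np.zeros((n, n))
    for j in range(n):
        s = R[:, j].sum()
        if s > 0:
            P[:, j] = R[:, j] / s
        elif dangling_uniform:
            P[:, j] = 1.0 / n
    u = np.full(n, 1.0 / n)
    pi = restart_prob * np.linalg.solve(np.eye(n) - (1 - restart_prob) * P, u)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# the fixed 3-cell / 2-GO worked example
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def toy():
    """Three cells, two GO terms, six genes, one sample; small enough to
    verify every matrix entry by hand."""
    cells = GeneSetCollection([
        GeneSet("A", {"g1", "g2", "g3"}, "lymphoid"),
        GeneSet("B", {"g1", "g2"}, "myeloid"),
        GeneSet("C", {"g4", "g5"}, "stromal"),
    ])
    gos = GeneSetCollection([
        GeneSet("GO1", {"g1", "g2"}, "go_bp"),
        GeneSet("GO2", {"g4", "g5", "g6"}, "go_bp"),
    ], kind="go_bp")
    expr = pd.Series({"g1": 2.0, "g2": 4.0, "g3": 1.0,
                      "g4": 5.0, "g5": 3.0, "g6": 2.0}, name="s1")
    return cells, gos, expr


@pytest.fixture(scope="session")
def toy_cohort():
    """Deterministic small synthetic cohort shared across tests."""
    from citmic import SyntheticSpec, generate
    spec = SyntheticSpec(n_genes=400, n_cells=6, n_go=30,
                         genes_per_cell=(10, 20), genes_per_go=(10, 25),
                         overlap_rate=0.5, n_samples=4, seed=42)
    return generate(spec)


def random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    A = rng.uniform(size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return A
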