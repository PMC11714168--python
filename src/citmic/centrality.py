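"""Node centrality on the crosstalk network via a restarted random walk.

The infiltration score of a cell is the limiting distribution of a random
walk on the weighted cell-cell network with uniform restarts: at each step
the walker restarts at a uniformly chosen cell with probability
``restart_prob`` and otherwise moves along an edge with probability
proportional to its weight. The limit is computed deterministically by
fixed-point iteration

    pi <- restart_prob * u + (1 - restart_prob) * P @ pi,    u = 1/n

(a PageRank-style recursion with uniform personalisation), so no seed is
involved despite the name; the starting distribution only affects the number
of iterations. With ``restart_prob > 0`` every cell retains strictly
positive mass, which keeps the downstream log10 transform defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RWRConfig", "CentralityResult", "transition_matrix", "rwr_stationary"]


@dataclass(frozen=True)
class RWRConfig:
    """Parameters of the restarted random walk.

    Parameters
    ----------
    restart_prob : float in (0, 1]
        Probability of teleporting back to a uniformly chosen node at each
        step; 0.15 is the conventional damping complement. Infiltration
        scores are used as relative quantities, and their ranking is stable
        across a broad range of restart probabilities.
    tol : float
        L1 convergence threshold of the fixed-point iteration.
    max_iter : int
        Iteration cap; non-convergence is reported, never silent.
    dangling_policy : {"uniform_redistribute", "self_restart"}
        What an isolated (zero-degree) cell's column of the transition
        matrix becomes: a uniform distribution (default; keeps all scores
        positive), or all zeros so its mass re-enters only via restart.
    """

    restart_prob: float = 0.15
    tol: float = 1e-10
    max_iter: int = 1000
    dangling_policy: str = "uniform_redistribute"

    def __post_init__(self):
        if not (0 < self.restart_prob <= 1):
            raise ValueError("restart_prob must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.dangling_policy not in ("uniform_redistribute", "self_restart"):
            raise ValueError(f"unknown dangling_policy {self.dangling_policy!r}")


@dataclass(frozen=True)
class CentralityResult:
    """Stationary distribution over cells (sums to 1)."""

    cells: tuple
    scores: np.ndarray
    iterations_used: int
    converged: bool


def transition_matrix(R: np.ndarray,
                      dangling_policy: str = "uniform_redistribute") -> np.ndarray:
    """Column-stochastic transition matrix of the weighted network.

    Column j is R[:, j] normalised by its sum; a zero column (isolated
    cell) is replaced by 1/n everywhere (``uniform_redistribute``) or left
    zero (``self_restart``).
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise ValueError("adjacency must be square")
    colsum = R.sum(axis=0)
    dangling = colsum == 0
    P = np.zeros_like(R)
    if (~dangling).any():
        P[:, ~dangling] = R[:, ~dangling] / colsum[~dangling]
    if dangling.any() and dangling_policy == "uniform_redistribute":
        P[:, dangling] = 1.0 / n
    return P


def rwr_stationary(R, cfg: RWRConfig = RWRConfig(),
                   cells=None) -> CentralityResult:
    """Limiting distribution of the restarted random walk on adjacency R.

    Iterates ``pi <- r*u + (1-r) P pi`` from the uniform vector until the L1
    change drops below ``cfg.tol`` or ``cfg.max_iter`` is hit (then a
    warning is emitted and ``converged`` is False). The returned scores are
    normalised to sum to 1.
    """
    if hasattr(R, "to_numpy"):
        if cells is None:
            cells = list(R.index)
        R = R.to_numpy()
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if n < 1:
        raise ValueError("need at least one cell")
    if cells is None:
        cells = list(range(n))
    P = transition_matrix(R, cfg.dangling_policy)
    u = np.full(n, 1.0 / n)
    r = cfg.restart_prob
    pi = u.copy()
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        nxt = r * u + (1 - r) * (P @ pi)
        delta = np.abs(nxt - pi).sum()
        pi = nxt
        if delta < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"random-walk iteration did not converge in {cfg.max_iter} "
            f"steps (last L1 change {delta:.3e})", RuntimeWarning)
    if r < 1.0:  # pure restart is exactly uniform; don't perturb it
        pi = pi / pi.sum()
    return CentralityResult(cells=tuple(cells), scores=pi,
                            iterations_used=iterations, converged=converged)
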