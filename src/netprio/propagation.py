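"""Propagation baselines: random walk with restart and PRINCE-style label propagation.

Both methods spread association signal from a set of seed genes over
the network by an iterative linear update, halting when the L1 change
between successive score vectors drops below a tolerance (1e-10 by
default, matching the convention under which the fixed parameters
r = 0.5 and alpha = 0.9 below were chosen).

Random walk with restart (RW)
    p(t+1) = (1 - r) * W * p(t) + r * p0,   p(0) = p0,
    with W column-stochastic (walker moves to a neighbor with
    probability proportional to the edge weight) and p0 uniform over
    the seed genes.  Isolated nodes get a self-transition so the walk
    conserves probability mass.

PRINCE-style propagation (PR)
    F(t) = alpha * W' * F(t-1) + (1 - alpha) * Y,   F(0) = Y,
    with W' = D^{-1/2} W D^{-1/2} the symmetrically degree-normalized
    adjacency and Y the binary seed indicator.  The iteration converges
    to (1 - alpha) (I - alpha W')^{-1} Y.  The prior here carries no
    phenotype-similarity weighting: seeds are marked 1, everything
    else 0.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable

import numpy as np
import scipy.sparse as sp

from .icn import RankedList, assign_ranks
from .network_io import GeneNetwork

__all__ = [
    "PropagationConfig",
    "ConvergenceError",
    "NodeScoreVector",
    "rw_transition_matrix",
    "random_walk",
    "prince_normalized_matrix",
    "prince_propagate",
    "propagation_ranked_list",
]


@dataclasses.dataclass(frozen=True)
class PropagationConfig:
    """Iteration parameters shared by both propagation methods.

    restart
        RW restart probability r: per-step probability of jumping back
        to the seed distribution.
    alpha
        PR smoothing weight: relative importance of network smoothing
        versus the seed prior.
    tolerance
        L1 halting threshold on the change between iterations.
    max_iterations
        Safety cap; exceeding it raises :class:`ConvergenceError`.
    """

    restart: float = 0.5
    alpha: float = 0.9
    tolerance: float = 1e-10
    max_iterations: int = 1_000_000

    def __post_init__(self):
        if not (0.0 <= self.restart <= 1.0):
            raise ValueError("restart probability must be in [0, 1]")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


class ConvergenceError(RuntimeError):
    """Iteration cap reached before the L1 halting criterion."""

    def __init__(self, method: str, iterations: int, residual: float):
        super().__init__(
            f"{method}: no convergence after {iterations} iterations "
            f"(last L1 residual {residual:.3e})"
        )
        self.method = method
        self.iterations = iterations
        self.residual = residual


class NodeScoreVector:
    """Final propagation scores over all network genes."""

    def __init__(
        self,
        genes,
        values,
        iterations: int,
        residuals,
        method: str,
        seeds: frozenset = frozenset(),
        history=None,
    ):
        self.genes: tuple[str, ...] = tuple(genes)
        self.values = np.asarray(values, dtype=float)
        self.iterations = int(iterations)
        self.residuals: tuple[float, ...] = tuple(float(r) for r in residuals)
        self.converged = True
        self.method = method
        self.seeds = frozenset(seeds)
        self.history = history  # list of per-iteration vectors when requested
        self._value_map = dict(zip(self.genes, self.values))
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("propagation scores must be finite and nonnegative")

    def __len__(self) -> int:
        return len(self.genes)

    def value_of(self, gene: str) -> float:
        return float(self._value_map[gene])

    def as_dict(self) -> dict[str, float]:
        return dict(self._value_map)


def rw_transition_matrix(network: GeneNetwork) -> sp.csr_matrix:
    """Column-stochastic walk operator: W[u, v] = w_uv / k_v.

    Isolated nodes receive a self-transition of 1 so every column sums
    to 1 and the walk conserves probability mass.
    """
    A = network.adjacency_matrix
    k = network.strengths
    inv_k = np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), 0.0)
    W = (A @ sp.diags(inv_k)).tocsr()
    isolated = np.flatnonzero(k == 0)
    if isolated.size:
        W = (W + sp.csr_matrix(
            (np.ones(isolated.size), (isolated, isolated)), shape=A.shape
        )).tocsr()
    return W


def prince_normalized_matrix(network: GeneNetwork) -> sp.csr_matrix:
    """Symmetric normalization W' = D^{-1/2} W D^{-1/2}; isolated rows stay zero."""
    A = network.adjacency_matrix
    k = network.strengths
    inv_sqrt = np.where(k > 0, 1.0 / np.sqrt(np.where(k > 0, k, 1.0)), 0.0)
    d = sp.diags(inv_sqrt)
    return (d @ A @ d).tocsr()


def _seed_vector(network: GeneNetwork, seeds: Iterable[str], uniform: bool) -> np.ndarray:
    seed_list = sorted(set(seeds))
    if not seed_list:
        raise ValueError("empty seed set")
    v = np.zeros(len(network.nodes))
    for s in seed_list:
        if s not in network:
            raise KeyError(f"seed gene {s!r} not in network")
        v[network.node_index[s]] = 1.0
    if uniform:
        v /= v.sum()
    return v


def _iterate(
    operator: sp.csr_matrix,
    base: np.ndarray,
    mix: float,
    start: np.ndarray,
    config: PropagationConfig,
    method: str,
    keep_history: bool,
):
    """Run x(t+1) = mix * operator @ x(t) + (1 - mix) * base until L1 convergence."""
    x = start.copy()
    residuals: list[float] = []
    history = [x.copy()] if keep_history else None
    for it in range(1, config.max_iterations + 1):
        x_next = mix * (operator @ x) + (1.0 - mix) * base
        res = float(np.abs(x_next - x).sum())
        residuals.append(res)
        x = x_next
        if keep_history:
            history.append(x.copy())
        if res < config.tolerance:
            return x, it, residuals, history
    raise ConvergenceError(method, config.max_iterations, residuals[-1])


def random_walk(
    network: GeneNetwork,
    seeds: Iterable[str],
    config: PropagationConfig | None = None,
    keep_history: bool = False,
) -> NodeScoreVector:
    """Random walk with restart from a uniform seed distribution."""
    config = config or PropagationConfig()
    p0 = _seed_vector(network, seeds, uniform=True)
    W = rw_transition_matrix(network)
    p, it, residuals, history = _iterate(
        W, p0, 1.0 - config.restart, p0, config, "random_walk", keep_history
    )
    return NodeScoreVector(
        network.nodes, p, it, residuals, method="rw", seeds=frozenset(seeds), history=history
    )


def prince_propagate(
    network: GeneNetwork,
    seeds: Iterable[str],
    config: PropagationConfig | None = None,
    keep_history: bool = False,
) -> NodeScoreVector:
    """PRINCE-style label propagation from a binary seed prior."""
    config = config or PropagationConfig()
    y = _seed_vector(network, seeds, uniform=False)
    Wn = prince_normalized_matrix(network)
    f, it, residuals, history = _iterate(
        Wn, y, config.alpha, y, config, "prince_propagate", keep_history
    )
    return NodeScoreVector(
        network.nodes, f, it, residuals, method="prince", seeds=frozenset(seeds), history=history
    )


def propagation_ranked_list(scores: NodeScoreVector, candidates: Iterable[str]) -> RankedList:
    """Restrict a propagation score vector to a candidate set and rank it."""
    cand_list = list(dict.fromkeys(candidates))
    missing = [c for c in cand_list if c not in scores._value_map]
    if missing:
        raise KeyError(f"candidates missing from score vector: {sorted(missing)}")
    return assign_ranks(
        ((c, scores.value_of(c)) for c in cand_list),
        method=scores.method,
        seeds=scores.seeds,
    )
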