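"""Stochastic ranking (Runarsson & Yao) over (objective, penalty) pairs.

A bubble-sort-like procedure compares adjacent individuals: when both are
feasible the comparison is by objective f; otherwise, with probability
``p_f`` by f and with probability ``1 - p_f`` by penalty phi.  This balances
descent in the objective against pressure toward the feasible region without
choosing penalty weights.  Ties never swap (stable), except that an exact
phi tie in a penalty comparison falls back to f, so the deterministic
``p_f = 0`` limit is the lexicographic (phi, f) sort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .problem import Individual

__all__ = ["RankingConfig", "stochastic_rank", "rank_arrays"]


@dataclass
class RankingConfig:
    """p_f: probability of an objective comparison when a pair is not all-feasible.

    n_sweeps defaults to the population size (enough for a complete bubble
    sort); sweeps stop early once a sweep makes no swap.
    """

    p_f: float = 0.45
    n_sweeps: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_f <= 1.0:
            raise ValueError("p_f must lie in [0, 1]")
        if self.n_sweeps is not None and self.n_sweeps < 1:
            raise ValueError("n_sweeps must be positive")


def rank_arrays(
    f: np.ndarray,
    phi: np.ndarray,
    p_f: float,
    rng: np.random.Generator,
    n_sweeps: Optional[int] = None,
    tol: float = 0.0,
) -> np.ndarray:
    """Rank by (f, phi) arrays; returns index permutation, best first."""
    f = np.asarray(f, dtype=float)
    phi = np.asarray(phi, dtype=float)
    lam = f.size
    if phi.size != lam:
        raise ValueError("f and phi must have equal length")
    sweeps = lam if n_sweeps is None else n_sweeps
    idx = np.arange(lam)
    if lam < 2:
        return idx
    # One uniform draw per potential comparison, taken up front so the number
    # of random variates consumed is independent of early termination.
    u = rng.random((sweeps, lam - 1))
    feas = phi <= tol
    for s in range(sweeps):
        swapped = False
        for j in range(lam - 1):
            a, b = idx[j], idx[j + 1]
            if (feas[a] and feas[b]) or u[s, j] < p_f:
                swap = f[a] > f[b]
            else:
                # penalty comparison; exact phi ties break by objective
                swap = phi[a] > phi[b] or (phi[a] == phi[b] and f[a] > f[b])
            if swap:
                idx[j], idx[j + 1] = b, a
                swapped = True
        if not swapped:
            break
    return idx


def stochastic_rank(
    population: Sequence[Individual],
    cfg: RankingConfig,
    rng: np.random.Generator,
    tol: float = 0.0,
) -> np.ndarray:
    """Return the ranking permutation of a fully evaluated population."""
    for ind in population:
        if not ind.evaluated:
            raise ValueError("rank before evaluation: population contains unevaluated individuals")
    f = np.array([ind.f for ind in population], dtype=float)
    phi = np.array([ind.phi for ind in population], dtype=float)
    return rank_arrays(f, phi, cfg.p_f, rng, n_sweeps=cfg.n_sweeps, tol=tol)
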