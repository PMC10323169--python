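"""Optimization problem contract: objective, constraints, penalty, fitness.

The package minimizes an objective ``f(x)`` over a bounded box, optionally
subject to inequality constraints ``g_j(x) <= 0``.  In the systems-biology
setting ``f`` is a sum-of-squares error between model predictions and
spatiotemporal observations, but any callable objective works.  Constraint
violation is summarized by a quadratic penalty

    phi(x) = sum_j max(0, g_j(x))**2

and a point is feasible when ``phi <= feasibility_tolerance``.  Selection
never uses a weighted combination of ``f`` and ``phi``: ranking balances the
two stochastically (see :mod:`isresplus.ranking`).  The combined score
``psi = f + r * phi`` is computed for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FAILED_OBJECTIVE",
    "ORIGINS",
    "BoundsBox",
    "Individual",
    "ProblemDefinition",
    "SpatioTemporalDataset",
    "evaluate_objective",
    "penalty",
    "fitness",
    "is_feasible",
]

#: Sentinel objective value for failed evaluations (solver blow-up, NaN).
#: Ranks strictly worse than any finite objective.
FAILED_OBJECTIVE = np.inf

#: Provenance tags for individuals, by the operator that created them.
ORIGINS = ("init", "recombination", "mutation", "linstep", "newton")


@dataclass(frozen=True)
class BoundsBox:
    """Axis-aligned search box ``lower[j] <= x[j] <= upper[j]``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper must be 1-d arrays of equal length")
        if lower.size < 1:
            raise ValueError("bounds must have dimension n >= 1")
        if not np.all(lower < upper):
            raise ValueError("require lower[j] < upper[j] for all j")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def n(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower) and np.all(x <= self.upper))

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """Map raw coordinates into the unit box (used for distances)."""
        return (np.asarray(x, dtype=float) - self.lower) / self.span


@dataclass
class Individual:
    """One candidate parameter vector with its self-adapted step sizes.

    ``eta`` holds the per-coordinate mutation step sizes (strategy
    parameters); ``origin`` records which operator created the individual.
    ``f``/``phi`` are ``None`` until evaluated.
    """

    x: np.ndarray
    eta: np.ndarray
    f: Optional[float] = None
    phi: Optional[float] = None
    feasible: Optional[bool] = None
    origin: str = "init"
    generation_born: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}; expected one of {ORIGINS}")
        if np.any(self.eta <= 0):
            raise ValueError("step sizes eta must be strictly positive")

    @property
    def evaluated(self) -> bool:
        return self.f is not None and self.phi is not None

    def copy(self) -> "Individual":
        return Individual(
            x=self.x.copy(),
            eta=self.eta.copy(),
            f=self.f,
            phi=self.phi,
            feasible=self.feasible,
            origin=self.origin,
            generation_born=self.generation_born,
        )


def penalty(g_values: Sequence[float]) -> float:
    """Quadratic constraint penalty ``sum_j max(0, g_j)**2`` (0 when m = 0)."""
    g = np.asarray(g_values, dtype=float)
    if g.size == 0:
        return 0.0
    return float(np.sum(np.maximum(0.0, g) ** 2))


def fitness(f: float, phi: float, r: float | Sequence[float] = 1.0) -> float:
    """Combined score ``psi = f + r * phi``, for reporting only.

    A vector ``r`` is applied per-constraint upstream (see
    :meth:`ProblemDefinition.psi`); here a scalar multiplies the already
    summed penalty.  Selection uses the (f, phi) pair under stochastic
    ranking, never psi.
    """
    r = float(np.asarray(r, dtype=float).sum()) if np.ndim(r) else float(r)
    return float(f + r * phi)


def is_feasible(phi: float, tol: float = 0.0) -> bool:
    """A point is feasible when its penalty does not exceed the tolerance."""
    return phi <= tol


class SpatioTemporalDataset:
    """Observations ``y_exp(s, t)`` over spatial/time coordinates plus a predictor.

    ``predictor(x, s, t)`` must accept coordinate arrays and return the model
    prediction at each (s, t) pair.  Serialized as CSV with columns s, t, y;
    the predictor is code and travels separately.
    """

    def __init__(
        self,
        coordinates: Sequence[tuple[float, float]],
        observations: Sequence[float],
        predictor: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    ) -> None:
        coords = np.asarray(coordinates, dtype=float)
        obs = np.asarray(observations, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coordinates must be (s, t) pairs")
        if coords.shape[0] != obs.size or obs.size < 1:
            raise ValueError("observations and coordinates must have equal length >= 1")
        self.s = coords[:, 0].copy()
        self.t = coords[:, 1].copy()
        self.observations = obs
        self.predictor = predictor

    def __len__(self) -> int:
        return self.observations.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"s": self.s, "t": self.t, "y": self.observations}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, predictor) -> "SpatioTemporalDataset":
        df = pd.read_csv(path)
        coords = np.column_stack([df["s"].to_numpy(float), df["t"].to_numpy(float)])
        return cls(coords, df["y"].to_numpy(float), predictor)


def evaluate_objective(x: np.ndarray, dataset: SpatioTemporalDataset) -> float:
    """Sum-of-squares error between model predictions and observations.

    Returns :data:`FAILED_OBJECTIVE` if the predictor raises or yields a
    non-finite value anywhere — such individuals are kept but ranked last.
    """
    try:
        pred = np.asarray(dataset.predictor(np.asarray(x, float), dataset.s, dataset.t), float)
    except Exception:
        return FAILED_OBJECTIVE
    if pred.shape != dataset.observations.shape or not np.all(np.isfinite(pred)):
        return FAILED_OBJECTIVE
    return float(np.sum((pred - dataset.observations) ** 2))


@dataclass
class ProblemDefinition:
    """The optimization contract: objective + constraints over a bounded box.

    ``penalty_coefficients`` (the vector r) weight constraints in the
    reported psi only; ranking is penalty-coefficient free.
    """

    objective: Callable[[np.ndarray], float]
    bounds: BoundsBox
    constraints: Sequence[Callable[[np.ndarray], float]] = field(default_factory=tuple)
    penalty_coefficients: Optional[np.ndarray] = None
    feasibility_tolerance: float = 0.0

    def __post_init__(self) -> None:
        self.constraints = tuple(self.constraints)
        if self.penalty_coefficients is None:
            self.penalty_coefficients = np.ones(len(self.constraints))
        else:
            self.penalty_coefficients = np.asarray(self.penalty_coefficients, dtype=float)
        if self.penalty_coefficients.size != len(self.constraints):
            raise ValueError("penalty_coefficients must have one entry per constraint")
        if np.any(self.penalty_coefficients < 0):
            raise ValueError("penalty coefficients must be non-negative")
        if self.feasibility_tolerance < 0:
            raise ValueError("feasibility_tolerance must be non-negative")

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    def constraint_values(self, x: np.ndarray) -> np.ndarray:
        return np.array([g(x) for g in self.constraints], dtype=float)

    def evaluate(self, x: np.ndarray) -> tuple[float, float]:
        """Return (f, phi); a failed objective maps to the sentinel worst value."""
        try:
            f = float(self.objective(np.asarray(x, dtype=float)))
        except Exception:
            f = FAILED_OBJECTIVE
        if not np.isfinite(f):
            f = FAILED_OBJECTIVE
        phi = penalty(self.constraint_values(x))
        return f, phi

    def evaluate_individual(self, ind: Individual) -> Individual:
        ind.f, ind.phi = self.evaluate(ind.x)
        ind.feasible = is_feasible(ind.phi, self.feasibility_tolerance)
        return ind

    def psi(self, x: np.ndarray) -> float:
        """Reported combined score with per-constraint coefficients r_j."""
        f, _ = self.evaluate(x)
        g = self.constraint_values(x)
        return float(f + np.sum(self.penalty_coefficients * np.maximum(0.0, g) ** 2))
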