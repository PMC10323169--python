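"""Built-in test problems: analytic benchmarks and synthetic ODE fixtures.

The benchmarks (sphere, Rosenbrock, a constrained toy) have known optima and
make every algorithmic claim testable offline.  The ODE fixtures emulate the
package's target use case — estimating kinetic parameters of a dynamical
model from noisy time-series observations by sum-of-squares error — at toy
scale: a 2-parameter exponential-decay model with a closed form, and a
3-species linear signaling cascade with 4 rate constants integrated by a
fixed-step RK4 scheme.  Parameters are searched over the wide box
[1e-4, 1e4] typical of kinetic rate constants whose magnitudes are unknown
a priori.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .problem import (
    BoundsBox,
    ProblemDefinition,
    SpatioTemporalDataset,
    evaluate_objective,
)

__all__ = [
    "BenchmarkProblem",
    "SyntheticODEFixture",
    "make_benchmark",
    "make_ode_fixture",
    "list_benchmarks",
    "DECAY_TRUE_PARAMS",
    "CASCADE_TRUE_PARAMS",
    "DEFAULT_TIMES",
]

#: Study-condition defaults for the decay fixture y(t) = A * exp(-k t).
DECAY_TRUE_PARAMS = np.array([2.0, 0.5])
#: Rate constants (k0, k1, k2, k3) of the linear cascade fixture.
CASCADE_TRUE_PARAMS = np.array([1.0, 0.8, 0.3, 0.1])
#: 20 sampling times over [0, 10].
DEFAULT_TIMES = np.linspace(0.0, 10.0, 20)

_SEARCH_LO, _SEARCH_HI = 1e-4, 1e4


@dataclass(frozen=True)
class BenchmarkProblem:
    name: str
    problem: ProblemDefinition
    known_optimum_x: Optional[np.ndarray] = None
    known_optimum_f: Optional[float] = None


@dataclass(frozen=True)
class SyntheticODEFixture:
    true_params: np.ndarray
    times: np.ndarray
    noise_sd: float
    seed: int
    dataset: SpatioTemporalDataset
    model: str = "decay"

    @property
    def x_true(self) -> np.ndarray:
        """The generating parameters in the search space (log10 rates)."""
        return np.log10(self.true_params)

    @staticmethod
    def params_from_x(x: np.ndarray) -> np.ndarray:
        """Map a search vector back to raw kinetic parameters."""
        return 10.0 ** np.asarray(x, dtype=float)


def _verify(bp: BenchmarkProblem) -> BenchmarkProblem:
    """Check the declared optimum by evaluation before handing the problem out."""
    if bp.known_optimum_x is not None:
        f, phi = bp.problem.evaluate(bp.known_optimum_x)
        if abs(f - bp.known_optimum_f) > 1e-10:
            raise AssertionError(f"{bp.name}: optimum value mismatch ({f} vs {bp.known_optimum_f})")
        if phi > bp.problem.feasibility_tolerance:
            raise AssertionError(f"{bp.name}: declared optimum violates constraints")
    return bp


def _sphere(n: int) -> BenchmarkProblem:
    bounds = BoundsBox(np.full(n, -5.0), np.full(n, 5.0))
    return BenchmarkProblem(
        name=f"sphere_{n}",
        problem=ProblemDefinition(lambda x: float(np.sum(x**2)), bounds),
        known_optimum_x=np.zeros(n),
        known_optimum_f=0.0,
    )


def _rosenbrock(n: int) -> BenchmarkProblem:
    if n < 2:
        raise ValueError("rosenbrock needs n >= 2")
    bounds = BoundsBox(np.full(n, -5.0), np.full(n, 10.0))

    def f(x: np.ndarray) -> float:
        return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))

    return BenchmarkProblem(
        name=f"rosenbrock_{n}",
        problem=ProblemDefinition(f, bounds),
        known_optimum_x=np.ones(n),
        known_optimum_f=0.0,
    )


def _constrained_disk() -> BenchmarkProblem:
    # minimize x1^2 + x2^2  subject to  1 - x1 <= 0; optimum f = 1 at (1, 0)
    bounds = BoundsBox(np.full(2, -10.0), np.full(2, 10.0))
    problem = ProblemDefinition(
        lambda x: float(np.sum(x**2)),
        bounds,
        constraints=(lambda x: float(1.0 - x[0]),),
    )
    return BenchmarkProblem(
        name="constrained_disk",
        problem=problem,
        known_optimum_x=np.array([1.0, 0.0]),
        known_optimum_f=1.0,
    )


def list_benchmarks() -> list[str]:
    return ["sphere_<n>", "rosenbrock_<n>", "constrained_disk", "decay_fixture", "cascade_fixture"]


def make_benchmark(name: str) -> BenchmarkProblem:
    """Look up a named analytic benchmark (e.g. 'sphere_3', 'constrained_disk')."""
    if name == "constrained_disk":
        return _verify(_constrained_disk())
    for prefix, factory in (("sphere_", _sphere), ("rosenbrock_", _rosenbrock)):
        if name.startswith(prefix):
            try:
                n = int(name[len(prefix):])
            except ValueError:
                break
            return _verify(factory(n))
    raise KeyError(f"unknown benchmark {name!r}; available: {list_benchmarks()}")


# -- ODE fixtures -----------------------------------------------------------


def _decay_predictor(x: np.ndarray, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    A, k = x
    return A * np.exp(-k * t)


def _rk4(deriv, y0: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Classic fixed-step 4th-order Runge-Kutta over a uniform grid."""
    ys = np.empty((t_grid.size, y0.size))
    ys[0] = y0
    y = y0.astype(float)
    for i in range(t_grid.size - 1):
        h = t_grid[i + 1] - t_grid[i]
        k1 = deriv(t_grid[i], y)
        k2 = deriv(t_grid[i] + h / 2, y + h / 2 * k1)
        k3 = deriv(t_grid[i] + h / 2, y + h / 2 * k2)
        k4 = deriv(t_grid[i] + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        ys[i + 1] = y
    return ys


def _cascade_solution(params: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Species trajectories of dy1 = k0 - k1 y1; dy2 = k1 y1 - k2 y2; dy3 = k2 y2 - k3 y3.

    Integrated with fixed-step RK4 at h = min(dt)/10 from y(0) = 0, then
    linearly interpolated onto the requested times.
    """
    k0, k1, k2, k3 = params

    def deriv(_t, y):
        return np.array(
            [k0 - k1 * y[0], k1 * y[0] - k2 * y[1], k2 * y[1] - k3 * y[2]]
        )

    t_max = float(np.max(times))
    dts = np.diff(np.unique(times))
    h = float(np.min(dts)) / 10.0 if dts.size else max(t_max, 1.0) / 100.0
    n_steps = max(int(np.ceil(t_max / h)), 1)
    grid = np.linspace(0.0, t_max, n_steps + 1)
    ys = _rk4(deriv, np.zeros(3), grid)
    out = np.empty((times.size, 3))
    for j in range(3):
        out[:, j] = np.interp(times, grid, ys[:, j])
    return out


def _cascade_predictor(x: np.ndarray, s: np.ndarray, t: np.ndarray) -> np.ndarray:
    # rate constants above ~1e3 on this grid overflow RK4; flag as failed
    if np.any(x[1:] > 2.0 / (np.min(np.diff(np.unique(t))) / 10.0)):
        raise FloatingPointError("stiff parameters exceed the fixed-step stability limit")
    traj = _cascade_solution(x, np.unique(t))
    t_unique = np.unique(t)
    t_index = np.searchsorted(t_unique, t)
    species = s.astype(int)
    return traj[t_index, species]


def make_ode_fixture(
    true_params: Optional[Sequence[float]] = None,
    times: Optional[Sequence[float]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    model: str = "decay",
) -> tuple[SyntheticODEFixture, ProblemDefinition]:
    """Generate a synthetic dataset and its SSE estimation problem.

    Observations are the model at the true parameters plus additive Gaussian
    noise of standard deviation ``noise_sd`` (seeded, bit-reproducible).  The
    returned problem minimizes the sum-of-squares error over log10-scaled
    parameters spanning [1e-4, 1e4]; use ``fixture.params_from_x`` to map a
    solution back to raw rates.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(DEFAULT_TIMES if times is None else times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if model == "decay":
        true = np.asarray(DECAY_TRUE_PARAMS if true_params is None else true_params, float)
        s = np.zeros_like(times)
        t = times
        predictor = _decay_predictor
    elif model == "cascade":
        true = np.asarray(CASCADE_TRUE_PARAMS if true_params is None else true_params, float)
        # observe all three species at every time; s is the species index
        s = np.repeat(np.arange(3.0), times.size)
        t = np.tile(times, 3)
        predictor = _cascade_predictor
    else:
        raise KeyError(f"unknown fixture model {model!r}; use 'decay' or 'cascade'")

    rng = np.random.Generator(np.random.PCG64(seed))
    clean = np.asarray(predictor(true, s, t), float)
    y = clean + (rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else 0.0)
    dataset = SpatioTemporalDataset(np.column_stack([s, t]), y, predictor)
    fixture = SyntheticODEFixture(
        true_params=true, times=times, noise_sd=noise_sd, seed=seed,
        dataset=dataset, model=model,
    )
    # Rate constants of unknown magnitude are searched on a log10 scale:
    # the box [1e-4, 1e4] per parameter becomes [-4, 4] in search space,
    # which weights each decade equally (the engine itself applies no
    # transformation; the fixture is the caller and pre-transforms).
    n = true.size
    bounds = BoundsBox(
        np.full(n, np.log10(_SEARCH_LO)), np.full(n, np.log10(_SEARCH_HI))
    )
    problem = ProblemDefinition(
        lambda z: evaluate_objective(10.0**z, dataset), bounds
    )
    return fixture, problem
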