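"""Least-squares landscape approximation: archive, clusters, Linstep, Newton step.

ISRES+ differs from baseline ISRES by mining the full cross-generation
evolutionary history.  Every evaluated individual is appended to an
:class:`Archive`.  Around the incumbent best, the nearest feasible archive
points form a "cluster bubble"; linear least squares over the cluster fits

* a hyperplane  f ~ a0 + a.x        -> approximate gradient v = a  (Linstep)
* a quadric     f - f_best ~ g.D + D.H.D/2,  D = x - x_best
                                    -> approximate gradient g and Hessian H
                                       (Newton step)

Linstep translates the fittest cluster members a distance
``beta_lin * d_cluster`` along the unit steepest-descent direction;
Newton step applies one iteration ``x_best - beta * H^{-1} g`` of Newton's
method.  Neither operator evaluates the objective to build its model: the
archive already paid for those evaluations.

Cluster distances are measured in box-normalized coordinates so that
parameters spanning wildly different scales (the usual 1e-4..1e4 search box)
contribute comparably; the step length d_cluster is taken in raw parameter
units so the move lives in parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .problem import BoundsBox, Individual, ORIGINS

__all__ = [
    "Archive",
    "Cluster",
    "SurfaceFit",
    "NotEnoughPoints",
    "OperatorSkip",
    "StagnationGuard",
    "update_archive",
    "select_cluster",
    "cluster_diameter",
    "fit_hyperplane",
    "fit_quadric",
    "linstep_offspring",
    "newton_offspring",
]

_ORIGIN_CODE = {name: i for i, name in enumerate(ORIGINS)}

#: Design-matrix condition number beyond which a fit is declared ill-conditioned.
COND_THRESHOLD = 1e10
#: Relative residual of the least-squares solve beyond which a fit is rejected.
RESIDUAL_THRESHOLD = 1e-6


class NotEnoughPoints(ValueError):
    """Raised when a cluster is too small for the requested polynomial fit."""


class OperatorSkip(RuntimeError):
    """Raised when an operator cannot act this generation (slots revert to mutation)."""


class Archive:
    """Append-only store of every evaluated individual across all generations.

    Backed by growing numpy buffers so nearest-neighbour queries against tens
    of thousands of records stay vectorized.  Records are never mutated after
    insertion.  A ring-buffer ``capacity`` may be set for very long runs; by
    default all history is kept.
    """

    def __init__(self, n: int, capacity: Optional[int] = None) -> None:
        if n < 1:
            raise ValueError("dimension n must be >= 1")
        self.n = n
        self.capacity = capacity
        self._size = 0
        self._alloc = 256
        self._x = np.empty((self._alloc, n))
        self._eta = np.empty((self._alloc, n))
        self._f = np.empty(self._alloc)
        self._phi = np.empty(self._alloc)
        self._feasible = np.empty(self._alloc, dtype=bool)
        self._origin = np.empty(self._alloc, dtype=np.int8)
        self._generation = np.empty(self._alloc, dtype=np.int32)

    def __len__(self) -> int:
        return self._size

    def _grow(self, need: int) -> None:
        while self._alloc < need:
            self._alloc *= 2
        for name in ("_x", "_eta", "_f", "_phi", "_feasible", "_origin", "_generation"):
            old = getattr(self, name)
            new = np.empty((self._alloc,) + old.shape[1:], dtype=old.dtype)
            new[: self._size] = old[: self._size]
            setattr(self, name, new)

    def append(self, individuals: Sequence[Individual]) -> None:
        for ind in individuals:
            if not ind.evaluated:
                raise ValueError("archive only accepts evaluated individuals")
        need = self._size + len(individuals)
        if need > self._alloc:
            self._grow(need)
        for ind in individuals:
            i = self._size
            self._x[i] = ind.x
            self._eta[i] = ind.eta
            self._f[i] = ind.f
            self._phi[i] = ind.phi
            self._feasible[i] = bool(ind.feasible)
            self._origin[i] = _ORIGIN_CODE[ind.origin]
            self._generation[i] = ind.generation_born
            self._size += 1
        if self.capacity is not None and self._size > self.capacity:
            drop = self._size - self.capacity
            for name in ("_x", "_eta", "_f", "_phi", "_feasible", "_origin", "_generation"):
                arr = getattr(self, name)
                arr[: self.capacity] = arr[drop : self._size]
            self._size = self.capacity

    @property
    def x(self) -> np.ndarray:
        return self._x[: self._size]

    @property
    def eta(self) -> np.ndarray:
        return self._eta[: self._size]

    @property
    def f(self) -> np.ndarray:
        return self._f[: self._size]

    @property
    def phi(self) -> np.ndarray:
        return self._phi[: self._size]

    @property
    def feasible(self) -> np.ndarray:
        return self._feasible[: self._size]

    @property
    def origin(self) -> np.ndarray:
        return np.array([ORIGINS[c] for c in self._origin[: self._size]])

    @property
    def generation(self) -> np.ndarray:
        return self._generation[: self._size]

    def record(self, i: int) -> Individual:
        """Reconstruct record i as an Individual (a copy; the store is immutable)."""
        return Individual(
            x=self._x[i].copy(),
            eta=self._eta[i].copy(),
            f=float(self._f[i]),
            phi=float(self._phi[i]),
            feasible=bool(self._feasible[i]),
            origin=ORIGINS[self._origin[i]],
            generation_born=int(self._generation[i]),
        )

    def to_dataframe(self):
        """Archive dump for post-hoc landscape inspection (x, f, phi, origin, gen)."""
        import pandas as pd

        d = {f"x{j}": self.x[:, j] for j in range(self.n)}
        d.update(
            f=self.f.copy(),
            phi=self.phi.copy(),
            feasible=self.feasible.copy(),
            origin=self.origin,
            generation=self.generation.copy(),
        )
        return pd.DataFrame(d)


def update_archive(archive: Archive, generation: Sequence[Individual]) -> Archive:
    """Append an evaluated generation to the archive (in place; returned for chaining)."""
    archive.append(generation)
    return archive


@dataclass
class Cluster:
    """The incumbent best plus its nearest feasible archive points, nearest first."""

    center_x: np.ndarray
    center_f: float
    center_eta: np.ndarray
    member_x: np.ndarray  # (k, n), sorted by normalized distance to center
    member_f: np.ndarray
    member_eta: np.ndarray
    complete: bool = True  # False when fewer than the requested k points existed

    @property
    def k(self) -> int:
        return self.member_x.shape[0]

    def points(self) -> np.ndarray:
        """All cluster points including the center, center first."""
        return np.vstack([self.center_x[None, :], self.member_x])

    def values(self) -> np.ndarray:
        return np.concatenate([[self.center_f], self.member_f])


@dataclass
class SurfaceFit:
    """Result of a polynomial least-squares fit over a cluster."""

    order: int
    gradient: np.ndarray
    hessian: Optional[np.ndarray] = None
    condition_ok: bool = True
    points_used: int = 0
    cond: float = np.nan
    rel_residual: float = np.nan


def select_cluster(
    archive: Archive, best: Individual, k: int, bounds: BoundsBox
) -> Cluster:
    """The k feasible archive records nearest to the incumbent best.

    Distances are Euclidean in box-normalized coordinates.  Exact duplicates
    of the best's x and duplicate records are dropped (duplicates would make
    the fit exactly rank-deficient).  If fewer than k distinct feasible
    records exist, all are returned with ``complete=False``.
    """
    if k < 1:
        raise ValueError("cluster size k must be >= 1")
    mask = archive.feasible & np.isfinite(archive.f)
    if not np.any(mask):
        return Cluster(
            center_x=best.x.copy(),
            center_f=float(best.f),
            center_eta=best.eta.copy(),
            member_x=np.empty((0, archive.n)),
            member_f=np.empty(0),
            member_eta=np.empty((0, archive.n)),
            complete=False,
        )
    idx_feas = np.nonzero(mask)[0]
    xs = archive.x[idx_feas]
    z = (xs - bounds.lower) / bounds.span
    z0 = bounds.normalize(best.x)
    dist = np.sqrt(np.sum((z - z0) ** 2, axis=1))
    order = np.argsort(dist, kind="stable")
    seen = {best.x.tobytes()}
    picked: list[int] = []
    for o in order:
        key = xs[o].tobytes()
        if key in seen:
            continue
        seen.add(key)
        picked.append(idx_feas[o])
        if len(picked) == k:
            break
    picked_arr = np.array(picked, dtype=int)
    return Cluster(
        center_x=best.x.copy(),
        center_f=float(best.f),
        center_eta=best.eta.copy(),
        member_x=archive.x[picked_arr].copy() if picked else np.empty((0, archive.n)),
        member_f=archive.f[picked_arr].copy() if picked else np.empty(0),
        member_eta=archive.eta[picked_arr].copy() if picked else np.empty((0, archive.n)),
        complete=len(picked) == k,
    )


def cluster_diameter(cluster: Cluster) -> float:
    """Maximum pairwise Euclidean distance (raw units) over members + center."""
    pts = cluster.points()
    if pts.shape[0] < 2:
        return 0.0
    return float(pdist(pts).max())


def normalized_diameter(cluster: Cluster, bounds: BoundsBox) -> float:
    """Cluster diameter after mapping points into the unit box (stagnation metric)."""
    pts = (cluster.points() - bounds.lower) / bounds.span
    if pts.shape[0] < 2:
        return 0.0
    return float(pdist(pts).max())


def _solve_scaled(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, int]:
    """Least-squares solve with column equilibration; returns (c, cond, rel_res, rank)."""
    col = np.linalg.norm(A, axis=0)
    col[col == 0] = 1.0
    As = A / col
    c, _, rank, sv = np.linalg.lstsq(As, y, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv.size and sv[-1] > 0 else np.inf
    res = float(np.linalg.norm(As @ c - y))
    scale = max(float(np.linalg.norm(y)), 1e-300)
    return c / col, cond, res / scale, int(rank)


def fit_hyperplane(cluster: Cluster) -> SurfaceFit:
    """First-order fit f ~ a0 + a.x over the cluster; gradient v = a.

    Requires at least n+1 points (center + n members).  Coordinates are
    centered on the best and scaled by the cluster diameter before solving,
    so the condition number reflects the cluster's geometry, not its scale.
    """
    pts = cluster.points()
    y = cluster.values()
    n = pts.shape[1]
    if pts.shape[0] < n + 1:
        raise NotEnoughPoints(f"hyperplane fit needs >= {n + 1} points, got {pts.shape[0]}")
    d = cluster_diameter(cluster)
    scale = d if d > 0 else 1.0
    D = (pts - cluster.center_x) / scale
    A = np.column_stack([np.ones(pts.shape[0]), D])
    c, cond, rel_res, rank = _solve_scaled(A, y)
    grad = c[1:] / scale
    ok = (
        rank == n + 1
        and np.isfinite(cond)
        and cond <= COND_THRESHOLD
        and rel_res <= RESIDUAL_THRESHOLD
    )
    return SurfaceFit(
        order=1,
        gradient=grad,
        condition_ok=bool(ok),
        points_used=pts.shape[0],
        cond=cond,
        rel_residual=rel_res,
    )


def _quadric_columns(D: np.ndarray) -> np.ndarray:
    """Design columns for g.D + D.H.D/2 with H symmetric (n + n(n+1)/2 unknowns)."""
    n = D.shape[1]
    cols = [D]
    cols.append(0.5 * D**2)  # coefficients H_jj
    cross = [D[:, j] * D[:, l] for j in range(n) for l in range(j + 1, n)]
    if cross:
        cols.append(np.column_stack(cross))  # coefficients H_jl (j < l)
    return np.column_stack(cols)


def quadric_min_points(n: int) -> int:
    """Members needed beyond the center for a determined quadric fit."""
    return n + n * (n + 1) // 2


def fit_quadric(cluster: Cluster) -> SurfaceFit:
    """Second-order fit f - f_best ~ g.D + D.H.D/2 around the incumbent best.

    The center contributes the (trivial) D = 0 equation, so the fit needs
    ``n + n(n+1)/2`` members beyond the center.  Returns the approximate
    gradient g at the best and the symmetric Hessian H.
    """
    n = cluster.center_x.size
    need = quadric_min_points(n)
    if cluster.k < need:
        raise NotEnoughPoints(f"quadric fit needs >= {need} cluster members, got {cluster.k}")
    d = cluster_diameter(cluster)
    scale = d if d > 0 else 1.0
    D = (cluster.member_x - cluster.center_x) / scale
    y = cluster.member_f - cluster.center_f
    A = _quadric_columns(D)
    c, cond, rel_res, rank = _solve_scaled(A, y)
    g = c[:n] / scale
    H = np.zeros((n, n))
    diag = c[n : 2 * n] / scale**2
    H[np.diag_indices(n)] = diag
    pos = 2 * n
    for j in range(n):
        for l in range(j + 1, n):
            H[j, l] = H[l, j] = c[pos] / scale**2
            pos += 1
    ok = (
        rank == A.shape[1]
        and np.isfinite(cond)
        and cond <= COND_THRESHOLD
        and rel_res <= RESIDUAL_THRESHOLD
    )
    return SurfaceFit(
        order=2,
        gradient=g,
        hessian=H,
        condition_ok=bool(ok),
        points_used=cluster.k + 1,
        cond=cond,
        rel_residual=rel_res,
    )


def linstep_offspring(
    cluster: Cluster,
    fit: SurfaceFit,
    beta_lin: float,
    n_lin: int,
    bounds: BoundsBox,
    rng: np.random.Generator,
    generation: int = 0,
) -> list[Individual]:
    """Translate the n_lin fittest cluster members along steepest descent.

    Each source point moves ``beta_lin * d_cluster`` along -v/|v| (the
    gradient is unit-normalized so beta_lin directly compares the step to the
    cluster-bubble diameter).  Step sizes eta are inherited from the source.
    """
    from .engine import repair_bounds  # local import to avoid a cycle

    if fit.order != 1:
        raise ValueError("linstep requires an order-1 fit")
    if not fit.condition_ok:
        raise OperatorSkip("linstep: ill-conditioned hyperplane fit")
    d = cluster_diameter(cluster)
    vnorm = float(np.linalg.norm(fit.gradient))
    # the fitted slope must predict an f-change resolvable at double precision
    fscale = float(np.max(np.abs(cluster.values()))) or 1.0
    if d <= 0 or not np.isfinite(vnorm) or d * vnorm <= 64 * np.finfo(float).eps * fscale:
        raise OperatorSkip("linstep: degenerate cluster (zero diameter or zero gradient)")
    vhat = fit.gradient / vnorm
    # candidate sources ordered by fitness, incumbent best first
    xs = cluster.points()
    fs = cluster.values()
    etas = np.vstack([cluster.center_eta[None, :], cluster.member_eta])
    order = np.concatenate([[0], 1 + np.argsort(fs[1:], kind="stable")])
    out: list[Individual] = []
    for rank_i in range(min(n_lin, xs.shape[0])):
        src = order[rank_i]
        x_new = xs[src] - beta_lin * d * vhat
        eta = etas[src].copy()
        x_new = repair_bounds(x_new, eta, bounds, rng, center=xs[src])
        out.append(
            Individual(x=x_new, eta=eta, origin="linstep", generation_born=generation)
        )
    return out


def newton_offspring(
    best: Individual,
    fit: SurfaceFit,
    n_newt: int,
    mode: str,
    rng: np.random.Generator,
    bounds: BoundsBox,
    generation: int = 0,
) -> list[Individual]:
    """One (damped) Newton iteration from the incumbent best.

    Solves H s = g (never inverting H explicitly) and steps x_best - beta*s.
    A single contribution takes the full step beta = 1; additional ones draw
    beta uniformly from (0, 1].  With ``mode='uniform_random'`` every beta is
    random.  Singular or numerically failed solves skip the operator.
    """
    from .engine import repair_bounds

    if fit.order != 2 or fit.hessian is None:
        raise ValueError("newton step requires an order-2 fit")
    if not fit.condition_ok:
        raise OperatorSkip("newton: ill-conditioned quadric fit")
    try:
        step = np.linalg.solve(fit.hessian, fit.gradient)
    except np.linalg.LinAlgError as exc:
        raise OperatorSkip(f"newton: singular Hessian ({exc})") from exc
    if not np.all(np.isfinite(step)):
        raise OperatorSkip("newton: non-finite Newton step")
    gnorm = float(np.linalg.norm(fit.gradient))
    if gnorm > 0:
        back = float(np.linalg.norm(fit.hessian @ step - fit.gradient)) / gnorm
        if back > RESIDUAL_THRESHOLD:
            raise OperatorSkip("newton: inaccurate linear solve")
    out: list[Individual] = []
    for i in range(n_newt):
        if mode == "full_step" and i == 0:
            beta = 1.0
        else:
            beta = 1.0 - rng.random()  # uniform on (0, 1]
        x_new = best.x - beta * step
        eta = best.eta.copy()
        x_new = repair_bounds(x_new, eta, bounds, rng, center=best.x)
        out.append(
            Individual(x=x_new, eta=eta, origin="newton", generation_born=generation)
        )
    return out


@dataclass
class StagnationGuard:
    """Silence Linstep/Newton while the evolutionary search is stuck.

    When the normalized cluster bubble shrinks below ``eps`` without the
    incumbent best improving, the landscape operators would keep re-fitting
    the same degenerate neighbourhood; they are silenced until the stochastic
    operators find a new best-fit individual, which re-activates them
    immediately.
    """

    eps: float = 1e-6
    silenced: bool = field(default=False)

    def decide(self, norm_diameter: float, incumbent_improved: bool) -> bool:
        """Return True when the operators may act this generation."""
        if incumbent_improved:
            self.silenced = False
            return True
        if norm_diameter < self.eps:
            self.silenced = True
        return not self.silenced


def stagnation_guard(
    cluster: Cluster,
    incumbent_improved: bool,
    state: StagnationGuard,
    bounds: BoundsBox,
) -> bool:
    """Functional wrapper around :meth:`StagnationGuard.decide`."""
    return state.decide(normalized_diameter(cluster, bounds), incumbent_improved)
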