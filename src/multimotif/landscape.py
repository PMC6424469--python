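"""Quasi-potential landscapes and minimum action paths.

The steady-state probability of the stochastic dynamics is
approximated self-consistently: around each attractor ``k`` the mean
follows the deterministic flow and the (diagonal) covariance obeys

    dsigma/dt = sigma A^T + A^T sigma + 2 D,

with ``A`` the Jacobian of the drift ``F``.  At a stable fixed point
the stationary diagonal variance is ``sigma_i* = -D / A_ii``.  The
total steady-state density is a weighted mixture of axis-aligned
Gaussians, one per attractor, and the quasi-potential is
``U(x) = -ln Pss(x)``.

Transition paths between attractors minimize the Freidlin-Wentzell
action ``S_T[phi] = 1/2 * int_0^T |dphi/dt - F(phi)|^2 dt`` over paths
with fixed endpoints; the minimal value is the transition action.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .attractors import AttractorSet, find_attractors
from .model import HillModel


# ---------------------------------------------------------------------------
# moment equations


@dataclass
class MomentState:
    mean: np.ndarray
    variance: np.ndarray  # diagonal of sigma
    D: float


def solve_moment_equations(model: HillModel, D: float, start: np.ndarray,
                           t_end: float = 500.0) -> MomentState:
    """Integrate mean + diagonal-covariance moment equations from ``start``.

    The mean converges to the attractor of ``start``'s basin; the
    variance is then polished with the stationary closed form
    ``sigma_i* = -D / A_ii`` at the converged mean (exact for linear
    drift, e.g. an Ornstein-Uhlenbeck process).
    """
    dim = model.n_dim

    def rhs(t, y):
        x = np.maximum(y[:dim], 0.0)
        sig = y[dim:]
        a_diag = np.diag(model.jacobian(x))
        return np.concatenate([model.rhs(x), 2.0 * a_diag * sig + 2.0 * D])

    y0 = np.concatenate([np.asarray(start, dtype=float), np.full(dim, D)])
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=1e-10, atol=1e-12)
    mean = np.maximum(sol.y[:dim, -1], 0.0)
    sig = sol.y[dim:, -1]
    if np.any(sig < 0):
        warnings.warn("negative variance clipped to zero in moment integration")
        sig = np.maximum(sig, 0.0)
    a_diag = np.diag(model.jacobian(mean))
    if np.all(a_diag < 0):
        sig = -D / a_diag  # stationary solution of the diagonal moment equation
    return MomentState(mean=mean, variance=sig, D=D)


def attractor_moments(model: HillModel, attractors: AttractorSet, D: float
                      ) -> list[MomentState]:
    """Stationary (mean, variance) for each stable attractor."""
    out = []
    for state, ok in zip(attractors.states, attractors.stable):
        if not ok:
            continue
        a_diag = np.diag(model.jacobian(np.maximum(state, 0.0)))
        if np.any(a_diag >= 0):
            raise ValueError("attractor with non-negative diagonal Jacobian entry")
        out.append(MomentState(mean=np.asarray(state, dtype=float),
                               variance=-D / a_diag, D=D))
    return out


# ---------------------------------------------------------------------------
# landscape grids


@dataclass
class LandscapeGrid:
    """Mixture-of-Gaussians steady-state density on a product grid.

    The mixture is separable per attractor, so the full grid is stored
    implicitly: ``axes[i]`` holds the grid of dimension ``i`` and
    ``component(k, i)`` the 1D Gaussian factor of attractor ``k`` on
    that axis.  Dense ``Pss``/``U`` arrays are materialized only for
    1D/2D views.
    """

    axes: list[np.ndarray]
    moments: list[MomentState]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        self.weights = w / w.sum()
        for m in self.moments:
            if np.any(m.variance <= 0):
                raise ValueError(
                    "degenerate zero-variance mixture component; increase D")

    @property
    def n_dim(self) -> int:
        return len(self.axes)

    def component(self, k: int, dim: int) -> np.ndarray:
        m = self.moments[k]
        ax = self.axes[dim]
        var = m.variance[dim]
        return np.exp(-((ax - m.mean[dim]) ** 2) / (2.0 * var)) / np.sqrt(
            2.0 * np.pi * var)

    def component_mass(self, k: int, dim: int) -> float:
        """Numerical (trapezoid) mass of one 1D factor on its axis."""
        return float(np.trapezoid(self.component(k, dim), self.axes[dim]))

    def total_mass(self) -> float:
        """Grid-integrated Pss (1 up to Gaussian truncation error)."""
        total = 0.0
        for k, w in enumerate(self.weights):
            mass = w
            for dim in range(self.n_dim):
                mass *= self.component_mass(k, dim)
            total += mass
        return total

    def pss(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        total = 0.0
        for k, w in enumerate(self.weights):
            m = self.moments[k]
            z = (x - m.mean) ** 2 / (2.0 * m.variance)
            norm = np.prod(np.sqrt(2.0 * np.pi * m.variance))
            total += w * np.exp(-z.sum()) / norm
        return float(total)

    def potential(self, x: np.ndarray) -> float:
        return -np.log(max(self.pss(x), 1e-300))

    def dense_pss(self, dims: tuple[int, ...] | None = None) -> np.ndarray:
        """Dense marginal Pss over the kept ``dims`` (others integrated out)."""
        if dims is None:
            dims = tuple(range(self.n_dim))
        if len(dims) > 2:
            raise ValueError("dense grids supported for at most 2 dimensions")
        shape = tuple(len(self.axes[d]) for d in dims)
        out = np.zeros(shape)
        for k, w in enumerate(self.weights):
            mass = w
            for d in range(self.n_dim):
                if d not in dims:
                    mass *= self.component_mass(k, d)
            factors = [self.component(k, d) for d in dims]
            if len(dims) == 1:
                out += mass * factors[0]
            else:
                out += mass * np.outer(factors[0], factors[1])
        return out

    def dense_potential(self, dims: tuple[int, ...] | None = None) -> np.ndarray:
        return -np.log(np.maximum(self.dense_pss(dims), 1e-300))


def build_landscape(model: HillModel, D: float = 0.01,
                    attractors: AttractorSet | None = None,
                    weights: str | np.ndarray = "basin",
                    n_grid: int = 100, margin: float = 1.2,
                    seed: int = 0) -> LandscapeGrid:
    """Self-consistent mean-field landscape for ``model``.

    Mixture weights default to the empirical basin occupancies of the
    multi-start attractor search ("basin"); pass "equal" or an explicit
    vector to override.  Axes span ``[0, margin * max attractor
    coordinate]`` with ``n_grid`` points.
    """
    if attractors is None:
        attractors = find_attractors(model, seed=seed)
    moments = attractor_moments(model, attractors, D)
    if not moments:
        raise ValueError("model has no stable attractor")
    if isinstance(weights, str):
        if weights == "basin":
            w = np.array([c for c, ok in zip(attractors.basin_counts,
                                             attractors.stable) if ok], dtype=float)
            if w.sum() == 0:
                w = np.ones(len(moments))
        elif weights == "equal":
            w = np.ones(len(moments))
        else:
            raise ValueError(f"unknown weight scheme {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)
    hi = margin * max(m.mean.max() for m in moments)
    hi = max(hi, 1e-2)
    # extend below zero so that components near the axis keep their full
    # Gaussian mass on the grid (the approximation's support, not physics)
    lo = min(0.0, min(float(m.mean[i] - 8.0 * np.sqrt(m.variance[i]))
                      for m in moments for i in range(model.n_dim)))
    axes = [np.linspace(lo, hi, n_grid) for _ in range(model.n_dim)]
    return LandscapeGrid(axes=axes, moments=moments, weights=w)


def project_landscape(grid: LandscapeGrid, keep_dims: tuple[int, int]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """2D marginal of the landscape: ``(axis0, axis1, Pss, U)``.

    Dropped dimensions are integrated out numerically (trapezoid on
    each separable factor).
    """
    if len(keep_dims) != 2 or any(d >= grid.n_dim for d in keep_dims):
        raise ValueError("keep_dims must name two valid dimensions")
    pss = grid.dense_pss(tuple(keep_dims))
    u = -np.log(np.maximum(pss, 1e-300))
    return grid.axes[keep_dims[0]], grid.axes[keep_dims[1]], pss, u


def count_local_minima_2d(u: np.ndarray) -> int:
    """Interior strict local minima of a 2D potential surface (4-neighborhood)."""
    c = u[1:-1, 1:-1]
    return int(np.sum((c < u[:-2, 1:-1]) & (c < u[2:, 1:-1]) &
                      (c < u[1:-1, :-2]) & (c < u[1:-1, 2:])))


# ---------------------------------------------------------------------------
# action functional and minimum action paths


def path_action(path: np.ndarray, times: np.ndarray, model: HillModel) -> float:
    """Freidlin-Wentzell action of a discretized path.

    Midpoint discretization: per segment the velocity is the finite
    difference and the drift is evaluated at the segment midpoint;
    segment Lagrangians are summed with their time steps (trapezoid in
    time).
    """
    phi = np.asarray(path, dtype=float)
    t = np.asarray(times, dtype=float)
    total = 0.0
    for m in range(len(t) - 1):
        dt = t[m + 1] - t[m]
        v = (phi[m + 1] - phi[m]) / dt
        y = np.maximum(0.5 * (phi[m + 1] + phi[m]), 0.0)
        r = v - model.rhs(y)
        total += 0.5 * float(r @ r) * dt
    return total


def _action_and_grad(interior: np.ndarray, ends: tuple[np.ndarray, np.ndarray],
                     dt: float, model: HillModel, dim: int) -> tuple[float, np.ndarray]:
    n_int = interior.size // dim
    phi = np.vstack([ends[0], interior.reshape(n_int, dim), ends[1]])
    n_seg = phi.shape[0] - 1
    res = np.empty((n_seg, dim))
    jacs = []
    total = 0.0
    for m in range(n_seg):
        y = np.maximum(0.5 * (phi[m + 1] + phi[m]), 0.0)
        v = (phi[m + 1] - phi[m]) / dt
        r = v - model.rhs(y)
        res[m] = r
        jacs.append(model.jacobian(y))
        total += 0.5 * float(r @ r) * dt
    grad = np.zeros((n_int, dim))
    for k in range(1, n_seg):  # interior node k sits between segments k-1 and k
        grad[k - 1] = (res[k - 1] - res[k]) \
            - 0.5 * dt * (jacs[k - 1].T @ res[k - 1] + jacs[k].T @ res[k])
    return total, grad.ravel()


@dataclass
class TransitionPath:
    times: np.ndarray
    points: np.ndarray  # (n_points, dim)
    action: float
    source: np.ndarray
    target: np.ndarray
    T: float
    converged: bool = True


def minimum_action_path(model: HillModel, from_state: np.ndarray,
                        to_state: np.ndarray, T: float | tuple = (20.0, 50.0, 100.0),
                        n_points: int = 100, init: np.ndarray | None = None,
                        maxiter: int = 400) -> TransitionPath:
    """Minimize the transition action between two attractors.

    The path is discretized on ``n_points`` nodes with fixed endpoints
    and optimized by L-BFGS-B with the analytic action gradient,
    starting from a straight line (or ``init``).  When ``T`` is a
    ladder of horizons, each is optimized and the minimizer returned.
    """
    a = np.asarray(from_state, dtype=float)
    b = np.asarray(to_state, dtype=float)
    dim = a.size
    horizons = (T,) if np.isscalar(T) else tuple(T)
    best: TransitionPath | None = None
    for horizon in horizons:
        dt = horizon / (n_points - 1)
        if init is not None and init.shape == (n_points, dim):
            phi0 = init.copy()
        else:
            lam = np.linspace(0.0, 1.0, n_points)[:, None]
            phi0 = (1 - lam) * a + lam * b
        x0 = phi0[1:-1].ravel()
        res = minimize(_action_and_grad, x0, args=((a, b), dt, model, dim),
                       jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * x0.size,
                       options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9})
        phi = np.vstack([a, res.x.reshape(-1, dim), b])
        times = np.linspace(0.0, horizon, n_points)
        action = path_action(phi, times, model)
        cand = TransitionPath(times=times, points=phi, action=action,
                              source=a, target=b, T=horizon,
                              converged=bool(res.success))
        if best is None or cand.action < best.action:
            best = cand
    assert best is not None
    return best


def discretize_path(path: TransitionPath | np.ndarray, levels: int = 2
                    ) -> np.ndarray:
    """Per-TF min-max normalization along the path, then equal-width binning.

    Returns an integer array (n_points, dim) with values in
    ``0 .. levels-1``; a TF constant along the path is assigned its
    lower boundary bin with a warning.
    """
    pts = path.points if isinstance(path, TransitionPath) else np.asarray(path)
    if pts.shape[0] < 2:
        raise ValueError("path needs at least 2 points")
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    out = np.zeros(pts.shape, dtype=int)
    for j in range(pts.shape[1]):
        if span[j] <= 0:
            warnings.warn(f"variable {j} constant along path; assigned bin 0")
            continue
        norm = (pts[:, j] - lo[j]) / span[j]
        out[:, j] = np.minimum((norm * levels).astype(int), levels - 1)
    return out


def switching_order(path: TransitionPath, names: list[str] | None = None
                    ) -> list[tuple[str, int]]:
    """First midpoint-crossing index of each variable along the path.

    Returns (name, index) sorted by crossing time; variables that never
    cross their min-max midpoint are omitted.
    """
    binary = discretize_path(path, levels=2)
    order = []
    for j in range(binary.shape[1]):
        flips = np.nonzero(np.diff(binary[:, j]) != 0)[0]
        if flips.size:
            name = names[j] if names else str(j)
            order.append((name, int(flips[0]) + 1))
    return sorted(order, key=lambda kv: kv[1])


# ---------------------------------------------------------------------------
# transition-action sensitivity


def sensitivity_scan(tcell_model, transitions: list[tuple[str, str]],
                     delta: float = 0.01, parameters: list[str] | None = None,
                     D: float = 0.01, n_points: int = 60,
                     T: float | tuple = 40.0, seed: int = 0):
    """Percent change of transition actions under per-parameter perturbation.

    Each parameter is multiplied by ``1 + delta`` and ``1 - delta``
    individually; models that lose quadristability are marked excluded.
    ``transitions`` are (from_stage, to_stage) label pairs.  Returns a
    pandas DataFrame with one row per (parameter, direction, transition).
    """
    import pandas as pd

    from .tcell import reference_attractors, stage_attractors

    base_refs = reference_attractors(tcell_model, seed=seed)
    base_actions = {}
    for src, dst in transitions:
        mp = minimum_action_path(tcell_model.model, base_refs[src], base_refs[dst],
                                 T=T, n_points=n_points)
        base_actions[(src, dst)] = mp.action

    names = parameters if parameters is not None else tcell_model.free_parameter_names()
    rows = []
    for name in names:
        for direction in (+1, -1):
            value = tcell_model.get_parameter(name) * (1.0 + direction * delta)
            perturbed = tcell_model.with_parameter(name, value)
            perturbed.set_notch(0.0)
            aset, labels = stage_attractors(perturbed, N=0.0, seed=seed)
            if labels is None or aset.n_stable != 4:
                for src, dst in transitions:
                    rows.append({"parameter": name, "direction": direction,
                                 "transition": f"{src}->{dst}",
                                 "pct_change": np.nan, "excluded": True})
                continue
            refs = {lab: s for lab, s in zip(labels, aset.stable_states)}
            for src, dst in transitions:
                mp = minimum_action_path(perturbed.model, refs[src], refs[dst],
                                         T=T, n_points=n_points)
                s0 = base_actions[(src, dst)]
                rows.append({"parameter": name, "direction": direction,
                             "transition": f"{src}->{dst}",
                             "pct_change": 100.0 * (mp.action - s0) / s0,
                             "excluded": False})
    return pd.DataFrame(rows)
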