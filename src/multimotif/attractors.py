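"""Attractor finding, stability analysis and ordering classification.

The workhorse is :func:`find_attractors`: integrate the ODEs from a
Latin-hypercube set of initial conditions, polish converged endpoints
by Newton root-finding, merge duplicates, and decide stability from
the eigenvalues of the analytic Jacobian.  Endpoints that fail to
converge are screened for sustained oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import HillModel, latin_hypercube_points

# ``stabilized`` threshold on the integration endpoint, before polishing
STABILIZED_TOL = 1e-3
# fixed-point tolerance after Newton polishing
FIXED_POINT_TOL = 1e-6
DEFAULT_MERGE_TOL = 1e-2


class PreconditionError(ValueError):
    """An operation was called outside its stated precondition."""


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (time, nodes)

    def tail(self, fraction: float) -> "Trajectory":
        t_cut = self.times[-1] - fraction * (self.times[-1] - self.times[0])
        mask = self.times >= t_cut
        return Trajectory(self.times[mask], self.states[mask])


@dataclass
class AttractorSet:
    """Merged stable steady states plus bookkeeping.

    ``ordering`` is ``"ordered"`` / ``"unordered"`` when the set holds
    exactly four stable states, ``"n/a"`` otherwise.
    """

    states: list[np.ndarray]
    stable: list[bool]
    eigenvalues: list[np.ndarray]
    merge_tolerance: float
    basin_counts: list[int]
    n_initial: int
    ordering: str = "n/a"
    n_failed: int = 0
    n_oscillatory: int = 0
    marginal: list[bool] = field(default_factory=list)

    @property
    def stable_states(self) -> list[np.ndarray]:
        return [s for s, ok in zip(self.states, self.stable) if ok]

    @property
    def n_stable(self) -> int:
        return sum(self.stable)


def linear_stability(model: HillModel, state: np.ndarray,
                     fp_tol: float = FIXED_POINT_TOL) -> tuple[bool, np.ndarray, bool]:
    """Classify a fixed point from Jacobian eigenvalues.

    Returns ``(stable, eigenvalues, marginal)``.  Stability requires
    every eigenvalue real part strictly negative; a zero-real-part
    eigenvalue is reported unstable with the ``marginal`` flag set.
    """
    state = np.asarray(state, dtype=float)
    if np.linalg.norm(model.rhs(np.maximum(state, 0.0)), np.inf) > fp_tol:
        raise PreconditionError("state is not a fixed point at the requested tolerance")
    eig = np.linalg.eigvals(model.jacobian(np.maximum(state, 0.0)))
    max_re = float(np.max(eig.real))
    stable = max_re < 0.0
    marginal = abs(max_re) < 1e-9
    return stable and not marginal, eig, marginal


def detect_oscillation(trajectory: Trajectory, tail_fraction: float = 0.1,
                       tol: float = 1e-2) -> bool:
    """True iff any variable's tail-window peak-to-peak amplitude exceeds ``tol``."""
    if tail_fraction > 0.5 or len(trajectory.times) < 3:
        raise PreconditionError("trajectory must span at least twice the tail window")
    tail = trajectory.tail(tail_fraction)
    amplitude = tail.states.max(axis=0) - tail.states.min(axis=0)
    return bool(np.any(amplitude > tol))


def _merge_states(states: list[np.ndarray], counts: list[int],
                  merge_tol: float) -> tuple[list[np.ndarray], list[int]]:
    """Greedy merge of states closer than ``merge_tol`` (relative Euclidean).

    States are processed in lexicographic order so the outcome does not
    depend on discovery order (which varies with the multistart seed).
    """
    order = sorted(range(len(states)), key=lambda i: tuple(states[i]))
    states = [states[i] for i in order]
    counts = [counts[i] for i in order]
    merged: list[np.ndarray] = []
    merged_counts: list[int] = []
    for s, c in zip(states, counts):
        for i, m in enumerate(merged):
            scale = max(1.0, np.linalg.norm(m))
            if np.linalg.norm(s - m) / scale < merge_tol:
                merged_counts[i] += c
                break
        else:
            merged.append(s)
            merged_counts.append(c)
    return merged, merged_counts


def find_attractors(model: HillModel, n_init: int = 125,
                    box: tuple[float, float] = (0.0, 3.3), t_end: float = 500.0,
                    merge_tol: float = DEFAULT_MERGE_TOL, seed: int = 0,
                    extra_starts: np.ndarray | None = None,
                    classify: bool = True) -> AttractorSet:
    """Locate stable steady states by multi-start integration.

    Initial conditions are ``n_init`` Latin-hypercube points in
    ``box^dims`` (plus optional ``extra_starts``).  Each trajectory is
    integrated to ``t_end``; endpoints with ``||RHS||_inf`` below the
    stabilization threshold are polished by Newton iteration, merged
    within ``merge_tol`` and stability-checked.  Non-converged runs are
    screened with :func:`detect_oscillation`.
    """
    dim = model.n_dim
    starts = latin_hypercube_points(n_init, dim, box[0], box[1], seed)
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([starts, np.asarray(extra_starts, dtype=float)])

    raw_states: list[np.ndarray] = []
    raw_counts: list[int] = []
    n_failed = 0
    n_osc = 0
    for x0 in starts:
        try:
            sol = solve_ivp(model.rhs_time, (0.0, t_end), x0, method="LSODA",
                            jac=model.jac_time, rtol=1e-8, atol=1e-10,
                            t_eval=np.linspace(0.0, t_end, 51))
        except Exception:
            n_failed += 1
            continue
        if not sol.success:
            n_failed += 1
            continue
        end = np.maximum(sol.y[:, -1], 0.0)
        if np.linalg.norm(model.rhs(end), np.inf) < STABILIZED_TOL:
            res = root(lambda x: model.rhs(np.maximum(x, 0.0)), end,
                       jac=lambda x: model.jacobian(np.maximum(x, 0.0)), method="hybr")
            cand = np.maximum(res.x, 0.0)
            if res.success and np.linalg.norm(model.rhs(cand), np.inf) < FIXED_POINT_TOL:
                raw_states.append(cand)
                raw_counts.append(1)
            else:
                n_failed += 1
        else:
            traj = Trajectory(sol.t, sol.y.T)
            if detect_oscillation(traj, tail_fraction=0.1, tol=1e-2):
                n_osc += 1
            else:
                n_failed += 1

    merged, counts = _merge_states(raw_states, raw_counts, merge_tol)
    states, stable, eigs, marg, basin = [], [], [], [], []
    for s, c in zip(merged, counts):
        ok, eig, marginal = linear_stability(model, s)
        states.append(s)
        stable.append(ok)
        eigs.append(eig)
        marg.append(marginal)
        basin.append(c)

    aset = AttractorSet(states=states, stable=stable, eigenvalues=eigs,
                        merge_tolerance=merge_tol, basin_counts=basin,
                        n_initial=len(starts), n_failed=n_failed,
                        n_oscillatory=n_osc, marginal=marg)
    if classify and aset.n_stable == 4:
        aset.ordering = classify_ordering(aset)
    return aset


def find_fixed_points(model: HillModel, n_starts: int = 60,
                      box: tuple[float, float] = (0.0, 3.3), seed: int = 0,
                      merge_tol: float = DEFAULT_MERGE_TOL,
                      extra_starts: np.ndarray | None = None,
                      grid_starts: int = 0) -> AttractorSet:
    """Enumerate fixed points (stable and unstable) by multi-start Newton.

    Complements :func:`find_attractors`, which only reaches stable
    states; saddles are needed for phase planes, bifurcation branches
    and steady-state counting.  ``grid_starts > 0`` adds a deterministic
    ``grid_starts**dim`` lattice of starting points, which makes the
    recovered fixed-point set essentially independent of ``seed``.
    """
    starts = latin_hypercube_points(n_starts, model.n_dim, box[0], box[1], seed)
    if grid_starts > 0:
        axes = [np.linspace(box[0], box[1], grid_starts + 2)[1:-1]] * model.n_dim
        lattice = np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, model.n_dim)
        starts = np.vstack([starts, lattice])
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([starts, np.asarray(extra_starts, dtype=float)])
    raw, counts = [], []
    for x0 in starts:
        res = root(lambda x: model.rhs(np.maximum(x, 0.0)), x0,
                   jac=lambda x: model.jacobian(np.maximum(x, 0.0)), method="hybr")
        cand = np.maximum(res.x, 0.0)
        if res.success and np.linalg.norm(model.rhs(cand), np.inf) < FIXED_POINT_TOL:
            raw.append(cand)
            counts.append(1)
    merged, counts = _merge_states(raw, counts, merge_tol)
    states, stable, eigs, marg, basin = [], [], [], [], []
    for s, c in zip(merged, counts):
        ok, eig, marginal = linear_stability(model, s)
        states.append(s)
        stable.append(ok)
        eigs.append(eig)
        marg.append(marginal)
        basin.append(c)
    return AttractorSet(states=states, stable=stable, eigenvalues=eigs,
                        merge_tolerance=merge_tol, basin_counts=basin,
                        n_initial=len(starts), marginal=marg)


def classify_ordering(attractors: AttractorSet | list[np.ndarray]) -> str:
    """Classify four stable states as ``ordered`` or ``unordered``.

    Ordered means the four states admit an arrangement along which
    every TF is monotone (non-strictly) and at least one TF strictly
    monotone: the "stepwise" pattern where any two TFs are monotonically
    coupled across the states.
    """
    if isinstance(attractors, AttractorSet):
        states = attractors.stable_states
    else:
        states = list(attractors)
    if len(states) != 4:
        raise PreconditionError("ordering is defined for exactly 4 stable states")
    mat = np.asarray(states)  # (4, n_tf)

    # Sorting by any single strictly-varying TF either yields a monotone
    # arrangement or none exists; checking both orientations of each TF's
    # sort covers ties, which is equivalent to scanning all 24 permutations.
    from itertools import permutations

    for perm in permutations(range(4)):
        arranged = mat[list(perm)]
        diffs = np.diff(arranged, axis=0)
        monotone = np.all(diffs >= -1e-9, axis=0) | np.all(diffs <= 1e-9, axis=0)
        strict = np.all(diffs > 1e-9, axis=0) | np.all(diffs < -1e-9, axis=0)
        if monotone.all() and strict.any():
            return "ordered"
    return "unordered"
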