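"""Performance comparison of motif circuits by quasi-steady-state reduction.

A network containing PU.1 is reduced to a single effective ODE for
PU.1: at each PU.1 level the remaining TFs are set to their (lowest
stable) steady state and substituted into PU.1's production term.  The
resulting effective production curve is fitted, by differential
evolution over the network's kinetic parameters, to a surrogate
production function whose intersections with the degradation line
define a four-attractor target system (seven crossings, alternating
stability).  Networks embedding more copies of the motif fit the
surrogate better, which is the comparison of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import differential_evolution, root

from .model import ADDITIVE, ParameterSet, build_model, hill_activation, substream_seed
from .topology import Topology

PU1 = "PU1"


# ---------------------------------------------------------------------------
# surrogate target system


def default_surrogate(rd: float = 1.0) -> tuple[Callable, Callable]:
    """A staircase production curve with 7 crossings of ``rd * x``.

    Returns ``(production, degradation)`` callables on PU.1 level.  The
    production curve is a sum of three sharp Hill steps plus a basal
    term; with the linear degradation line it has seven intersections
    of alternating stability, hence four stable states.
    """
    # each plateau must overshoot the degradation line at its step and be
    # overtaken again before the next step: 4 stable / 3 unstable crossings
    steps = ((0.75, 0.5), (1.10, 1.5), (1.20, 2.5))  # (height, center)
    basal = 0.12

    def production(x):
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, basal)
        for height, center in steps:
            out = out + height * hill_activation(x, center, 12.0)
        return out

    def degradation(x):
        return rd * np.asarray(x, dtype=float)

    return production, degradation


def count_crossings(production: Callable, degradation: Callable,
                    grid: np.ndarray) -> int:
    diff = production(grid) - degradation(grid)
    return int(np.sum(np.sign(diff[1:]) != np.sign(diff[:-1])))


# ---------------------------------------------------------------------------
# QSS reduction


@dataclass
class EffectiveProductionCurve:
    grid: np.ndarray
    rates: np.ndarray
    network_id: str
    multivalued: bool = False


def qss_reduce(topology: Topology, params: ParameterSet, grid: np.ndarray,
               pu1: str = PU1) -> EffectiveProductionCurve:
    """Effective PU.1 production rate under the quasi-steady-state assumption.

    At each grid value of PU.1 the non-PU.1 subsystem is relaxed to its
    steady state (lowest stable branch, tracked by continuation from
    the previous grid point) and PU.1's production term is evaluated
    there.
    """
    if pu1 not in topology.nodes:
        raise ValueError(f"{pu1} not in topology")
    model = build_model(topology, params)
    idx = topology.nodes.index(pu1)
    others = [i for i in range(model.n_dim) if i != idx]
    rates = np.empty(len(grid))
    multivalued = False
    # start others at their basal levels
    y_prev = np.array([params.k0[v] / params.rd[v] + 1e-3 for v in topology.nodes])

    for g, p_val in enumerate(np.asarray(grid, dtype=float)):
        if others:
            def sub_rhs(y):
                x = y_prev.copy()
                x[idx] = p_val
                x[others] = np.maximum(y, 0.0)
                return model.rhs(np.maximum(x, 0.0))[others]

            guesses = [y_prev[others]]
            if g == 0:
                guesses += [np.full(len(others), 0.05),
                            np.full(len(others), 1.0)]
            sols = []
            for y0 in guesses:
                res = root(sub_rhs, y0, method="hybr")
                if res.success:
                    sols.append(np.maximum(res.x, 0.0))
            if not sols:
                rates[g] = rates[g - 1] if g else np.nan
                multivalued = True
                continue
            if len(sols) > 1 and np.ptp([s.sum() for s in sols]) > 1e-6:
                multivalued = True
            best = min(sols, key=lambda s: s.sum())  # lowest branch convention
            y_prev[others] = best
        x = y_prev.copy()
        x[idx] = p_val
        # production part of PU.1's RHS (add back degradation)
        rates[g] = model.rhs(np.maximum(x, 0.0))[idx] + params.rd[pu1] * p_val
    return EffectiveProductionCurve(grid=np.asarray(grid, dtype=float), rates=rates,
                                    network_id=topology.canonical_key(),
                                    multivalued=multivalued)


def ssd_objective(curve: np.ndarray, surrogate: np.ndarray) -> float:
    """Sum of squared distances between two curves on a common grid."""
    c = np.asarray(curve, dtype=float)
    s = np.asarray(surrogate, dtype=float)
    if c.shape != s.shape:
        raise ValueError("curves must share a grid")
    return float(np.sum((c - s) ** 2))


# ---------------------------------------------------------------------------
# example circuits: one vs. several interlinked PU.1-centred loops


def pu1_loop_network(n_loops: int) -> Topology:
    """PU.1 with a self-activation and ``n_loops - 1`` two-node positive
    loops through helper TFs — every loop closes at PU.1, so three or
    more loops form the shared-node (Type I) motif family."""
    if n_loops < 1:
        raise ValueError("need at least one loop")
    nodes = [PU1] + [f"H{i}" for i in range(1, n_loops)]
    edges = [(PU1, PU1, 1)]
    for helper in nodes[1:]:
        edges += [(PU1, helper, 1), (helper, PU1, 1)]
    return Topology.from_edges(nodes, edges)


def _vector_to_params(topology: Topology, vec: np.ndarray,
                      rd: float = 1.0) -> ParameterSet:
    """Map an optimizer vector to an additive-form ParameterSet.

    Layout: [k0_PU1, then per regulation (beta*k amplitude, K, n)].
    Helper TFs get fixed unit kinetics; only regulation shapes are free.
    """
    edges = topology.sorted_edges()
    k0 = {v: 0.0 for v in topology.nodes}
    k = {v: 1.0 for v in topology.nodes}
    rd_map = {v: rd for v in topology.nodes}
    k0[PU1] = float(vec[0])
    K, n, beta = {}, {}, {}
    for i, (s, t, _g) in enumerate(edges):
        amp, kk, nn = vec[1 + 3 * i: 4 + 3 * i]
        beta[(s, t)] = float(amp)
        K[(s, t)] = float(kk)
        n[(s, t)] = float(nn)
    return ParameterSet(k0=k0, k=k, rd=rd_map, K=K, n=n, beta=beta, form=ADDITIVE)


def fit_network_to_surrogate(topology: Topology, grid: np.ndarray,
                             target: np.ndarray, seed: int,
                             maxiter: int = 60, popsize: int = 12) -> float:
    """One differential-evolution run; returns the best SSD found."""
    n_edges = topology.n_regulations
    bounds = [(0.0, 0.5)] + [(0.0, 1.5), (0.05, 3.0), (1.0, 12.0)] * n_edges

    def objective(vec):
        params = _vector_to_params(topology, vec)
        try:
            curve = qss_reduce(topology, params, grid)
        except Exception:
            return 1e6
        if np.any(~np.isfinite(curve.rates)):
            return 1e6
        return ssd_objective(curve.rates, target)

    res = differential_evolution(objective, bounds, seed=int(seed),
                                 maxiter=maxiter, popsize=popsize, tol=1e-8,
                                 polish=False, updating="deferred")
    return float(res.fun)


def compare_networks(network1: Topology, network2: Topology,
                     runs: int = 20, seed: int = 0, n_grid: int = 40,
                     maxiter: int = 60) -> dict[str, np.ndarray]:
    """Distributions of best SSDs from repeated optimization runs.

    The surrogate is the default seven-crossing staircase.  Returns
    ``{"network1": ssd array, "network2": ssd array}``; a lower median
    for the network embedding more motif copies is the expected
    outcome.
    """
    grid = np.linspace(0.0, 3.4, n_grid)
    production, _deg = default_surrogate()
    target = production(grid)
    out = {}
    for label, topo in (("network1", network1), ("network2", network2)):
        ssds = np.array([
            fit_network_to_surrogate(topo, grid, target,
                                     substream_seed(seed, "ssd", label, r),
                                     maxiter=maxiter)
            for r in range(runs)
        ])
        out[label] = ssds
    return out
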