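"""Early T-cell commitment model: four core TFs driven by Notch.

The network couples PU.1 (progenitor / alternative-lineage factor)
with the T-lineage factors TCF-1, GATA3 and BCL11B.  Its four stable
states at zero Notch correspond to the ETP/DN1, DN2a, DN2b and DN3
developmental stages: PU.1 decreases and the three T-lineage factors
increase monotonically along the stage sequence.  Increasing Notch
removes the earlier states through a cascade of saddle-node
bifurcations, which is what makes each commitment step irreversible.

The model definition (topology, multiplicative-form parameters and the
additive Notch drives) ships as a packaged JSON fixture.  The fixture
is synthetic: it was constructed by the package's own random parameter
search under the four-attractor selection criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .attractors import (AttractorSet, PreconditionError, Trajectory,
                         find_attractors, find_fixed_points)
from .model import (ConfigurationError, HillModel, InputDrive, ParameterSet,
                    build_model, substream_seed)
from .topology import Topology

TF_NODES = ("PU1", "TCF1", "GATA3", "BCL11B")
STAGES = ("ETP", "DN2a", "DN2b", "DN3")
NOTCH = "Notch"

# state-space box for multi-start searches, sized to the fixture's dynamic range
STATE_BOX = (0.0, 3.3)


@dataclass
class TCellModel:
    """A compiled T-cell model plus its definition for round-tripping."""

    model: HillModel
    topology: Topology
    params: ParameterSet
    inputs: list[InputDrive]

    @property
    def N(self) -> float:
        try:
            return self.model.get_input(NOTCH)
        except KeyError:
            return 0.0

    def set_notch(self, value: float) -> None:
        self.model.set_input(NOTCH, value)

    def free_parameter_names(self) -> list[str]:
        """Flat names of all free parameters, excluding the signal level N."""
        names = [k for k in self.params.to_flat_dict() if k != "form"]
        for d in self.inputs:
            for field in ("k", "K", "n"):
                names.append(f"input.{d.signal}->{d.target}.{field}")
        return names

    @property
    def n_free_parameters(self) -> int:
        return len(self.free_parameter_names())

    def with_parameter(self, name: str, value: float) -> "TCellModel":
        """Return a copy with one flat-named parameter replaced."""
        if name.startswith("input."):
            _, rest = name.split(".", 1)
            edge, field = rest.rsplit(".", 1)
            signal, _, target = edge.partition("->")
            new_inputs = []
            hit = False
            for d in self.inputs:
                if d.signal == signal and d.target == target:
                    kwargs = {"signal": d.signal, "target": d.target,
                              "k": d.k, "K": d.K, "n": d.n}
                    kwargs[field] = float(value)
                    new_inputs.append(InputDrive(**kwargs))
                    hit = True
                else:
                    new_inputs.append(d)
            if not hit:
                raise ConfigurationError(f"unknown input parameter {name!r}")
            params = self.params
        else:
            flat = self.params.to_flat_dict()
            if name not in flat:
                raise ConfigurationError(f"unknown parameter {name!r}")
            flat[name] = float(value)
            params = ParameterSet.from_flat_dict(flat)
            new_inputs = list(self.inputs)
        out = TCellModel(model=build_model(self.topology, params, new_inputs),
                         topology=self.topology, params=params, inputs=new_inputs)
        if any(d.signal == NOTCH for d in new_inputs):
            out.set_notch(self.N)
        return out

    def get_parameter(self, name: str) -> float:
        if name.startswith("input."):
            _, rest = name.split(".", 1)
            edge, field = rest.rsplit(".", 1)
            signal, _, target = edge.partition("->")
            for d in self.inputs:
                if d.signal == signal and d.target == target:
                    return getattr(d, field)
            raise ConfigurationError(f"unknown input parameter {name!r}")
        flat = self.params.to_flat_dict()
        if name not in flat:
            raise ConfigurationError(f"unknown parameter {name!r}")
        return float(flat[name])

    def to_definition_dict(self) -> dict:
        return {
            "topology": self.topology.to_dict(),
            "parameters": self.params.to_flat_dict(),
            "inputs": [
                {"signal": d.signal, "target": d.target, "k": d.k, "K": d.K, "n": d.n}
                for d in self.inputs
            ],
        }


def load_model_definition(source: str | Path | dict) -> TCellModel:
    """Build a T-cell model from a definition mapping or JSON file.

    The definition carries the 4-TF topology, a multiplicative-form
    parameter set and the additive external drives of the reserved
    input signal ``Notch``.
    """
    if isinstance(source, dict):
        d = source
    else:
        p = Path(source)
        d = json.loads(p.read_text() if p.exists() else str(source))
    missing = [k for k in ("topology", "parameters", "inputs") if k not in d]
    if missing:
        raise ConfigurationError(f"model definition missing entries: {missing}")
    topology = Topology.from_dict(d["topology"])
    params = ParameterSet.from_flat_dict(d["parameters"])
    inputs = [InputDrive(signal=e["signal"], target=e["target"],
                         k=float(e["k"]), K=float(e["K"]), n=float(e["n"]))
              for e in d["inputs"]]
    model = build_model(topology, params, inputs)
    return TCellModel(model=model, topology=topology, params=params, inputs=inputs)


def tcell_model(N: float = 0.0) -> TCellModel:
    """Load the packaged (synthetic) T-cell model fixture at Notch level ``N``."""
    text = resources.files("multimotif.data").joinpath(
        "tcell_model_synthetic.json").read_text()
    tm = load_model_definition(json.loads(text))
    tm.set_notch(N)
    return tm


def apply_knockout(tm: TCellModel, factor: str, zero_basal: bool = True) -> TCellModel:
    """Knock out a factor by zeroing its regulated (and basal) production.

    Double application is idempotent.  ``zero_basal=False`` zeroes only
    the regulated maximum production rate.
    """
    if factor not in tm.topology.nodes:
        raise ConfigurationError(f"unknown factor {factor!r}")
    out = tm.with_parameter(f"k.{factor}", 0.0)
    if zero_basal:
        out = out.with_parameter(f"k0.{factor}", 0.0)
    return out


# ---------------------------------------------------------------------------
# attractors and stage labels


def stage_attractors(tm: TCellModel, N: float | None = None, n_init: int = 125,
                     seed: int = 0, references: dict[str, np.ndarray] | None = None
                     ) -> tuple[AttractorSet, list[str] | None]:
    """Attractors at Notch level ``N`` with developmental stage labels.

    With four stable states, labels are assigned by rank along the
    monotone ordering (PU.1 descending).  With fewer states (knockouts,
    high Notch), labels are taken from the nearest ``references``
    attractor when provided; otherwise ranks are counted from the top
    of the sequence, which matches the high-Notch case where only the
    most committed states survive.  If the stable states violate the
    stepwise ordering (PU.1 decreasing, the T-lineage factors
    non-decreasing), labels are withheld and the raw attractors
    returned.
    """
    if N is not None:
        tm.set_notch(N)
    aset = find_attractors(tm.model, n_init=n_init, box=STATE_BOX, seed=seed)
    states = aset.stable_states
    if not states:
        return aset, None
    if references is not None:
        return aset, [nearest_stage(s, references) for s in states]
    pu1 = tm.topology.nodes.index("PU1")
    order = np.argsort([-s[pu1] for s in states])
    mat = np.asarray([states[i] for i in order])
    if len(states) > 1:
        diffs = np.diff(mat, axis=0)
        ok = np.all(diffs[:, pu1] < 0)
        for j in range(mat.shape[1]):
            if j == pu1:
                continue
            ok = ok and np.all(diffs[:, j] > -1e-6)
        if not ok:
            return aset, None
    # stages assigned from the top: a monostable high-Notch system is DN3
    n = len(states)
    offset = 4 - n if n <= 4 else 0
    labels_sorted = [STAGES[min(offset + i, 3)] for i in range(n)]
    labels = [""] * n
    for rank, idx in enumerate(order):
        labels[idx] = labels_sorted[rank]
    return aset, labels


def reference_attractors(tm: TCellModel, seed: int = 0) -> dict[str, np.ndarray]:
    """The four N=0 reference states keyed by stage label."""
    notch0 = tm.N
    aset, labels = stage_attractors(tm, N=0.0, seed=seed)
    tm.set_notch(notch0)
    if labels is None or aset.n_stable != 4:
        raise PreconditionError("model is not quadristable at N = 0")
    return {lab: s for lab, s in zip(labels, aset.stable_states)}


def nearest_stage(state: np.ndarray, references: dict[str, np.ndarray],
                  log_floor: float = 1e-3) -> str:
    """Stage of the nearest reference attractor in log-concentration space."""
    logs = np.log(np.maximum(np.asarray(state, dtype=float), log_floor))
    best, best_d = None, np.inf
    for lab, ref in references.items():
        d = np.linalg.norm(logs - np.log(np.maximum(ref, log_floor)))
        if d < best_d:
            best, best_d = lab, d
    return best


# ---------------------------------------------------------------------------
# bifurcation scanning


@dataclass
class BifurcationBranch:
    control: str
    grid: np.ndarray
    points: list[AttractorSet]  # fixed points (stable + unstable) per grid value
    saddle_nodes: list[float]

    @property
    def stable_counts(self) -> np.ndarray:
        return np.array([a.n_stable for a in self.points])


def _model_at(tm: TCellModel, control: str, value: float) -> TCellModel:
    if control in ("N", NOTCH):
        out = tm
        out.set_notch(value)
        return out
    # aliases kB etc. map to flat parameter names
    alias = {"kB": "k.BCL11B", "kP": "k.PU1", "kT": "k.TCF1", "kG": "k.GATA3"}
    return tm.with_parameter(alias.get(control, control), value)


def _fixed_points_at(tm: TCellModel, control: str, value: float,
                     extra_starts, seed: int, n_starts: int = 80) -> AttractorSet:
    m = _model_at(tm, control, value)
    return find_fixed_points(m.model, n_starts=n_starts, box=STATE_BOX,
                             seed=seed, extra_starts=extra_starts)


def scan_bifurcation(tm: TCellModel, control: str, grid,
                     seed: int = 0, refine_tol: float = 1e-4) -> BifurcationBranch:
    """Brute-force continuation along a monotone control grid.

    At each grid value all fixed points are recomputed by multi-start
    Newton, seeding the search with the previous step's branch points
    so that branches are tracked through folds.  Saddle-node events are
    localized by bisection on the stable-state count between adjacent
    grid values, to ``refine_tol`` in the control parameter.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("control grid must be strictly increasing")
    has_notch = any(d.signal == NOTCH for d in tm.inputs)
    notch0 = tm.N
    points: list[AttractorSet] = []
    prev_states: np.ndarray | None = None
    for v in grid:
        aset = _fixed_points_at(tm, control, v, prev_states, seed)
        points.append(aset)
        prev_states = np.asarray(aset.states) if aset.states else None

    saddle_nodes: list[float] = []
    counts = [a.n_stable for a in points]
    for i in range(len(grid) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = grid[i], grid[i + 1]
        c_lo = counts[i]
        seeds_states = np.asarray(points[i].states) if points[i].states else None
        # one event per unit change in stable count across the interval
        n_events = abs(counts[i + 1] - c_lo)
        a, b = lo, hi
        for _ in range(n_events):
            a_, b_ = a, b
            while b_ - a_ > refine_tol:
                mid = 0.5 * (a_ + b_)
                c_mid = _fixed_points_at(tm, control, mid, seeds_states, seed).n_stable
                if c_mid == c_lo:
                    a_ = mid
                else:
                    b_ = mid
            saddle_nodes.append(0.5 * (a_ + b_))
            break  # multiple events inside one interval are rare at sane grids
    if has_notch:
        tm.set_notch(notch0)
    return BifurcationBranch(control=control, grid=grid, points=points,
                             saddle_nodes=saddle_nodes)


# ---------------------------------------------------------------------------
# signal protocols


def relax_to_stage(tm: TCellModel, x0: np.ndarray, references: dict[str, np.ndarray],
                   t_relax: float = 500.0) -> tuple[str, np.ndarray]:
    sol = solve_ivp(tm.model.rhs_time, (0.0, t_relax), x0, method="LSODA",
                    jac=tm.model.jac_time, rtol=1e-8, atol=1e-10)
    end = np.maximum(sol.y[:, -1], 0.0)
    return nearest_stage(end, references), end


def signal_response_grid(tm: TCellModel, strengths, durations,
                         seed: int = 0) -> np.ndarray:
    """Stage matrix for pulses of Notch: strength held for a duration, then 0.

    Returns an integer stage-index matrix of shape
    ``(len(strengths), len(durations))`` (-1 marks a non-converged cell).
    The system starts at the ETP attractor.
    """
    refs = reference_attractors(tm, seed=seed)
    etp = refs["ETP"]
    durations = np.asarray(sorted(durations), dtype=float)
    out = np.zeros((len(strengths), len(durations)), dtype=int)
    stage_index = {s: i for i, s in enumerate(STAGES)}
    for i, s in enumerate(strengths):
        tm.set_notch(float(s))
        if s <= 0 or durations[-1] <= 0:
            pulse_states = [etp for _ in durations]
        else:
            t_eval = np.maximum(durations, 0.0)
            sol = solve_ivp(tm.model.rhs_time, (0.0, float(durations[-1])), etp,
                            method="LSODA", jac=tm.model.jac_time,
                            rtol=1e-8, atol=1e-10, t_eval=t_eval)
            pulse_states = [np.maximum(sol.y[:, j], 0.0) for j in range(sol.y.shape[1])]
        tm.set_notch(0.0)
        for j, xd in enumerate(pulse_states):
            if durations[j] <= 0:
                out[i, j] = 0
                continue
            stage, _ = relax_to_stage(tm, xd, refs)
            out[i, j] = stage_index[stage]
    return out


def fluctuating_signal_sim(tm: TCellModel, mean_schedule, noise_sd: float,
                           t_end: float, interval: float = 0.1, seed: int = 0,
                           x0: np.ndarray | None = None
                           ) -> tuple[Trajectory, list[str]]:
    """Integrate under a piecewise-constant fluctuating Notch signal.

    Per 0.1-time-unit interval the signal is
    ``max(0, mean_schedule(t) + Normal(0, noise_sd))``.  Returns the
    trajectory sampled at interval boundaries and the stage path by
    nearest N=0 reference attractor.
    """
    refs = reference_attractors(tm)
    if x0 is None:
        x0 = refs["ETP"]
    rng = np.random.default_rng(substream_seed(seed, "notch-noise"))
    n_steps = int(round(t_end / interval))
    times = [0.0]
    states = [np.asarray(x0, dtype=float)]
    stages = [nearest_stage(x0, refs)]
    x = np.asarray(x0, dtype=float)
    for step in range(n_steps):
        t0 = step * interval
        mean = float(mean_schedule(t0)) if callable(mean_schedule) else float(mean_schedule)
        level = max(0.0, mean + rng.normal(0.0, noise_sd)) if noise_sd > 0 else max(0.0, mean)
        tm.set_notch(level)
        sol = solve_ivp(tm.model.rhs_time, (0.0, interval), x, method="LSODA",
                        jac=tm.model.jac_time, rtol=1e-7, atol=1e-9)
        x = np.maximum(sol.y[:, -1], 0.0)
        times.append(t0 + interval)
        states.append(x)
        stages.append(nearest_stage(x, refs))
    tm.set_notch(0.0)
    return Trajectory(np.array(times), np.array(states)), stages
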